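name: linear_pathway
theta: 0.5
time_unit: arbitrary
variables:
- name: X0
  role: independent
  initial_value: 1.0
  description: constant pathway input
- name: X1
  role: dependent
  initial_value: 1.18
  description: intermediate
- name: X2
  role: dependent
  initial_value: 0.64
  description: product pool
equations:
  X1:
    terms:
    - sign: 1
      rate: 2.0
      exponents:
        X0: 1.0
    - sign: -1
      rate: 1.75
      exponents:
        X1: 0.8
  X2:
    terms:
    - sign: 1
      rate: 1.75
      exponents:
        X1: 0.8
    - sign: -1
      rate: 2.5
      exponents:
        X2: 0.5
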
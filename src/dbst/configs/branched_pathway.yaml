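name: branched_pathway
theta: 1.0
time_unit: arbitrary
variables:
- name: X1
  role: dependent
  initial_value: 1.0
- name: X2
  role: dependent
  initial_value: 1.0
- name: X3
  role: dependent
  initial_value: 1.0
- name: X4
  role: dependent
  initial_value: 1.0
equations:
  X1:
    terms:
    - sign: 1
      rate: 0.25
      exponents:
        X3: -2.0
    - sign: -1
      rate: 0.08
      exponents:
        X1: 1.0
    - sign: -1
      rate: 0.15
      exponents:
        X1: 2.0
        X3: 0.5
  X2:
    terms:
    - sign: 1
      rate: 0.08
      exponents:
        X1: 1.0
    - sign: -1
      rate: 0.2
      exponents:
        X2: 0.4
  X3:
    terms:
    - sign: 1
      rate: 0.2
      exponents:
        X2: 0.4
    - sign: -1
      rate: 0.3
      exponents:
        X3: 0.6
  X4:
    terms:
    - sign: 1
      rate: 0.15
      exponents:
        X1: 2.0
        X3: 0.5
    - sign: -1
      rate: 0.25
      exponents:
        X4: 0.8
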
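name: lorenz_discrete
theta: 1.0
time_unit: arbitrary
variables:
- name: X1
  role: dependent
  initial_value: 10.0
- name: X2
  role: dependent
  initial_value: 10.0
- name: X3
  role: dependent
  initial_value: 30.0
equations:
  X1:
    terms:
    - sign: 1
      rate: 0.2
      exponents:
        X2: 1.0
    - sign: -1
      rate: 0.2
      exponents:
        X1: 1.0
  X2:
    terms:
    - sign: 1
      rate: 0.6
      exponents:
        X1: 1.0
    - sign: -1
      rate: 0.02
      exponents:
        X2: 1.0
    - sign: -1
      rate: 0.02
      exponents:
        X1: 1.0
        X3: 1.0
  X3:
    terms:
    - sign: 1
      rate: 0.02
      exponents:
        X1: 1.0
        X2: 1.0
    - sign: -1
      rate: 0.05
      exponents:
        X3: 1.0
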
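name: limit_cycle_oscillator
theta: 0.1
time_unit: arbitrary
variables:
- name: X1
  role: dependent
  initial_value: 0.7249193
- name: X2
  role: dependent
  initial_value: 0.8685822
equations:
  X1:
    terms:
    - sign: 1
      rate: 0.011
      exponents:
        X1: 2.0
        X2: 3.0
    - sign: -1
      rate: 0.011
      exponents:
        X1: 1.0
        X2: 1.0
  X2:
    terms:
    - sign: 1
      rate: 0.01
      exponents:
        X1: -1.0
        X2: 4.0
    - sign: -1
      rate: 0.01
      exponents:
        X1: 3.0
        X2: 5.0
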
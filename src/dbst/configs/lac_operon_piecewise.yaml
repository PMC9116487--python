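name: lac_operon_piecewise
theta: 0.1
time_unit: arbitrary
variables:
- name: X1
  role: dependent
  initial_value: 0.4308869380063768
  description: lac operon mRNA
- name: X2
  role: dependent
  initial_value: 0.2154434690031884
  description: beta-galactosidase
- name: X3
  role: dependent
  initial_value: 0.4641588833612779
  description: intracellular lactose
- name: X4
  role: independent
  initial_value: 0.1
  description: external lactose
equations:
  X1:
    regimes:
      switch: X3
      low: 0.3
      high: 0.7
      below:
      - sign: 1
        rate: 0.018
        exponents: {}
      - sign: -1
        rate: 0.1
        exponents:
          X1: 1.0
      below_label: low transcription
      middle:
      - sign: 1
        rate: 0.2
        exponents:
          X3: 2.0
      - sign: -1
        rate: 0.1
        exponents:
          X1: 1.0
      middle_label: lactose-responsive
      above:
      - sign: 1
        rate: 0.09799999999999999
        exponents: {}
      - sign: -1
        rate: 0.1
        exponents:
          X1: 1.0
      above_label: saturated transcription
  X2:
    terms:
    - sign: 1
      rate: 0.5
      exponents:
        X1: 1.0
    - sign: -1
      rate: 1.0
      exponents:
        X2: 1.0
  X3:
    terms:
    - sign: 1
      rate: 0.1
      exponents:
        X4: 1.0
    - sign: -1
      rate: 0.1
      exponents:
        X2: 1.0
        X3: 1.0
events:
- target: X4
  mode: table
  table:
  - - 0.0
    - 0.1
  - - 10.0
    - 1.0
  - - 60.0
    - 0.5
  - - 110.0
    - 0.1
  - - 160.0
    - 1.2
  - - 210.0
    - 0.4
  - - 260.0
    - 1.0
  - - 310.0
    - 0.1
metadata:
  thresholds:
    X3_low: 0.3
    X3_high: 0.7
    alpha_low: 0.018
    alpha_high: 0.09799999999999999
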
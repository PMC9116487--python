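name: ahr_delays_and_noise
theta: 0.1
time_unit: hours (approximate)
variables:
- name: L
  role: independent
  initial_value: 0.0
  description: xenobiotic ligand (independent, scheduled)
- name: X1
  role: dependent
  initial_value: 10.0
  description: free AhR
- name: X2
  role: dependent
  initial_value: 0.0
  description: ligand-bound AhR
- name: X3
  role: dependent
  initial_value: 10.0
  description: free ARNT
- name: X4
  role: dependent
  initial_value: 0.0
  description: "AhR\xB7L\xB7ARNT transcription factor"
- name: X5
  role: dependent
  initial_value: 0.0
  description: AhRR repressor protein
- name: X6
  role: dependent
  initial_value: 0.0
  description: "AhRR\xB7ARNT repressor complex"
- name: X7
  role: dependent
  initial_value: 0.0
  description: AhRR mRNA
- name: X8
  role: dependent
  initial_value: 0.0
  description: target-protein mRNA
- name: X9
  role: dependent
  initial_value: 0.0
  description: target protein (TP)
equations:
  X1:
    terms:
    - sign: -1
      rate: 1.0
      exponents:
        L: 1.0
        X1: 1.0
    - sign: 1
      rate: 2.0
      exponents:
        X2: 1.0
  X2:
    terms:
    - sign: 1
      rate: 1.0
      exponents:
        L: 1.0
        X1: 1.0
    - sign: -1
      rate: 2.0
      exponents:
        X2: 1.0
    - sign: -1
      rate: 1.0
      exponents:
        X2: 1.0
        X3: 1.0
    - sign: 1
      rate: 1.0
      exponents:
        X4: 1.0
  X3:
    terms:
    - sign: -1
      rate: 1.0
      exponents:
        X2: 1.0
        X3: 1.0
    - sign: 1
      rate: 1.0
      exponents:
        X4: 1.0
    - sign: -1
      rate: 1.0
      exponents:
        X3: 1.0
        X5: 1.0
    - sign: 1
      rate: 2.0
      exponents:
        X6: 1.0
  X4:
    terms:
    - sign: 1
      rate: 1.0
      exponents:
        X2: 1.0
        X3: 1.0
    - sign: -1
      rate: 1.0
      exponents:
        X4: 1.0
  X5:
    terms:
    - sign: 1
      rate: 10.0
      exponents:
        X7: 1.0
      delay:
        X7: 4.0
      noise: sigma3
    - sign: -1
      rate: 1.0
      exponents:
        X3: 1.0
        X5: 1.0
    - sign: 1
      rate: 2.0
      exponents:
        X6: 1.0
    - sign: -1
      rate: 2.0
      exponents:
        X5: 1.0
  X6:
    terms:
    - sign: 1
      rate: 1.0
      exponents:
        X3: 1.0
        X5: 1.0
    - sign: -1
      rate: 2.0
      exponents:
        X6: 1.0
  X7:
    terms:
    - sign: 1
      rate: 6.0
      exponents:
        X4: 1.0
        X6: -4.0
      delay:
        X4: 3.0
        X6: 3.0
      offset:
        X6: 1.0
      noise: sigma1
    - sign: -1
      rate: 10.0
      exponents:
        X7: 1.0
  X8:
    terms:
    - sign: 1
      rate: 6.0
      exponents:
        X4: 1.0
        X6: -4.0
      delay:
        X4: 3.0
        X6: 3.0
      offset:
        X6: 1.0
      noise: sigma2
    - sign: -1
      rate: 10.0
      exponents:
        X8: 1.0
  X9:
    terms:
    - sign: 1
      rate: 10.0
      exponents:
        X8: 1.0
      delay:
        X8: 4.0
      noise: sigma4
    - sign: -1
      rate: 2.0
      exponents:
        X9: 1.0
events:
- target: L
  mode: table
  table:
  - - 0.0
    - 0.0
  - - 2.0
    - 2.0
  - - 12.0
    - 0.0
noise:
- id: sigma1
  distribution: normal
  refresh: 1
  target: term
  mu: 1.0
  sigma: 0.1
- id: sigma2
  distribution: normal
  refresh: 1
  target: term
  mu: 1.0
  sigma: 0.1
- id: sigma3
  distribution: normal
  refresh: 1
  target: term
  mu: 1.0
  sigma: 0.1
- id: sigma4
  distribution: normal
  refresh: 1
  target: term
  mu: 1.0
  sigma: 0.1
- id: ligand_noise
  distribution: normal
  refresh: 1
  target: variable
  mu: 1.0
  sigma: 0.1
  variable: L
max_delay: 4.0
metadata:
  scenario: delays_and_noise
  tau1: 3.0
  tau2: 4.0
  g: -4.0
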
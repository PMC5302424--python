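# Xylanase activity from solid-state fermentation on wheat bran: five coded
# variables on a central-composite design with axial level alpha = 2.378,
# maximized over [-2.378, 2.378]^5.  Natural limits are stored normalized
# (smaller natural value with the smaller coded level), which keeps the
# design center at coded zero.
name: xylanase
goal: maximize
objective:
  kind: quadratic
  response_name: xylanase activity
  response_units: IU/gds
  intercept: 525.67
  linear: [21.55, 25.73, 34.15, 18.05, 23.95]
  quadratic: [-30.22, -29.74, -30.53, -20.58, -29.89]
  interactions:
    - [1, 2, -17.02]
    - [1, 3, -5.11]
    - [1, 4, 9.75]
    - [1, 5, 5.07]
    - [2, 3, -9.85]
    - [2, 4, 11.33]
    - [2, 5, 1.31]
    - [3, 4, 2.09]
    - [3, 5, 6.77]
    - [4, 5, -0.57]
variables:
  - {name: substrate_concentration, units: g, natural_low: 5.2, natural_high: 14.8, coded_low: -2.378, coded_high: 2.378}
  - {name: temperature, units: degC, natural_low: 27.2, natural_high: 36.8, coded_low: -2.378, coded_high: 2.378}
  - {name: incubation_time, units: h, natural_low: 62.9, natural_high: 177.1, coded_low: -2.378, coded_high: 2.378}
  - {name: initial_moisture, units: '%', natural_low: 68.1, natural_high: 91.9, coded_low: -2.378, coded_high: 2.378}
  - {name: initial_pH, units: '', natural_low: 3.8, natural_high: 6.2, coded_low: -2.378, coded_high: 2.378}
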
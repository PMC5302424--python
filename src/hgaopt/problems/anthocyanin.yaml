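# Anthocyanin extraction yield from purple sweet potato: second-order
# response surface in four coded process variables, maximized over the
# factorial box [-1, 1]^4.
name: anthocyanin
goal: maximize
objective:
  kind: quadratic
  response_name: anthocyanin yield
  response_units: '%'
  intercept: 85.96
  linear: [-1.66, -1.81, 1.95, -8.76]
  quadratic: [-2.87, 2.25, -4.11, -8.07]
  interactions:  # 1-based variable indices: [i, j, coefficient of x_i * x_j]
    - [1, 2, -0.5]
    - [1, 3, -7.31]
    - [1, 4, -0.33]
    - [2, 3, -0.19]
    - [2, 4, -0.99]
    - [3, 4, -0.93]
variables:
  - {name: liquid_solid_ratio, units: mL/g, natural_low: 40.0, natural_high: 60.0, coded_low: -1.0, coded_high: 1.0}
  - {name: ethanol_concentration, units: '%', natural_low: 23.0, natural_high: 27.0, coded_low: -1.0, coded_high: 1.0}
  - {name: ammonium_sulphate, units: '%', natural_low: 20.0, natural_high: 22.0, coded_low: -1.0, coded_high: 1.0}
  - {name: pH, units: '', natural_low: 3.0, natural_high: 4.0, coded_low: -1.0, coded_high: 1.0}
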
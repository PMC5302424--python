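# Fatty acid methyl ester (biodiesel) yield from transesterification of
# Jatropha curcas oil over a CaO-MgO catalyst, maximized over [-1, 1]^4.
name: fame
goal: maximize
objective:
  kind: quadratic
  response_name: FAME yield
  response_units: '%'
  intercept: 85.17
  linear: [2.54, 2.29, 17.37, 7.21]
  quadratic: [0.10, -0.36, -8.49, -4.74]
  interactions:
    - [1, 2, 0.19]
    - [1, 3, -4.06]
    - [1, 4, -2.56]
    - [2, 3, 0.94]
    - [2, 4, 0.19]
    - [3, 4, -9.31]
variables:
  - {name: reaction_time, units: h, natural_low: 2.0, natural_high: 4.0, coded_low: -1.0, coded_high: 1.0}
  - {name: methanol_oil_ratio, units: 'mol/mol', natural_low: 10.0, natural_high: 40.0, coded_low: -1.0, coded_high: 1.0}
  - {name: reaction_temperature, units: degC, natural_low: 80.0, natural_high: 120.0, coded_low: -1.0, coded_high: 1.0}
  - {name: catalyst_amount, units: 'wt.%', natural_low: 2.0, natural_high: 4.0, coded_low: -1.0, coded_high: 1.0}
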
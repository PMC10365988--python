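# CO2-equivalence conversion factors (kg CO2e per kg gas), IPCC AR6 vintage.
# GWP100 is the de facto reporting standard; GTP100 emphasises long-term
# temperature response (down-weighting short-lived CH4); GWP20 emphasises
# near-term forcing (up-weighting CH4).  Edit or extend for other vintages.
version: AR6
metrics:
  GWP100:
    ch4_factor: 27
    n2o_factor: 273
  GTP100:
    ch4_factor: 11
    n2o_factor: 297
  GWP20:
    ch4_factor: 86
    n2o_factor: 268
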
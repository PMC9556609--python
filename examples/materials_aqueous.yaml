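energy_pair:
  e_low: 50.0
  e_high: 200.0
materials:
- name: eosin
  mu_low: 0.29
  mu_high: 0.141
  units: 1/cm
  stock_concentration_mg_per_ml: 40.0
  provenance: regression endpoint (example)
- name: iomeprol
  mu_low: 0.433
  mu_high: 0.152
  units: 1/cm
  stock_concentration_mg_per_ml: 20.0
  provenance: regression endpoint (example)
- name: water
  mu_low: 0.2269
  mu_high: 0.137
  units: 1/cm
  stock_concentration_mg_per_ml: null
  provenance: config constant
- name: sodium_chloride
  mu_low: 0.306
  mu_high: 0.151
  units: 1/cm
  stock_concentration_mg_per_ml: 200.0
  provenance: regression endpoint (example)
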
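energy_pair:
  e_low: 50.0
  e_high: 200.0
materials:
- name: fibrin_platelets
  mu_low: 0.2892
  mu_high: 0.1847
  units: 1/cm
  stock_concentration_mg_per_ml: null
  provenance: chemical assumption (example)
- name: RBC
  mu_low: 0.0731
  mu_high: 0.045
  units: 1/cm
  stock_concentration_mg_per_ml: null
  provenance: chemical assumption (example)
- name: WBC
  mu_low: 0.223
  mu_high: 0.1361
  units: 1/cm
  stock_concentration_mg_per_ml: null
  provenance: config constant
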
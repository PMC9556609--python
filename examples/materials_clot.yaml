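energy_pair:
  e_low: 50.0
  e_high: 200.0
materials:
- name: fibrin_platelets
  mu_low: 0.2693
  mu_high: 0.1636
  units: 1/cm
  stock_concentration_mg_per_ml: null
  provenance: calibrated example value
- name: RBC
  mu_low: 0.2769
  mu_high: 0.1703
  units: 1/cm
  stock_concentration_mg_per_ml: null
  provenance: calibrated example value
- name: WBC
  mu_low: 0.223
  mu_high: 0.1361
  units: 1/cm
  stock_concentration_mg_per_ml: null
  provenance: config constant
- name: formalin
  mu_low: 0.2293
  mu_high: 0.1383
  units: 1/cm
  stock_concentration_mg_per_ml: null
  provenance: config constant
- name: iomeprol
  mu_low: 0.433
  mu_high: 0.152
  units: 1/cm
  stock_concentration_mg_per_ml: 20.0
  provenance: regression endpoint (example)
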
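reference_arm: eve_exe
annual_discount_rate: 0.035
cycle_length_months: 1.0
horizon_months: 240.0
wtp_threshold: 36000.0
utilities:
  pre_progression: 0.7733
  post_progression: 0.4964
scenario_flags:
  half_cycle_correction: false
  discount_from_start: false
  apply_rdi: false
  fixed_post_progression_survival_months: null
survival:
  pfs:
    family: weibull
    params:
      shape: 1.3
      scale: 10.34
  os:
    family: weibull
    params:
      shape: 1.2
      scale: 42.07
arms:
- id: eve_exe
  label: everolimus + exemestane
  pre_progression_cycle_costs:
    drug_acquisition: 2447.75
    administration: 0.0
    pretreatment: 0.0
    lab_tests: 42.82
    monitoring: 52.34
    prophylaxis: 0.0
  relative_dose_intensity: 0.86
  post_progression_cycle_cost: 1057.41
  end_of_life_cost: 823.6
  adverse_events:
  - label: grade 3/4 adverse events (EVE+EXE, aggregate)
    frequency: 1.0
    unit_cost: 62.0
    disutility: 0.029
- id: bev_pacl
  label: bevacizumab + paclitaxel
  pre_progression_cycle_costs:
    drug_acquisition: 3806.42
    administration: 260.89
    pretreatment: 82.58
    lab_tests: 52.41
    monitoring: 52.34
    prophylaxis: 274.72
  relative_dose_intensity: 0.86
  post_progression_cycle_cost: 1057.41
  end_of_life_cost: 823.6
  adverse_events:
  - label: grade 3/4 adverse events (BEV+PACL, aggregate)
    frequency: 1.0
    unit_cost: 5.14
    disutility: 0.027
  hazard_ratios:
    pfs:
    - label: indirect comparison (synthetic)
      hr: 1.45
    os:
    - label: indirect comparison (synthetic)
      hr: 0.98
- id: bev_cape
  label: bevacizumab + capecitabine
  pre_progression_cycle_costs:
    drug_acquisition: 3510.97
    administration: 115.95
    pretreatment: 36.69
    lab_tests: 48.25
    monitoring: 52.34
    prophylaxis: 416.77
  relative_dose_intensity: 0.86
  post_progression_cycle_cost: 1057.41
  end_of_life_cost: 823.6
  adverse_events:
  - label: grade 3/4 adverse events (BEV+CAPE, aggregate)
    frequency: 1.0
    unit_cost: 1.0
    disutility: 0.0031
  hazard_ratios:
    pfs:
    - label: indirect comparison (synthetic)
      hr: 1.7
    os:
    - label: indirect comparison (synthetic)
      hr: 0.97
one_way_sa:
- path: utilities.pre_progression
  low: 0.36
  high: 0.9
- path: utilities.post_progression
  low: 0.2
  high: 0.97
- path: arms.bev_pacl.post_progression_cycle_cost
  low: 500.0
  high: 1500.0
- path: arms.eve_exe.pre_progression_cycle_costs.drug_acquisition
  low: 2000.0
  high: 5000.0
- path: arms.bev_pacl.hr_pfs
  low: 0.725
  high: 2.175
- path: survival.os.hazard_scale
  low: 0.5
  high: 1.5
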
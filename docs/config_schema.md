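# Model configuration schema

A model configuration is a single YAML document. The packaged example
lives at `src/pscea/data/base_case_fixture.yaml` and loads via
`pscea.load_config(path)` (or `pscea.base_case_fixture()` for the same
content built programmatically).

```yaml
reference_arm: eve_exe        # required unless one arm carries `reference: true`
annual_discount_rate: 0.035   # fraction in [0, 1); default 0.035
cycle_length_months: 1        # default 1
horizon_months: 240           # default 180; must cover >= 1 cycle
wtp_threshold: 36000          # euros per QALY, > 0; default 36000

utilities:                    # required; annual weights in [0, 1]
  pre_progression: 0.7733     # base case requires post <= pre
  post_progression: 0.4964

scenario_flags:               # optional, all default to off
  half_cycle_correction: false
  discount_from_start: false  # continuous discounting from time zero
  apply_rdi: false            # scale drug cost by relative dose intensity
  fixed_post_progression_survival_months: null   # number of months, or null

survival:                     # reference-arm curves; required
  pfs:                        # exactly one of `params` or `ipd` per endpoint
    family: weibull           # exponential | weibull | gompertz | loglogistic
    params: {shape: 1.3, scale: 10.34}
  os:
    ipd: path/to/os_ipd.csv   # two columns: time_months,event (header required)
    family: best              # a family name, `best` (AIC selection),
                              # or `exponential_endpoint`
    landmark_months: 18       # only for exponential_endpoint (optional)
    # hazard_scale: 1.0       # PH multiplier, the +-50% sensitivity lever

arms:                         # one entry per arm; ids must be unique
  - id: eve_exe
    label: everolimus + exemestane
    pre_progression_cycle_costs:          # euros per cycle, >= 0;
      drug_acquisition: 2447.75           # omitted components default to 0
      administration: 0
      pretreatment: 0
      lab_tests: 42.82
      monitoring: 52.34
      prophylaxis: 0
    relative_dose_intensity: 0.86         # fraction in (0, 1]; default 0.86
    post_progression_cycle_cost: 1057.41  # default 1057.41
    end_of_life_cost: 823.60              # one-off at death; default 823.60
    adverse_events:                       # optional; one-off at entry
      - {label: "grade 3/4 (aggregate)", frequency: 1.0,
         unit_cost: 62.0, disutility: 0.029}   # decrement magnitude >= 0
    # reference: true                     # alternative to top-level key
  - id: bev_pacl
    pre_progression_cycle_costs: {drug_acquisition: 3806.42, administration: 260.89,
                                  pretreatment: 82.58, lab_tests: 52.41,
                                  monitoring: 52.34, prophylaxis: 274.72}
    hazard_ratios:                        # vs the reference arm; omitted = 1.0
      pfs: 1.45                           # scalar, or a chain:
      os:                                 # combined HR = product of links
        - {label: "indirect comparison", hr: 0.98}

one_way_sa:                   # optional; consumed by `cea owsa` / one_way_sa()
  - {path: utilities.pre_progression, low: 0.36, high: 0.90}
  - {path: arms.bev_pacl.hr_pfs, low: 0.725, high: 2.175}
```

## Parameter paths

One-way and probabilistic sensitivity analyses address scalars inside a
loaded configuration with dotted paths:

| path | meaning |
|---|---|
| `annual_discount_rate`, `horizon_months`, `wtp_threshold` | top-level scalars |
| `utilities.pre_progression`, `utilities.post_progression` | utility weights |
| `survival.<pfs\|os>.hazard_scale` | PH multiplier on the reference curve |
| `arms.<id>.pre_progression_cycle_costs.<component>` | one cost component |
| `arms.<id>.post_progression_cycle_cost` | monthly post-progression cost |
| `arms.<id>.end_of_life_cost` | terminal-care one-off |
| `arms.<id>.relative_dose_intensity` | RDI fraction |
| `arms.<id>.hr_pfs`, `arms.<id>.hr_os` | combined hazard ratio (setting replaces the chain with a single link) |
| `arms.<id>.ae_total_cost`, `arms.<id>.ae_total_disutility` | expected AE totals (setting rescales the profile proportionally) |

## Result files

`write_results` produces a long CSV with columns
`block,name,outcome,value`: one `arm` row per (arm, outcome) — the five
cost components plus totals, QALYs and life years (discounted and
undiscounted) — followed by one `incremental` block per comparison
(`delta_cost`, `delta_effect`, `icer`, `label`, `quadrant`). Euros are
written with 2 decimals, QALYs/life years with 3.
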
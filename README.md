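# pscea — partitioned-survival cost-effectiveness analysis

`pscea` is a decision-analytic modelling library for two-way oncology
treatment comparisons, built around the three-state partitioned survival
model used in health-technology assessments of second-line therapy for
HR+/HER2− metastatic breast cancer (everolimus + exemestane vs
bevacizumab-based chemotherapy, from a third-party-payer perspective,
costs in euros). It is written for health economists and methodologists
who want the whole pipeline — survival extrapolation, cohort trace,
costing, incremental analysis, sensitivity analysis — as tested,
composable Python functions rather than a spreadsheet.

## The model

**States and trace.** A cohort enters *pre-progression* and moves
through *post-progression* into *death* (absorbing) on monthly cycles.
No transition matrix is specified; occupancy is read directly off the
progression-free survival (PFS) and overall survival (OS) curves
("partitioned survival"):

    pre(t)  = PFS(t)          dead(t) = 1 − OS(t)
    post(t) = OS(t) − PFS(t)

**Survival extrapolation.** Reference-arm PFS and OS are parametric
curves — exponential, Weibull `S(t) = exp(−(t/λ)^k)`, Gompertz or
log-logistic — either declared or fitted to right-censored pseudo
individual-patient data by maximum likelihood, with AIC model selection.
Comparator curves come from hazard-ratio chains under proportional
hazards, `S_new(t) = S_ref(t)^HR`, with PFS clamped at or below OS.

**Economics.** Per cycle, occupancy accrues per-cycle costs (drug
acquisition — optionally scaled by relative dose intensity —
administration, background care, post-progression care), one-off costs
(adverse-event management at entry, terminal care at death) and QALYs
(annual utilities 0.7733 pre- / 0.4964 post-progression, weighted by
cycle length). Costs and outcomes beyond one year are discounted at
3.5%/year. Comparisons report Δcost, ΔQALY/ΔLY, the ICER
`ΔC/ΔE`, net monetary benefit `NMB = WTP·E − C` at a 36,000 €/QALY
threshold, and a dominance label (dominant / dominated / cost-effective
/ "less effective and cheaper").

**Uncertainty.** One-way sensitivity analysis reruns the pipeline over
low/high parameter ranges; the probabilistic sensitivity analysis
samples costs (gamma), utilities (beta) and hazard ratios (lognormal)
by moment matching, propagates 1,000 Monte-Carlo draws and summarises
them as cost-effectiveness acceptability curves (CEAC).

The packaged fixture (`pscea.base_case_fixture()`) carries the published
cost inputs, utilities, discount rate and threshold exactly; its
survival parameters and hazard ratios are **synthetic placeholders**
(the source prints neither), so fixture-level totals are illustrative
while the worked example below is exact.

## Worked example

Feeding the published per-arm component values through the
incremental-analysis stage (`examples/04_worked_incremental.py`):

```
   eve_exe: total cost  55,021.51 €, QALYs 1.724, LYs disc. 3.043, NMB at 36,000 €/QALY      7,042 €
  bev_pacl: total cost  67,979.41 €, QALYs 1.689, LYs disc. 3.081, NMB at 36,000 €/QALY     -7,175 €
  bev_cape: total cost  62,821.77 €, QALYs 1.720, LYs disc. 3.140, NMB at 36,000 €/QALY       -902 €

vs bev_pacl [QALY]: ΔC -12,957.90 €, ΔE +0.035 -> Dominant
vs bev_pacl [LY]: ΔC -12,957.90 €, ΔE -0.038 -> Less effective
vs bev_cape [QALY]: ΔC -7,800.26 €, ΔE +0.004 -> Dominant
vs bev_cape [LY]: ΔC -7,800.26 €, ΔE -0.097 -> Less effective
```

Reading: everolimus + exemestane costs ~12,958 € less and yields 0.035
more QALYs than bevacizumab + paclitaxel, so it *dominates* on the QALY
scale; on the (discounted) life-year scale it is cheaper but slightly
less effective, hence the "less effective" label rather than an ICER.
The full deterministic pipeline on the packaged fixture
(`examples/03_deterministic_cea.py`) reproduces this qualitative
pattern with synthetic curves.

Other capabilities, one script each, under `examples/`: survival
fitting and selection (01), the cohort trace (02), one-way sensitivity
analysis (05) and the PSA/CEAC (06). A thin CLI wraps the same
pipeline:

```bash
cea run  --config src/pscea/data/base_case_fixture.yaml --out scratch/run
cea psa  --config src/pscea/data/base_case_fixture.yaml --draws 1000 --seed 1 --out scratch/psa
cea owsa --config src/pscea/data/base_case_fixture.yaml --out scratch/owsa
cea simulate-ipd --n 500 --median 7.8 --censor 0.2 --seed 1 --out scratch/ipd.csv
```

The configuration schema is documented in `docs/config_schema.md`, the
modelling choices in `docs/methods.md`.

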
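# Methods

This note documents the model implemented by `pscea`, its assumptions,
the numerical choices made where the design was genuinely open, and
what the synthetic data generator does and does not emulate.

## Model structure

A cohort of patients with HR+/HER2− metastatic breast cancer enters a
three-state structure — pre-progression, post-progression, death
(absorbing) — on a monthly cycle. The model is a *partitioned survival*
model: state occupancy at each cycle boundary is read directly off the
progression-free survival (PFS) and overall survival (OS) functions
(`pre = PFS`, `dead = 1 − OS`, `post = OS − PFS`) rather than derived
from per-cycle transition probabilities. This is the standard
construction when a model is specified through survival curves plus
hazard ratios: it reproduces the three-state structure exactly and
avoids inventing transition matrices the inputs do not determine. A
consequence worth remembering is that exits from pre-progression to
post-progression and direct deaths from pre-progression are not
separately identified; the trace's `new_progressions` column records
the full per-cycle decline of PFS.

Cycle `t` covers the interval `(t−1, t]` months and events within a
cycle are attributed to its end (no half-cycle correction in the base
case; a standard start/end-averaging correction is available as a
scenario flag). Time is in months with 1 year = 12 months exactly.

## Survival curves and extrapolation

Four families are supported, parameterised as

| family | S(t) | parameters |
|---|---|---|
| exponential | exp(−rate·t) | rate |
| Weibull | exp(−(t/scale)^shape) | shape, scale |
| Gompertz | exp(−(rate/shape)(e^{shape·t}−1)) | shape > 0, rate |
| log-logistic | 1/(1+(t/scale)^shape) | shape, scale |

The Gompertz shape is restricted to be strictly positive: a negative
shape implies a plateau (cure fraction), which is inconsistent with a
lifetime-horizon model of metastatic disease, so such fits are rejected
by construction.

Fitting maximises the right-censored log-likelihood (events contribute
log f, censored observations log S) over log-parameters with L-BFGS-B
(Nelder–Mead fallback), from fixed method-of-moments-style starting
values: the exponential MLE has a closed form (events / total follow-up)
and seeds the Weibull and Gompertz starts; the log-logistic starts at
the median event time with shape 1.5. Fits are therefore deterministic
given the data. Model selection minimises AIC with ties broken by fewer
parameters, then by declared family order. The fitting code is
implemented in-package (on `scipy.optimize`) because no single installed
library covers all four families; the test suite cross-checks the
exponential, Weibull and log-logistic fits against `lifelines` on the
same data.

Two exponential fitting modes are exposed, reflecting the two
conventional readings of "exponential" extrapolation: an ML fit to the
full follow-up ("curve") and a rate matched to a single Kaplan–Meier
landmark probability, `rate = −ln S(t*)/t*` ("endpoint", landmark
defaulting to the last time the Kaplan–Meier estimate is positive).

Comparator curves are obtained from the reference arm's curves by
proportional hazards, `S_new = S_ref^HR`, where HR is the product of an
ordered chain of hazard ratios (an indirect treatment comparison).
Exponential, Weibull and Gompertz are closed under this transform and
return closed-form curves; the log-logistic (and any composite curve)
returns a power wrapper. Because PFS and OS chains are independent
inputs, the transformed curves can cross; PFS is therefore clamped
point-wise at `min(PFS, OS)` before the trace is built, and the trace
itself raises if it ever sees PFS above OS.

## Discounting

Costs and outcomes beyond one year are discounted at an annual rate
(default 3.5%). The source wording ("beyond one year") is ambiguous
between stepwise-annual and continuous discounting, so both are
implemented and neither is claimed to be the authors' choice:

* **annual step (default):** factor 1 for months ≤ 12, then
  `(1+r)^(−floor(month/12))` — the first model year is undiscounted and
  month 24 carries `(1.035)^−2`;
* **from start (`discount_from_start`):** `(1+r)^(−month/12)`
  continuously from time zero, the more common textbook convention.

Setting the rate to zero makes discounted and undiscounted totals
bit-identical (the undiscounted accumulators use the same reduction).

## Costing and QALY accrual

Five cost components per arm mirror the published base-case table:

1. **treatment & administration** — per-cycle drug acquisition
   (optionally scaled by the relative dose intensity, RDI 0.86 for all
   regimens; RDI applies to drug cost only, since dose reductions cut
   drug consumed, not infusion visits) plus administration, weighted by
   pre-progression occupancy;
2. **adverse events** — one-off at model entry (cycle 0, undiscounted):
   expected cost `Σ frequency·unit_cost`; the matching QALY decrement
   `Σ frequency·disutility` is subtracted from pre-progression QALYs.
   Entry timing is the simplest reading of "one-off" and is numerically
   immaterial at the published magnitudes (≤ 62 €);
3. **pre-progression background** — pretreatment, lab tests, monitoring
   and prophylaxis per cycle, weighted by pre-progression occupancy;
4. **post-progression background** — a single monthly figure
   (1,057.41 € in the fixture), derivable from duration-weighted
   treatment-line strategies via `post_progression_cycle_cost()`
   (50/50 strategy weighting in the source); the base case uses the
   published aggregate directly;
5. **terminal care** — 823.60 € attached to the cycle of death via the
   per-cycle death increment and discounted at that cycle, which
   reproduces the pattern of the published discounted terminal-care
   entries (≈ 735–738 €).

Drug reimbursement rules are exposed as `reimbursed_price`: hospital
price +5% mark-up (intravenous hospital drugs), −5% rebate (high-cost
outpatient drugs), or the listed social-security price (retail). All
prices are stored exactly as printed, without inflation adjustment.

Utilities are annual weights (0.7733 pre-, 0.4964 post-progression,
age-adjusted standard-gamble values), so one cycle contributes
`occupancy · u · cycle_length/12` QALYs. Life years use weight 1. The
base case requires `u_post ≤ u_pre`; the constructor itself only
enforces the [0, 1] range because published one-way ranges deliberately
push the pre-progression utility (down to 0.36) below the
post-progression one, and the one-way analysis must be able to follow
them — its reruns skip base-case re-validation, while PSA draws that
violate an invariant are recorded as failures and excluded.

A *fixed post-progression survival* scenario replaces the OS curve:
every cohort fraction leaving pre-progression dies exactly `k` months
after progression (`k = 0` empties the post-progression state).

The default horizon is 180 months; the packaged fixture uses 240 months
because under its placeholder curves that leaves under 0.1% of the
cohort alive, which is the threshold of the built-in truncation warning
for a "lifetime" model.

## Incremental analysis

For intervention `a` vs comparator `b`: `ΔC = C_a − C_b`,
`ΔE = E_a − E_b` on the QALY or discounted life-year scale, ICER
`ΔC/ΔE` (defined whenever ΔE ≠ 0), and NMB `WTP·E − C` at the
36,000 €/QALY willingness-to-pay (3× Greek GDP per capita, per WHO
guidance). Quadrants of the cost-effectiveness plane map to labels:
SE → dominant (strict: cheaper *and* more effective), NW → dominated,
NE → cost-effective iff ICER ≤ WTP, SW → "less effective and cheaper",
where the SW ICER (savings per unit of effect forgone) is reported
alongside the label rather than discarded. On the axes (ΔE = 0 or
ΔC = 0) the quadrant is undefined and the label falls back to the
net-benefit ordering. Extended dominance does not arise: all
comparisons are two-way.

## Sensitivity analysis

**One-way.** Each parameter path is set to its low/high value and the
full pipeline is rerun, everything else at base case; results are
reported as ICER-or-label per comparator, the layout of a published
sensitivity table. ±50% variations of survival are implemented as
multiplicative variation of the comparator's hazard ratio, or of a
`hazard_scale` multiplier on the reference arm's own curve — the only
survival levers a curves-plus-HRs model has. The published sensitivity
ICERs are not reproducible targets because they also depend on
unpublished survival parameters.

**Probabilistic.** Every cost, utility and hazard ratio is sampled
independently (no correlation structure is published): beta for
utilities, gamma for costs, lognormal for hazard ratios, each
moment-matched to its central value and dispersion. The source reports
no standard errors, so the defaults — CV 20% for costs and hazard
ratios, SE 0.05 for utilities — are conventional and overridable per
parameter; consequently the published CEAC percentages (95.5%/87.2% at
36,000 €/QALY) are not reproducible targets either. One thousand draws
rerun the deterministic pipeline per draw from a single seeded
generator (fully reproducible); a zero dispersion degenerates a
parameter to its central value, making a zero-dispersion PSA reproduce
the deterministic run draw for draw. Draws violating a model invariant
are excluded and counted; the run fails if more than 1% are lost. The
CEAC reports, per willingness-to-pay, the fraction of draws with
strictly positive incremental net benefit (ties count as not
cost-effective); the "bootstrapping" of the source is this Monte-Carlo
parameter resampling — there is no patient-level sample to resample.

## Synthetic data

The reference arm's trial data are not publicly deposited, so
`pscea.synthetic` generates pseudo individual-patient data from declared
parametric truths by inverse-CDF sampling. Censoring combines an
administrative cutoff with non-informative random dropout: one
independent Uniform(0, c_max) censoring time per subject, with c_max
calibrated against the truth curve so the expected censored fraction
hits the requested value (censoring times must not depend on the
subject's own event time, or maximum-likelihood fits would be biased).
Paired PFS/OS tables enforce progression ≤ death per subject by taking
component-wise minima of the two draws and share one censoring time per
subject across endpoints.

The packaged fixture reproduces the published per-cycle cost inputs,
utilities, discount rate and threshold exactly. Its survival parameters
(Weibull PFS median 7.8 months, shape 1.3; OS median 31 months, shape
1.2) and hazard-ratio chains (PFS/OS 1.45/0.98 and 1.70/0.97 for the
two comparators) are placeholders chosen once to be loosely evocative of
the clinical setting — comparators with worse PFS but marginally better
OS — and are **not** published values. Passing tests on this fixture
therefore demonstrate the pipeline's arithmetic and its qualitative
behaviour (dominance on QALYs, "less effective" on life years), not the
published totals; those are anchored instead by the worked example that
feeds the published per-arm components directly into the incremental
stage. What the generator does not emulate: dependence between
progression and death beyond the shared-minimum coupling, time-varying
hazard ratios, covariates, or recruitment patterns.

## Numerical choices and limitations

* Currency arithmetic is floating point; printed outputs round euros
  half-up to whole euros, result files keep 2 decimals for euros and 3
  for QALYs/LYs.
* Component totals are `math.fsum` reductions, so "total = sum of
  components" holds to accumulation precision.
* Curve evaluations clip into [0, 1] and guard Gompertz overflow at
  long horizons.
* Optimiser bounds on log-parameters keep fits finite; non-convergence
  raises an explicit error rather than returning a partial fit.
* Model-selection AIC ties are broken deterministically (fewer
  parameters, then exponential < Weibull < Gompertz < log-logistic).
* Problem sizes used by the test suite and the acceptance script —
  5,000 subjects for parameter recovery, 10,000 for empirical-median
  and Kaplan–Meier convergence checks, 1,000 PSA draws, 1,000 random
  curve pairs, 10,000 ICER/NMB pairs — were chosen so sampling error is
  far inside the asserted tolerances.
* Out of scope: spline/flexible parametric models, covariate-adjusted
  survival, microsimulation, tunnel states, background mortality,
  efficiency frontiers across more than two arms, value-of-information
  analysis, and reconstruction of published Kaplan–Meier curves.
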
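"""Simulate censored pseudo-IPD and pick the best-fitting survival family.

Draws 2,000 subjects from a known Weibull truth with ~20% random
censoring, fits all four parametric families under right-censoring, and
selects the minimum-AIC model. The fitted shape/scale should land close
to the truth (1.4, 11.0) and Weibull should win the AIC race.
"""
from pscea import IpdSimSpec, fit_all_families, select_best_fit, simulate_ipd

truth_shape, truth_scale = 1.4, 11.0
ipd = simulate_ipd(IpdSimSpec(
    n=2000, family="weibull", params=(truth_shape, truth_scale),
    random_censor_frac=0.2, seed=20240101))
print(f"simulated {ipd.n} subjects: {ipd.n_events} events, "
      f"{ipd.n_censored} censored")

fits = fit_all_families(ipd)
for fit in fits:
    params = ", ".join(f"{k}={v:.3f}" for k, v in fit.curve.param_dict.items())
    print(f"{fit.curve.family:>12}: log-lik {fit.log_likelihood:10.1f}  "
          f"AIC {fit.aic:10.1f}  ({params})")

best = select_best_fit(fits)
print(f"\nbest fit by AIC: {best.curve.family} "
      f"(truth was weibull shape={truth_shape}, scale={truth_scale}); "
      f"fitted median {best.curve.median():.2f} months")
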
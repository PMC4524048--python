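"""Run the deterministic base case on the packaged three-arm fixture.

The fixture's cost inputs, utilities, 3.5% discount rate and
36,000 EUR/QALY threshold are the published values; its survival curves
and hazard ratios are synthetic placeholders, so the totals differ from
the published ones while reproducing the qualitative pattern (the
reference regimen saves money and gains QALYs but loses a little
life-time against both comparators).
"""
from pscea import format_incremental, run_model, base_case_fixture

config = base_case_fixture()
run = run_model(config)

print(f"{'arm':>10} {'total cost':>12} {'QALYs':>7} {'LYs (disc.)':>12}")
for arm_id, res in run.arm_results.items():
    print(f"{arm_id:>10} {res.total_cost:>10,.0f} € {res.total_qalys:>7.3f} "
          f"{res.ly_total_discounted:>12.3f}")

print()
for inc in run.incrementals:
    icer = "-" if inc.icer is None else f"{inc.icer:,.0f} €"
    print(f"{inc.intervention} vs {inc.comparator} [{inc.effect_measure}]: "
          f"ΔC {inc.delta_cost:+,.0f} €, ΔE {inc.delta_effect:+.3f}, "
          f"ICER {icer} -> {format_incremental(inc)}")
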
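"""Push the published per-arm component values through the incremental stage.

The published evaluation prints each arm's discounted component costs,
QALYs and life years; feeding those components to the incremental
analysis must reproduce the printed totals (55,022 / 67,980 /
62,822 EUR), the savings (12,958 and 7,800 EUR), the QALY gains
(+0.035, +0.004) and the dominance labels (dominant on QALYs, "less
effective" but cheaper on life years vs the taxane comparator).
"""
from pscea import format_incremental, incremental, nmb, published_base_case

results = published_base_case()
for arm_id, res in results.items():
    print(f"{arm_id:>10}: total cost {res.total_cost:>10,.2f} €, "
          f"QALYs {res.total_qalys:.3f}, LYs disc. {res.ly_total_discounted:.3f}, "
          f"NMB at 36,000 €/QALY {nmb(res, 36000):>10,.0f} €")

print()
eve = results["eve_exe"]
for comparator in ("bev_pacl", "bev_cape"):
    for measure in ("QALY", "LY"):
        inc = incremental(eve, results[comparator], measure)
        print(f"vs {comparator} [{measure}]: ΔC {inc.delta_cost:+,.2f} €, "
              f"ΔE {inc.delta_effect:+.3f} -> {format_incremental(inc)}")
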
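"""Incremental cost-effectiveness analysis and deterministic pipeline.

``run_model`` executes the full deterministic pipeline for a
configuration: resolve the reference arm's PFS/OS curves (declared
parameters or fits to pseudo-IPD), derive each comparator's curves via
its hazard-ratio chains under proportional hazards, clamp PFS at or
below OS, build the partitioned-survival trace, accrue costs and
(quality-adjusted) life years, and compute the incremental comparison
of the reference arm against every comparator on both the QALY and the
(discounted) life-year scale.

Quadrants on the cost-effectiveness plane (x = incremental effect,
y = incremental cost, reference minus comparator):

* SE (cheaper, more effective)  -> dominant
* NW (costlier, less effective) -> dominated
* NE (costlier, more effective) -> ICER vs the willingness-to-pay
* SW (cheaper, less effective)  -> "less effective and cheaper"; the SW
  ICER (savings per unit of effect forgone) is reported alongside the
  label rather than discarded.
"""
from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .config import ModelConfig, OwsaSpec, set_parameter
from .costing import ArmResult, accrue
from .errors import TruncationWarning, ValidationError
from .io import read_ipd
from .survival import (
    FitResult,
    MinimumSurvival,
    SurvivalCurve,
    apply_hazard_ratio,
    fit_all_families,
    fit_exponential_endpoint,
    fit_parametric,
    select_best_fit,
)
from .trace import CohortTrace, build_trace

__all__ = [
    "LABELS",
    "IncrementalResult",
    "ModelRun",
    "incremental",
    "nmb",
    "format_incremental",
    "resolve_reference_curves",
    "run_model",
    "one_way_sa",
    "scenario_run",
]

LABELS = (
    "dominant",
    "dominated",
    "cost_effective",
    "not_cost_effective",
    "less_effective_and_cheaper",
)


@dataclass(frozen=True)
class IncrementalResult:
    """One two-way comparison on one effect scale."""

    intervention: str
    comparator: str
    effect_measure: str  # "QALY" or "LY"
    delta_cost: float
    delta_effect: float
    icer: float | None
    label: str
    quadrant: str | None
    wtp: float


def incremental(a: ArmResult, b: ArmResult, measure: str = "QALY",
                wtp: float = 36000.0) -> IncrementalResult:
    """Incremental analysis of intervention ``a`` against comparator ``b``.

    ``measure`` selects total QALYs or total discounted life years. The
    ICER is defined whenever the effect difference is non-zero; on the
    axes of the plane (a zero difference) the quadrant is ``None`` and
    the label falls back to the net-benefit ordering.
    """
    if measure not in ("QALY", "LY"):
        raise ValidationError(f"effect measure must be 'QALY' or 'LY', got {measure!r}")
    if (
        a.horizon_months is not None
        and b.horizon_months is not None
        and not math.isclose(a.horizon_months, b.horizon_months)
    ):
        raise ValidationError(
            f"cannot compare results over different horizons "
            f"({a.horizon_months} vs {b.horizon_months} months)"
        )
    delta_cost = a.total_cost - b.total_cost
    if measure == "QALY":
        delta_effect = a.total_qalys - b.total_qalys
    else:
        delta_effect = a.ly_total_discounted - b.ly_total_discounted

    icer = delta_cost / delta_effect if delta_effect != 0.0 else None

    if delta_effect > 0 and delta_cost < 0:
        quadrant, label = "SE", "dominant"
    elif delta_effect < 0 and delta_cost > 0:
        quadrant, label = "NW", "dominated"
    elif delta_effect > 0 and delta_cost > 0:
        quadrant = "NE"
        label = "cost_effective" if icer <= wtp else "not_cost_effective"
    elif delta_effect < 0 and delta_cost < 0:
        quadrant, label = "SW", "less_effective_and_cheaper"
    else:
        # on an axis: order by net benefit at the stated threshold
        quadrant = None
        net = wtp * delta_effect - delta_cost
        label = "cost_effective" if net > 0 else "not_cost_effective"

    return IncrementalResult(
        intervention=a.arm_id,
        comparator=b.arm_id,
        effect_measure=measure,
        delta_cost=delta_cost,
        delta_effect=delta_effect,
        icer=icer,
        label=label,
        quadrant=quadrant,
        wtp=wtp,
    )


def nmb(result: ArmResult, wtp: float) -> float:
    """Net monetary benefit: WTP * total QALYs - total cost."""
    if wtp < 0:
        raise ValidationError(f"willingness-to-pay must be >= 0, got {wtp}")
    return wtp * result.total_qalys - result.total_cost


def format_incremental(inc: IncrementalResult) -> str:
    """Presentation-style cell: a dominance label, or the rounded ICER."""
    if inc.label == "dominant":
        return "Dominant"
    if inc.label == "dominated":
        return "Dominated"
    if inc.label == "less_effective_and_cheaper":
        return "Less effective"
    if inc.icer is None:
        return inc.label
    return f"{inc.icer:,.0f}"


@dataclass
class ModelRun:
    """Everything a deterministic pipeline execution produced."""

    config: ModelConfig
    reference_curves: dict
    arm_results: dict
    incrementals: list
    traces: dict
    fits: dict = field(default_factory=dict)

    def incremental_for(self, comparator: str, measure: str = "QALY") -> IncrementalResult:
        for inc in self.incrementals:
            if inc.comparator == comparator and inc.effect_measure == measure:
                return inc
        raise ValidationError(
            f"no {measure} comparison against {comparator!r} in this run"
        )


def _resolve_endpoint(spec):
    """One endpoint's curve (and fit diagnostics, if it was fitted)."""
    fits = None
    if spec.params is not None:
        curve = spec.build_curve()
    else:
        ipd = read_ipd(spec.ipd_path, endpoint=spec.endpoint)
        if spec.family == "best":
            fits = fit_all_families(ipd)
            best = select_best_fit(fits)
        elif spec.family == "exponential_endpoint":
            best = fit_exponential_endpoint(ipd, spec.landmark_months)
            fits = [best]
        else:
            best = fit_parametric(ipd, spec.family)
            fits = [best]
        curve = best.curve
    if spec.hazard_scale != 1.0:
        curve = apply_hazard_ratio(curve, spec.hazard_scale)
    return curve, fits


def resolve_reference_curves(config: ModelConfig):
    """Resolve the reference arm's PFS and OS curves from the config."""
    curves, fits = {}, {}
    for key in ("pfs", "os"):
        curve, endpoint_fits = _resolve_endpoint(config.survival[key])
        curves[key] = curve
        if endpoint_fits is not None:
            fits[key] = endpoint_fits
    return curves, fits


def run_model(config: ModelConfig, reference_curves: dict | None = None,
              *, validate: bool = True) -> ModelRun:
    """Execute the deterministic pipeline for every arm.

    ``reference_curves`` lets callers (notably the PSA loop) reuse
    already-resolved reference curves when the survival specification is
    not being varied. ``validate=False`` skips base-case invariant
    checks, which one-way sensitivity reruns need when a published range
    deliberately violates one.
    """
    if validate:
        config.validate()
    if reference_curves is None:
        reference_curves, fits = resolve_reference_curves(config)
    else:
        fits = {}
    flags = config.scenario_flags

    arm_results, traces = {}, {}
    for arm in config.arms:
        pfs = apply_hazard_ratio(reference_curves["pfs"], arm.hr_pfs)
        os_curve = apply_hazard_ratio(reference_curves["os"], arm.hr_os)
        pfs = MinimumSurvival(pfs, os_curve)  # progression precedes death
        trace = build_trace(
            pfs,
            os_curve,
            config.horizon_months,
            fixed_pps=flags.fixed_post_progression_survival_months,
            annual_rate=config.annual_discount_rate,
            from_start=flags.discount_from_start,
            cycle_length=config.cycle_length_months,
        )
        traces[arm.arm_id] = trace
        arm_results[arm.arm_id] = accrue(
            trace,
            arm,
            config.utilities,
            apply_rdi=flags.apply_rdi,
            half_cycle_correction=flags.half_cycle_correction,
        )

    reference = arm_results[config.reference_arm_id]
    incrementals = []
    for comparator_id in config.comparator_ids:
        for measure in ("QALY", "LY"):
            incrementals.append(
                incremental(reference, arm_results[comparator_id],
                            measure, config.wtp_threshold)
            )

    return ModelRun(
        config=config,
        reference_curves=reference_curves,
        arm_results=arm_results,
        incrementals=incrementals,
        traces=traces,
        fits=fits,
    )


def one_way_sa(config: ModelConfig, specs=None, measure: str = "QALY") -> pd.DataFrame:
    """One-way sensitivity analysis.

    Re-runs the full deterministic pipeline twice per parameter (all
    else at base case) and reports, per comparator, the ICER or the
    dominance label at the low and high value.

    Only the varied leaf is re-validated, not the whole base-case
    invariant set: published one-way ranges deliberately explore values
    (a pre-progression utility below the post-progression one, say) that
    a base case would reject.
    """
    specs = list(specs) if specs is not None else list(config.owsa_specs)
    if not specs:
        raise ValidationError("no one-way sensitivity parameters supplied")
    specs = [s if isinstance(s, OwsaSpec) else OwsaSpec(*s) for s in specs]

    rows = []
    for spec in specs:
        bounds = {}
        for which, value in (("low", spec.low), ("high", spec.high)):
            varied = copy.deepcopy(config)
            set_parameter(varied, spec.path, value)
            with warnings.catch_warnings():
                # extreme survival variations routinely trip the
                # horizon-truncation check; the base case already reports it
                warnings.simplefilter("ignore", TruncationWarning)
                bounds[which] = run_model(varied, validate=False)
        for comparator in config.comparator_ids:
            row = {
                "parameter": spec.path,
                "comparator": comparator,
                "low_value": spec.low,
                "high_value": spec.high,
            }
            for which, run in bounds.items():
                inc = run.incremental_for(comparator, measure)
                row[f"{which}_icer"] = inc.icer
                row[f"{which}_label"] = inc.label
                row[f"{which}_result"] = format_incremental(inc)
            rows.append(row)
    return pd.DataFrame(rows)


_UNSET = object()


def scenario_run(
    config: ModelConfig,
    *,
    family: str | None = None,
    pfs_params: dict | None = None,
    os_params: dict | None = None,
    fixed_pps=_UNSET,
    half_cycle_correction: bool | None = None,
    apply_rdi: bool | None = None,
    discount_from_start: bool | None = None,
) -> ModelRun:
    """Deterministic pipeline under a structural variant.

    ``family`` refits both endpoints with an alternative distribution
    (requires IPD-backed survival specs). ``pfs_params`` / ``os_params``
    replace an endpoint's curve outright (e.g. an alternative PFS
    assessment supplied as ``{"family": ..., <param>: ...}``). The flag
    overrides mirror the scenario_flags block.
    """
    varied = copy.deepcopy(config)
    if family is not None:
        for key in ("pfs", "os"):
            spec = varied.survival[key]
            if spec.ipd_path is None:
                if spec.family == family:
                    continue
                raise ValidationError(
                    f"cannot refit {spec.endpoint} with family {family!r}: the "
                    "survival spec declares frozen parameters, not IPD"
                )
            spec.family = family
    for key, params in (("pfs", pfs_params), ("os", os_params)):
        if params is not None:
            params = dict(params)
            spec = varied.survival[key]
            spec.family = params.pop("family", spec.family)
            spec.params = params
            spec.ipd_path = None
    flags = varied.scenario_flags
    if fixed_pps is not _UNSET:
        flags.fixed_post_progression_survival_months = fixed_pps
    if half_cycle_correction is not None:
        flags.half_cycle_correction = half_cycle_correction
    if apply_rdi is not None:
        flags.apply_rdi = apply_rdi
    if discount_from_start is not None:
        flags.discount_from_start = discount_from_start
    varied.validate()
    return run_model(varied)
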
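"""Per-arm economic inputs and cost/QALY accrual over a cohort trace.

Costs are in euros at the prices printed in the source tariffs (no
inflation adjustment); utilities are annual weights, so one cycle in a
state contributes ``occupancy * utility * cycle_length/12`` QALYs.

Component bookkeeping mirrors the base-case results table of the
evaluation this package reimplements, with five cost components per arm:
treatment & administration, adverse events (one-off), pre-progression
background, post-progression background, and terminal care.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .survival import HazardRatioChain
from .trace import CohortTrace

__all__ = [
    "COST_COMPONENTS",
    "PRICE_CHANNELS",
    "AdverseEvent",
    "UtilitySet",
    "StrategyLine",
    "ArmConfig",
    "ArmResult",
    "reimbursed_price",
    "cycle_cost_pre",
    "ae_one_off",
    "post_progression_cycle_cost",
    "accrue",
]

#: Pre-progression per-cycle cost components, in presentation order.
COST_COMPONENTS = (
    "drug_acquisition",
    "administration",
    "pretreatment",
    "lab_tests",
    "monitoring",
    "prophylaxis",
)

#: Reimbursement channels: hospital price +5% mark-up for in-hospital IV
#: drugs, -5% rebate for high-cost outpatient drugs, and retail drugs
#: reimbursed at the listed social-security price.
PRICE_CHANNELS = {"hospital_markup": 1.05, "outpatient_rebate": 0.95, "retail": 1.0}


def reimbursed_price(price: float, channel: str) -> float:
    """Reimbursed price from a list price under the stated channel rules."""
    if price <= 0:
        raise ValidationError(f"list price must be positive, got {price}")
    try:
        factor = PRICE_CHANNELS[channel]
    except KeyError:
        raise ValidationError(
            f"unknown price channel {channel!r}; expected one of "
            f"{sorted(PRICE_CHANNELS)}"
        ) from None
    return price * factor


@dataclass(frozen=True)
class AdverseEvent:
    """One grade-3/4 adverse event line: frequency, management cost, disutility.

    ``disutility`` is stored as a positive QALY decrement magnitude.
    """

    label: str
    frequency: float
    unit_cost: float
    disutility: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.frequency <= 1.0:
            raise ValidationError(
                f"AE {self.label!r}: frequency must lie in [0, 1], got {self.frequency}"
            )
        if self.unit_cost < 0:
            raise ValidationError(
                f"AE {self.label!r}: unit cost must be >= 0, got {self.unit_cost}"
            )
        if self.disutility < 0:
            raise ValidationError(
                f"AE {self.label!r}: disutility is a positive decrement, "
                f"got {self.disutility}"
            )


@dataclass(frozen=True)
class UtilitySet:
    """Annual health-state utilities.

    Each weight must lie in [0, 1]. The base-case ordering invariant
    (post-progression utility at or below pre-progression) is enforced
    at configuration validation, not here, because published one-way
    sensitivity ranges deliberately push the pre-progression utility
    below the post-progression one.
    """

    u_pre: float
    u_post: float

    def __post_init__(self):
        for name, value in (("u_pre", self.u_pre), ("u_post", self.u_post)):
            if not 0.0 <= value <= 1.0:
                raise ValidationError(
                    f"utility {name} must lie in [0, 1], got {value}"
                )


@dataclass(frozen=True)
class StrategyLine:
    """One treatment line within a post-progression strategy."""

    label: str
    monthly_cost: float
    duration_months: float

    def __post_init__(self):
        if self.duration_months <= 0:
            raise ValidationError(
                f"line {self.label!r}: duration must be positive, "
                f"got {self.duration_months}"
            )
        if self.monthly_cost < 0:
            raise ValidationError(
                f"line {self.label!r}: monthly cost must be >= 0, "
                f"got {self.monthly_cost}"
            )


def post_progression_cycle_cost(strategies) -> float:
    """Average monthly post-progression cost across weighted strategies.

    ``strategies`` is a sequence of ``(weight, [StrategyLine, ...])``.
    Each strategy's monthly cost is the duration-weighted mean over its
    treatment lines; the overall figure is the weight-averaged mean
    across strategies (weights must sum to 1).
    """
    strategies = list(strategies)
    if not strategies:
        raise ValidationError("at least one post-progression strategy is required")
    total_weight = math.fsum(w for w, _ in strategies)
    if abs(total_weight - 1.0) > 1e-9:
        raise ValidationError(
            f"strategy weights must sum to 1, got {total_weight!r}"
        )
    overall = 0.0
    for weight, lines in strategies:
        lines = list(lines)
        if not lines:
            raise ValidationError("each strategy needs at least one treatment line")
        total_duration = math.fsum(line.duration_months for line in lines)
        mean_monthly = (
            math.fsum(line.monthly_cost * line.duration_months for line in lines)
            / total_duration
        )
        overall += weight * mean_monthly
    return overall


@dataclass
class ArmConfig:
    """All per-arm economic inputs.

    ``hr_pfs`` / ``hr_os`` are hazard-ratio chains vs the reference arm
    (identity chains on the reference arm itself).
    """

    arm_id: str
    pre_progression_cycle_costs: dict
    label: str = ""
    relative_dose_intensity: float = 0.86
    post_progression_cycle_cost: float = 1057.41
    end_of_life_cost: float = 823.60
    ae_profile: list = field(default_factory=list)
    hr_pfs: HazardRatioChain = field(default_factory=HazardRatioChain.identity)
    hr_os: HazardRatioChain = field(default_factory=HazardRatioChain.identity)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not self.arm_id:
            raise ValidationError("arm_id must be a non-empty identifier")
        unknown = set(self.pre_progression_cycle_costs) - set(COST_COMPONENTS)
        if unknown:
            raise ValidationError(
                f"arm {self.arm_id!r}: unknown cost components {sorted(unknown)}; "
                f"expected {COST_COMPONENTS}"
            )
        costs = {c: float(self.pre_progression_cycle_costs.get(c, 0.0))
                 for c in COST_COMPONENTS}
        for name, value in costs.items():
            if value < 0:
                raise ValidationError(
                    f"arm {self.arm_id!r}: cost {name!r} must be >= 0, got {value}"
                )
        self.pre_progression_cycle_costs = costs
        if not 0.0 < self.relative_dose_intensity <= 1.0:
            raise ValidationError(
                f"arm {self.arm_id!r}: relative dose intensity must lie in (0, 1], "
                f"got {self.relative_dose_intensity}"
            )
        if self.post_progression_cycle_cost < 0:
            raise ValidationError(
                f"arm {self.arm_id!r}: post-progression cycle cost must be >= 0"
            )
        if self.end_of_life_cost < 0:
            raise ValidationError(f"arm {self.arm_id!r}: end-of-life cost must be >= 0")


def cycle_cost_pre(arm: ArmConfig, apply_rdi: bool = False) -> float:
    """Total pre-progression cost per cycle.

    The relative dose intensity scales drug acquisition only: a dose
    reduction cuts drug consumed, not infusion visits or monitoring.
    """
    c = arm.pre_progression_cycle_costs
    rdi = arm.relative_dose_intensity if apply_rdi else 1.0
    return (
        c["drug_acquisition"] * rdi
        + c["administration"]
        + c["pretreatment"]
        + c["lab_tests"]
        + c["monitoring"]
        + c["prophylaxis"]
    )


def ae_one_off(arm: ArmConfig):
    """Expected one-off adverse-event cost and QALY decrement at model entry."""
    cost = math.fsum(ae.frequency * ae.unit_cost for ae in arm.ae_profile)
    decrement = math.fsum(ae.frequency * ae.disutility for ae in arm.ae_profile)
    return cost, decrement


@dataclass
class ArmResult:
    """Discounted component costs and (quality-adjusted) life years per arm.

    Totals are derived properties, so the accounting identity
    ``total = sum of components`` holds by construction.
    """

    arm_id: str
    cost_treatment_and_administration: float
    cost_adverse_events: float
    cost_pre_progression_background: float
    cost_post_progression_background: float
    cost_terminal_care: float
    qalys_pre: float
    qalys_post: float
    ly_pre_discounted: float
    ly_post_discounted: float
    ly_pre_undiscounted: float
    ly_post_undiscounted: float
    total_cost_undiscounted: float | None = None
    total_qalys_undiscounted: float | None = None
    horizon_months: float | None = None

    COST_FIELDS = (
        "cost_treatment_and_administration",
        "cost_adverse_events",
        "cost_pre_progression_background",
        "cost_post_progression_background",
        "cost_terminal_care",
    )

    @property
    def total_cost(self) -> float:
        return math.fsum(getattr(self, f) for f in self.COST_FIELDS)

    @property
    def total_qalys(self) -> float:
        return self.qalys_pre + self.qalys_post

    @property
    def ly_total_discounted(self) -> float:
        return self.ly_pre_discounted + self.ly_post_discounted

    @property
    def ly_total_undiscounted(self) -> float:
        return self.ly_pre_undiscounted + self.ly_post_undiscounted


def accrue(
    trace: CohortTrace,
    arm: ArmConfig,
    utilities: UtilitySet,
    *,
    disutility_on: bool = True,
    apply_rdi: bool = False,
    half_cycle_correction: bool = False,
) -> ArmResult:
    """Accrue costs, QALYs and life years for one arm over a trace.

    Per cycle, occupancy (end-of-cycle, or the start/end average under
    the half-cycle correction) is multiplied by per-cycle costs and
    utilities and by the cycle's discount factor. Adverse-event cost and
    disutility are one-off at model entry (cycle 0, undiscounted);
    terminal-care cost attaches to the cycle of death via new deaths.
    """
    pre, post = trace.pre, trace.post
    if half_cycle_correction:
        w_pre = 0.5 * (pre[:-1] + pre[1:])
        w_post = 0.5 * (post[:-1] + post[1:])
    else:
        w_pre = pre[1:]
        w_post = post[1:]
    new_deaths = trace.new_deaths[1:]
    df_cost = trace.df_costs[1:]
    df_out = trace.df_outcomes[1:]
    years_per_cycle = trace.cycle_length / 12.0

    c = arm.pre_progression_cycle_costs
    rdi = arm.relative_dose_intensity if apply_rdi else 1.0
    treat_per_cycle = c["drug_acquisition"] * rdi + c["administration"]
    background_per_cycle = (
        c["pretreatment"] + c["lab_tests"] + c["monitoring"] + c["prophylaxis"]
    )
    ae_cost, ae_decrement = ae_one_off(arm)
    if not disutility_on:
        ae_decrement = 0.0

    pre_disc = float(w_pre @ df_cost)
    post_disc = float(w_post @ df_cost)
    deaths_disc = float(new_deaths @ df_cost)
    pre_out = float(w_pre @ df_out)
    post_out = float(w_post @ df_out)
    # undiscounted twins use the same reduction so that a zero discount
    # rate makes discounted and undiscounted totals identical, not merely
    # close to rounding
    ones = np.ones_like(df_cost)
    pre_sum = float(w_pre @ ones)
    post_sum = float(w_post @ ones)
    deaths_sum = float(new_deaths @ ones)

    # summed in COST_FIELDS order with the same fsum reduction as
    # ArmResult.total_cost, so a zero discount rate gives exact equality
    undiscounted_cost = math.fsum([
        treat_per_cycle * pre_sum,
        ae_cost,
        background_per_cycle * pre_sum,
        arm.post_progression_cycle_cost * post_sum,
        arm.end_of_life_cost * deaths_sum,
    ])
    # same grouping as ArmResult.total_qalys (pre incl. AE decrement, then post)
    undiscounted_qalys = (
        (utilities.u_pre * years_per_cycle * pre_sum - ae_decrement)
        + utilities.u_post * years_per_cycle * post_sum
    )

    return ArmResult(
        arm_id=arm.arm_id,
        cost_treatment_and_administration=treat_per_cycle * pre_disc,
        cost_adverse_events=ae_cost,
        cost_pre_progression_background=background_per_cycle * pre_disc,
        cost_post_progression_background=arm.post_progression_cycle_cost * post_disc,
        cost_terminal_care=arm.end_of_life_cost * deaths_disc,
        qalys_pre=utilities.u_pre * years_per_cycle * pre_out - ae_decrement,
        qalys_post=utilities.u_post * years_per_cycle * post_out,
        ly_pre_discounted=years_per_cycle * pre_out,
        ly_post_discounted=years_per_cycle * post_out,
        ly_pre_undiscounted=years_per_cycle * pre_sum,
        ly_post_undiscounted=years_per_cycle * post_sum,
        total_cost_undiscounted=undiscounted_cost,
        total_qalys_undiscounted=undiscounted_qalys,
        horizon_months=trace.n_cycles * trace.cycle_length,
    )
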
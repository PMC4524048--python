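"""Model configuration: typed container, YAML loader/saver, parameter paths.

A model configuration is a single YAML document holding every scalar
input of the decision model (per-arm costs, utilities, discounting,
willingness-to-pay, survival specification, hazard-ratio chains and
scenario flags). The schema is documented in ``docs/config_schema.md``.

Parameter paths (used by the one-way and probabilistic sensitivity
analyses) address individual scalars inside a loaded configuration with
dotted strings such as ``utilities.pre_progression`` or
``arms.bev_pacl.pre_progression_cycle_costs.drug_acquisition``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import yaml

from .costing import (
    COST_COMPONENTS,
    AdverseEvent,
    ArmConfig,
    UtilitySet,
)
from .errors import SchemaError, ValidationError
from .survival import (
    FAMILY_ORDER,
    PARAM_NAMES,
    HazardRatioChain,
    ParametricSurvival,
)

__all__ = [
    "ScenarioFlags",
    "SurvivalSpec",
    "OwsaSpec",
    "ModelConfig",
    "load_config",
    "save_config",
    "set_parameter",
    "get_parameter",
]


@dataclass
class ScenarioFlags:
    """Structural scenario switches (all off in the base case)."""

    half_cycle_correction: bool = False
    discount_from_start: bool = False
    apply_rdi: bool = False
    fixed_post_progression_survival_months: float | None = None

    def validate(self) -> None:
        fpps = self.fixed_post_progression_survival_months
        if fpps is not None and fpps < 0:
            raise ValidationError(
                f"fixed post-progression survival must be >= 0 months, got {fpps}"
            )


@dataclass
class SurvivalSpec:
    """How one reference-arm endpoint curve (PFS or OS) is obtained.

    Either ``family`` + ``params`` declare a frozen parametric curve, or
    ``ipd_path`` points at a pseudo-IPD file to be fitted (``family`` may
    then be a family name, ``"best"`` for AIC selection across all four,
    or ``"exponential_endpoint"`` for the landmark-matched exponential).
    ``hazard_scale`` is a proportional-hazards multiplier applied after
    resolution — the sensitivity-analysis lever for +-50% variations of
    the reference arm's own survival.
    """

    endpoint: str
    family: str | None = None
    params: dict | None = None
    ipd_path: str | None = None
    landmark_months: float | None = None
    hazard_scale: float = 1.0

    def validate(self) -> None:
        if self.endpoint not in ("PFS", "OS"):
            raise ValidationError(
                f"survival endpoint must be 'PFS' or 'OS', got {self.endpoint!r}"
            )
        if (self.params is None) == (self.ipd_path is None):
            raise ValidationError(
                f"survival spec for {self.endpoint}: exactly one of 'params' or "
                "'ipd' must be given"
            )
        if self.params is not None:
            if self.family not in FAMILY_ORDER:
                raise ValidationError(
                    f"survival spec for {self.endpoint}: family must be one of "
                    f"{FAMILY_ORDER} when params are given, got {self.family!r}"
                )
            self.build_curve()  # parameter validation
        else:
            allowed = FAMILY_ORDER + ("best", "exponential_endpoint")
            if self.family not in allowed:
                raise ValidationError(
                    f"survival spec for {self.endpoint}: fitting family must be one "
                    f"of {allowed}, got {self.family!r}"
                )
        if not math.isfinite(self.hazard_scale) or self.hazard_scale <= 0:
            raise ValidationError(
                f"survival spec for {self.endpoint}: hazard_scale must be > 0, "
                f"got {self.hazard_scale}"
            )

    def build_curve(self) -> ParametricSurvival:
        if self.params is None:
            raise ValidationError(
                f"survival spec for {self.endpoint} is IPD-backed; fit it first"
            )
        names = PARAM_NAMES[self.family]
        missing = [n for n in names if n not in self.params]
        if missing:
            raise SchemaError(
                f"survival spec for {self.endpoint}: missing required field "
                f"'params.{missing[0]}' for family {self.family!r}"
            )
        values = tuple(float(self.params[n]) for n in names)
        return ParametricSurvival(self.family, values, endpoint_label=self.endpoint)


@dataclass(frozen=True)
class OwsaSpec:
    """One one-way sensitivity row: a parameter path and its low/high values."""

    path: str
    low: float
    high: float

    def __post_init__(self):
        if not self.low < self.high:
            raise ValidationError(
                f"one-way range for {self.path!r} requires low < high, "
                f"got ({self.low}, {self.high})"
            )


@dataclass
class ModelConfig:
    """A fully specified decision model."""

    arms: list
    reference_arm_id: str
    utilities: UtilitySet
    survival: dict
    annual_discount_rate: float = 0.035
    cycle_length_months: float = 1.0
    horizon_months: float = 180.0
    wtp_threshold: float = 36000.0
    scenario_flags: ScenarioFlags = field(default_factory=ScenarioFlags)
    owsa_specs: list = field(default_factory=list)

    def arm(self, arm_id: str) -> ArmConfig:
        for arm in self.arms:
            if arm.arm_id == arm_id:
                return arm
        raise ValidationError(f"unknown arm {arm_id!r}")

    @property
    def reference_arm(self) -> ArmConfig:
        return self.arm(self.reference_arm_id)

    @property
    def comparator_ids(self) -> list:
        return [a.arm_id for a in self.arms if a.arm_id != self.reference_arm_id]

    def validate(self) -> None:
        if not self.arms:
            raise ValidationError("at least one arm is required")
        ids = [a.arm_id for a in self.arms]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate arm identifiers in {ids}")
        if self.reference_arm_id not in ids:
            raise ValidationError(
                f"reference arm {self.reference_arm_id!r} is not among arms {ids}"
            )
        if not 0.0 <= self.annual_discount_rate < 1.0:
            raise ValidationError(
                f"annual discount rate must lie in [0, 1), got "
                f"{self.annual_discount_rate}"
            )
        if self.cycle_length_months <= 0:
            raise ValidationError("cycle length must be positive")
        if self.horizon_months < self.cycle_length_months:
            raise ValidationError(
                f"horizon ({self.horizon_months} months) must cover at least one "
                f"cycle ({self.cycle_length_months} months)"
            )
        if self.wtp_threshold <= 0:
            raise ValidationError(
                f"willingness-to-pay threshold must be > 0, got {self.wtp_threshold}"
            )
        if self.utilities.u_post > self.utilities.u_pre:
            raise ValidationError(
                f"utilities must satisfy u_post <= u_pre in the base case, got "
                f"u_pre={self.utilities.u_pre}, u_post={self.utilities.u_post}"
            )
        for arm in self.arms:
            arm.validate()
        for endpoint in ("PFS", "OS"):
            key = endpoint.lower()
            if key not in self.survival:
                raise SchemaError(f"missing required field 'survival.{key}'")
            self.survival[key].validate()
            if self.survival[key].endpoint != endpoint:
                raise ValidationError(
                    f"survival spec under 'survival.{key}' is labelled "
                    f"{self.survival[key].endpoint!r}"
                )
        self.scenario_flags.validate()


# ---------------------------------------------------------------------------
# YAML loading / saving
# ---------------------------------------------------------------------------


def _require(mapping, key, context):
    if not isinstance(mapping, dict) or key not in mapping:
        raise SchemaError(f"missing required field '{context}{key}'")
    return mapping[key]


def _parse_chain(raw, context) -> HazardRatioChain:
    if raw is None:
        return HazardRatioChain.identity()
    if isinstance(raw, (int, float)):
        return HazardRatioChain.single(float(raw), label=context)
    links = []
    for i, link in enumerate(raw):
        links.append(
            (str(link.get("label", f"link{i}")), float(_require(link, "hr", f"{context}.")))
        )
    try:
        return HazardRatioChain(tuple(links))
    except ValueError as exc:
        raise ValidationError(f"{context}: {exc}") from None


def _parse_arm(raw, index) -> tuple:
    ctx = f"arms[{index}]."
    arm_id = str(_require(raw, "id", ctx))
    costs = _require(raw, "pre_progression_cycle_costs", ctx)
    ae_profile = [
        AdverseEvent(
            label=str(ae.get("label", f"ae{i}")),
            frequency=float(_require(ae, "frequency", f"{ctx}adverse_events[{i}].")),
            unit_cost=float(_require(ae, "unit_cost", f"{ctx}adverse_events[{i}].")),
            disutility=float(ae.get("disutility", 0.0)),
        )
        for i, ae in enumerate(raw.get("adverse_events", []))
    ]
    hrs = raw.get("hazard_ratios", {}) or {}
    arm = ArmConfig(
        arm_id=arm_id,
        label=str(raw.get("label", arm_id)),
        pre_progression_cycle_costs={k: float(v) for k, v in costs.items()},
        relative_dose_intensity=float(raw.get("relative_dose_intensity", 0.86)),
        post_progression_cycle_cost=float(raw.get("post_progression_cycle_cost", 1057.41)),
        end_of_life_cost=float(raw.get("end_of_life_cost", 823.60)),
        ae_profile=ae_profile,
        hr_pfs=_parse_chain(hrs.get("pfs"), f"{ctx}hazard_ratios.pfs"),
        hr_os=_parse_chain(hrs.get("os"), f"{ctx}hazard_ratios.os"),
    )
    return arm, bool(raw.get("reference", False))


def _parse_survival_spec(raw, endpoint) -> SurvivalSpec:
    ctx = f"survival.{endpoint.lower()}."
    if not isinstance(raw, dict):
        raise SchemaError(f"missing required field 'survival.{endpoint.lower()}'")
    spec = SurvivalSpec(
        endpoint=endpoint,
        family=raw.get("family"),
        params={k: float(v) for k, v in raw["params"].items()} if "params" in raw else None,
        ipd_path=raw.get("ipd"),
        landmark_months=(float(raw["landmark_months"])
                         if raw.get("landmark_months") is not None else None),
        hazard_scale=float(raw.get("hazard_scale", 1.0)),
    )
    if spec.params is None and spec.ipd_path is None:
        raise SchemaError(f"missing required field '{ctx}params' (or '{ctx}ipd')")
    return spec


def from_mapping(raw: dict) -> ModelConfig:
    """Build and validate a ModelConfig from a parsed YAML mapping."""
    if not isinstance(raw, dict):
        raise SchemaError("configuration document must be a mapping")

    arms_raw = _require(raw, "arms", "")
    parsed = [_parse_arm(arm_raw, i) for i, arm_raw in enumerate(arms_raw)]
    arms = [arm for arm, _ in parsed]
    flagged = [arm.arm_id for arm, is_ref in parsed if is_ref]
    if len(flagged) > 1:
        raise ValidationError(
            f"exactly one arm may be flagged as reference, got {flagged}"
        )
    reference = raw.get("reference_arm") or (flagged[0] if flagged else None)
    if reference is None:
        raise SchemaError("missing required field 'reference_arm'")
    if flagged and flagged[0] != reference:
        raise ValidationError(
            f"'reference_arm: {reference}' conflicts with reference flag on "
            f"{flagged[0]!r}"
        )

    utilities_raw = _require(raw, "utilities", "")
    utilities = UtilitySet(
        u_pre=float(_require(utilities_raw, "pre_progression", "utilities.")),
        u_post=float(_require(utilities_raw, "post_progression", "utilities.")),
    )

    survival_raw = _require(raw, "survival", "")
    survival = {
        "pfs": _parse_survival_spec(_require(survival_raw, "pfs", "survival."), "PFS"),
        "os": _parse_survival_spec(_require(survival_raw, "os", "survival."), "OS"),
    }

    flags_raw = raw.get("scenario_flags", {}) or {}
    fpps = flags_raw.get("fixed_post_progression_survival_months")
    flags = ScenarioFlags(
        half_cycle_correction=bool(flags_raw.get("half_cycle_correction", False)),
        discount_from_start=bool(flags_raw.get("discount_from_start", False)),
        apply_rdi=bool(flags_raw.get("apply_rdi", False)),
        fixed_post_progression_survival_months=(float(fpps) if fpps is not None else None),
    )

    owsa = [
        OwsaSpec(
            path=str(_require(spec, "path", f"one_way_sa[{i}].")),
            low=float(_require(spec, "low", f"one_way_sa[{i}].")),
            high=float(_require(spec, "high", f"one_way_sa[{i}].")),
        )
        for i, spec in enumerate(raw.get("one_way_sa", []) or [])
    ]

    config = ModelConfig(
        arms=arms,
        reference_arm_id=str(reference),
        utilities=utilities,
        survival=survival,
        annual_discount_rate=float(raw.get("annual_discount_rate", 0.035)),
        cycle_length_months=float(raw.get("cycle_length_months", 1.0)),
        horizon_months=float(raw.get("horizon_months", 180.0)),
        wtp_threshold=float(raw.get("wtp_threshold", 36000.0)),
        scenario_flags=flags,
        owsa_specs=owsa,
    )
    config.validate()
    return config


def load_config(path) -> ModelConfig:
    """Read, parse and validate a YAML model configuration."""
    with open(path, "r", encoding="utf-8") as handle:
        raw = yaml.safe_load(handle)
    return from_mapping(raw)


def to_mapping(config: ModelConfig) -> dict:
    """Serialise a ModelConfig back into a plain YAML-ready mapping."""
    def chain_to_raw(chain):
        return [{"label": label, "hr": hr} for label, hr in chain.links] or None

    def spec_to_raw(spec):
        raw = {}
        if spec.family is not None:
            raw["family"] = spec.family
        if spec.params is not None:
            raw["params"] = dict(spec.params)
        if spec.ipd_path is not None:
            raw["ipd"] = spec.ipd_path
        if spec.landmark_months is not None:
            raw["landmark_months"] = spec.landmark_months
        if spec.hazard_scale != 1.0:
            raw["hazard_scale"] = spec.hazard_scale
        return raw

    arms = []
    for arm in config.arms:
        raw = {
            "id": arm.arm_id,
            "label": arm.label,
            "pre_progression_cycle_costs": dict(arm.pre_progression_cycle_costs),
            "relative_dose_intensity": arm.relative_dose_intensity,
            "post_progression_cycle_cost": arm.post_progression_cycle_cost,
            "end_of_life_cost": arm.end_of_life_cost,
            "adverse_events": [
                {"label": ae.label, "frequency": ae.frequency,
                 "unit_cost": ae.unit_cost, "disutility": ae.disutility}
                for ae in arm.ae_profile
            ],
        }
        hrs = {}
        if arm.hr_pfs.links:
            hrs["pfs"] = chain_to_raw(arm.hr_pfs)
        if arm.hr_os.links:
            hrs["os"] = chain_to_raw(arm.hr_os)
        if hrs:
            raw["hazard_ratios"] = hrs
        arms.append(raw)

    flags = config.scenario_flags
    return {
        "reference_arm": config.reference_arm_id,
        "annual_discount_rate": config.annual_discount_rate,
        "cycle_length_months": config.cycle_length_months,
        "horizon_months": config.horizon_months,
        "wtp_threshold": config.wtp_threshold,
        "utilities": {
            "pre_progression": config.utilities.u_pre,
            "post_progression": config.utilities.u_post,
        },
        "scenario_flags": {
            "half_cycle_correction": flags.half_cycle_correction,
            "discount_from_start": flags.discount_from_start,
            "apply_rdi": flags.apply_rdi,
            "fixed_post_progression_survival_months":
                flags.fixed_post_progression_survival_months,
        },
        "survival": {
            "pfs": spec_to_raw(config.survival["pfs"]),
            "os": spec_to_raw(config.survival["os"]),
        },
        "arms": arms,
        "one_way_sa": [
            {"path": s.path, "low": s.low, "high": s.high} for s in config.owsa_specs
        ],
    }


def save_config(config: ModelConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        yaml.safe_dump(to_mapping(config), handle, sort_keys=False)


# ---------------------------------------------------------------------------
# Parameter paths (shared by the one-way SA and the PSA)
# ---------------------------------------------------------------------------

_TOP_LEVEL = {
    "annual_discount_rate",
    "horizon_months",
    "wtp_threshold",
}

_ARM_SCALARS = {
    "post_progression_cycle_cost",
    "end_of_life_cost",
    "relative_dose_intensity",
}


def _path_error(path):
    return ValidationError(f"unresolvable parameter path {path!r}")


def _ae_totals(arm):
    cost = sum(ae.frequency * ae.unit_cost for ae in arm.ae_profile)
    dis = sum(ae.frequency * ae.disutility for ae in arm.ae_profile)
    return cost, dis


def get_parameter(config: ModelConfig, path: str) -> float:
    """Read the scalar a parameter path points at."""
    parts = path.split(".")
    if parts[0] in _TOP_LEVEL and len(parts) == 1:
        return float(getattr(config, parts[0]))
    if parts[0] == "utilities" and len(parts) == 2:
        if parts[1] == "pre_progression":
            return config.utilities.u_pre
        if parts[1] == "post_progression":
            return config.utilities.u_post
        raise _path_error(path)
    if parts[0] == "survival" and len(parts) == 3 and parts[2] == "hazard_scale":
        if parts[1] not in ("pfs", "os"):
            raise _path_error(path)
        return config.survival[parts[1]].hazard_scale
    if parts[0] == "arms" and len(parts) >= 3:
        try:
            arm = config.arm(parts[1])
        except ValidationError:
            raise _path_error(path) from None
        leaf = parts[2]
        if leaf == "pre_progression_cycle_costs" and len(parts) == 4:
            if parts[3] not in COST_COMPONENTS:
                raise _path_error(path)
            return arm.pre_progression_cycle_costs[parts[3]]
        if leaf in _ARM_SCALARS and len(parts) == 3:
            return float(getattr(arm, leaf))
        if leaf in ("hr_pfs", "hr_os") and len(parts) == 3:
            return getattr(arm, leaf).combined_hr
        if leaf == "ae_total_cost" and len(parts) == 3:
            return _ae_totals(arm)[0]
        if leaf == "ae_total_disutility" and len(parts) == 3:
            return _ae_totals(arm)[1]
    raise _path_error(path)


def set_parameter(config: ModelConfig, path: str, value: float) -> None:
    """Set the scalar a parameter path points at (in place).

    ``arms.<id>.hr_pfs`` / ``hr_os`` replace the chain with a single
    link carrying the given combined hazard ratio.
    ``arms.<id>.ae_total_cost`` / ``ae_total_disutility`` rescale every
    adverse-event line proportionally so the expected total matches.
    """
    value = float(value)
    parts = path.split(".")
    if parts[0] in _TOP_LEVEL and len(parts) == 1:
        setattr(config, parts[0], value)
        return
    if parts[0] == "utilities" and len(parts) == 2:
        if parts[1] == "pre_progression":
            config.utilities = UtilitySet(value, config.utilities.u_post)
            return
        if parts[1] == "post_progression":
            config.utilities = UtilitySet(config.utilities.u_pre, value)
            return
        raise _path_error(path)
    if parts[0] == "survival" and len(parts) == 3 and parts[2] == "hazard_scale":
        if parts[1] not in ("pfs", "os"):
            raise _path_error(path)
        config.survival[parts[1]].hazard_scale = value
        config.survival[parts[1]].validate()
        return
    if parts[0] == "arms" and len(parts) >= 3:
        try:
            arm = config.arm(parts[1])
        except ValidationError:
            raise _path_error(path) from None
        leaf = parts[2]
        if leaf == "pre_progression_cycle_costs" and len(parts) == 4:
            if parts[3] not in COST_COMPONENTS:
                raise _path_error(path)
            arm.pre_progression_cycle_costs[parts[3]] = value
            arm.validate()
            return
        if leaf in _ARM_SCALARS and len(parts) == 3:
            setattr(arm, leaf, value)
            arm.validate()
            return
        if leaf in ("hr_pfs", "hr_os") and len(parts) == 3:
            setattr(arm, leaf, HazardRatioChain.single(value, label=path))
            return
        if leaf in ("ae_total_cost", "ae_total_disutility") and len(parts) == 3:
            index = 0 if leaf == "ae_total_cost" else 1
            current = _ae_totals(arm)[index]
            if current <= 0:
                raise ValidationError(
                    f"cannot rescale {path!r}: current total is {current}"
                )
            factor = value / current
            attr = "unit_cost" if index == 0 else "disutility"
            arm.ae_profile = [
                replace(ae, **{attr: getattr(ae, attr) * factor})
                for ae in arm.ae_profile
            ]
            return
    raise _path_error(path)
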
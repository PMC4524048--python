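"""Synthetic inputs: pseudo-IPD with known truth, and config fixtures.

The trial underlying the reference arm's survival is not publicly
deposited, so the package generates pseudo individual-patient data from
declared parametric truths (inverse-CDF sampling with administrative
and random right-censoring). The packaged cost fixture reproduces the
published per-cycle cost inputs, utilities, discount rate and
willingness-to-pay exactly; its survival parameters and hazard-ratio
chains are documented synthetic placeholders (the source evaluation
prints neither), chosen to be loosely evocative of second-line
metastatic breast cancer: comparators with worse progression-free but
marginally better overall survival than the reference regimen.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import ModelConfig, ScenarioFlags, SurvivalSpec, OwsaSpec
from .costing import AdverseEvent, ArmConfig, ArmResult, UtilitySet
from .errors import ValidationError
from .io import IPDTable
from .survival import PARAM_NAMES, HazardRatioChain, ParametricSurvival

__all__ = [
    "IpdSimSpec",
    "simulate_ipd",
    "paired_ipd",
    "base_case_fixture",
    "fixture_path",
    "published_base_case",
]


def fixture_path():
    """Filesystem path of the packaged fixture configuration (YAML)."""
    from importlib.resources import files

    return files("pscea").joinpath("data/base_case_fixture.yaml")


@dataclass(frozen=True)
class IpdSimSpec:
    """Recipe for simulated time-to-event data with a known truth curve.

    Censoring combines an administrative cutoff (everyone still at risk
    at ``admin_cutoff_months`` is censored there) with non-informative
    random dropout: every subject receives an independent censoring time
    drawn uniformly on (0, c_max), with c_max calibrated against the
    truth curve so the expected censored fraction equals
    ``random_censor_frac``.
    """

    n: int
    family: str
    params: tuple
    admin_cutoff_months: float = math.inf
    random_censor_frac: float = 0.0
    seed: int = 0
    endpoint: str | None = None

    def __post_init__(self):
        if self.n < 2:
            raise ValidationError(f"need n >= 2 subjects, got {self.n}")
        if not 0.0 <= self.random_censor_frac < 1.0:
            raise ValidationError(
                f"random censoring fraction must lie in [0, 1), got "
                f"{self.random_censor_frac}"
            )
        if self.admin_cutoff_months <= 0:
            raise ValidationError("administrative cutoff must be positive")
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        self.truth  # parameter validation via the curve constructor

    @property
    def truth(self) -> ParametricSurvival:
        return ParametricSurvival(self.family, self.params, self.endpoint)


def _inverse_sf(family, params, u):
    """Event times t with S(t) = u, per family (u uniform on (0,1))."""
    if family == "exponential":
        (rate,) = params
        return -np.log(u) / rate
    if family == "weibull":
        shape, scale = params
        return scale * np.power(-np.log(u), 1.0 / shape)
    if family == "gompertz":
        shape, rate = params
        return np.log1p(-(shape / rate) * np.log(u)) / shape
    shape, scale = params
    return scale * np.power((1.0 - u) / u, 1.0 / shape)


def _draw_event_times(spec: IpdSimSpec, rng: np.random.Generator) -> np.ndarray:
    u = rng.uniform(size=spec.n)
    # guard against u exactly 0/1 at float resolution
    u = np.clip(u, 1e-15, 1.0 - 1e-15)
    return _inverse_sf(spec.family, spec.params, u)


def _calibrate_uniform_censoring(sf, frac: float) -> float:
    """c_max of a Uniform(0, c_max) censoring process hitting a target fraction.

    With independent C ~ U(0, c_max), P(censored) = E[P(C < T)] =
    (1/c_max) * integral_0^c_max S(t) dt, which decreases from 1 to 0 in
    c_max, so the target is always bracketable.
    """
    from scipy import integrate, optimize

    def expected_fraction(c_max):
        value, _ = integrate.quad(sf, 0.0, c_max, limit=200)
        return value / c_max

    hi = 1.0
    for _ in range(64):
        if expected_fraction(hi) <= frac:
            break
        hi *= 2.0
    return float(optimize.brentq(
        lambda c: expected_fraction(c) - frac, 1e-9, hi, xtol=1e-9))


def _apply_censoring(times, spec, rng):
    events = np.ones(times.size, dtype=int)
    if spec.random_censor_frac > 0.0:
        c_max = _calibrate_uniform_censoring(spec.truth.sf, spec.random_censor_frac)
        censor_times = np.maximum(rng.uniform(0.0, c_max, size=times.size), 1e-9)
        dropout = censor_times < times
        times = np.where(dropout, censor_times, times)
        events = np.where(dropout, 0, events)
    over = times > spec.admin_cutoff_months
    times = np.where(over, spec.admin_cutoff_months, times)
    events = np.where(over, 0, events)
    return times, events


def simulate_ipd(spec: IpdSimSpec) -> IPDTable:
    """Simulate one endpoint's pseudo-IPD table, reproducible by seed."""
    rng = np.random.default_rng(spec.seed)
    times = _draw_event_times(spec, rng)
    times, events = _apply_censoring(times, spec, rng)
    return IPDTable(times, events, endpoint=spec.endpoint)


def paired_ipd(pfs_spec: IpdSimSpec, os_spec: IpdSimSpec, seed: int = 0):
    """Jointly simulate PFS and OS tables with progression <= death per subject.

    Death times come from the OS truth; progression candidates from the
    PFS truth; the PFS endpoint time is the component-wise minimum of
    the two draws, so every subject progresses (or has the PFS event) at
    or before death. Censoring is shared: one uniform censoring time per
    subject applies to both endpoints, calibrated (on the PFS endpoint's
    effective survival, the product of the two truths) to the
    ``random_censor_frac`` of ``os_spec``. Emits a warning if the
    declared truth curves cross.
    """
    if pfs_spec.n != os_spec.n:
        raise ValidationError("paired simulation requires equal sample sizes")
    grid = np.linspace(0.0, 4.0 * os_spec.truth.median(), 129)
    if np.any(pfs_spec.truth.sf(grid) > os_spec.truth.sf(grid) + 1e-9):
        import warnings

        warnings.warn(
            "PFS truth exceeds OS truth on part of the grid; downstream "
            "clamping will apply",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    t_death = _draw_event_times(os_spec, rng)
    t_prog = _draw_event_times(pfs_spec, rng)
    t_pfs = np.minimum(t_prog, t_death)

    pfs_events = np.ones(os_spec.n, dtype=int)
    os_events = np.ones(os_spec.n, dtype=int)
    pfs_times, os_times = t_pfs.copy(), t_death.copy()
    if os_spec.random_censor_frac > 0.0:
        min_sf = lambda t: pfs_spec.truth.sf(t) * os_spec.truth.sf(t)
        c_max = _calibrate_uniform_censoring(min_sf, os_spec.random_censor_frac)
        censor = np.maximum(rng.uniform(0.0, c_max, size=os_spec.n), 1e-9)
        pfs_events = np.where(censor < pfs_times, 0, pfs_events)
        pfs_times = np.minimum(pfs_times, censor)
        os_events = np.where(censor < os_times, 0, os_events)
        os_times = np.minimum(os_times, censor)
    cutoff = os_spec.admin_cutoff_months
    for times, events in ((pfs_times, pfs_events), (os_times, os_events)):
        over = times > cutoff
        times[over] = cutoff
        events[over] = 0

    return (
        IPDTable(pfs_times, pfs_events, endpoint="PFS"),
        IPDTable(os_times, os_events, endpoint="OS"),
    )


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

# Synthetic survival placeholders (NOT published values): reference-arm
# Weibull PFS median 7.8 months (shape 1.3) and OS median 31 months
# (shape 1.2); comparator hazard-ratio chains with worse PFS and
# marginally better OS than the reference regimen.
_PLACEHOLDER_PFS = {"family": "weibull", "shape": 1.3, "scale": 10.34}
_PLACEHOLDER_OS = {"family": "weibull", "shape": 1.2, "scale": 42.07}
_PLACEHOLDER_HRS = {
    "bev_pacl": {"pfs": 1.45, "os": 0.98},
    "bev_cape": {"pfs": 1.70, "os": 0.97},
}


def _aggregate_ae(label, cost, disutility):
    # the source prints only per-arm AE totals, so one aggregate line
    return [AdverseEvent(label=f"grade 3/4 adverse events ({label}, aggregate)",
                         frequency=1.0, unit_cost=cost, disutility=disutility)]


def base_case_fixture() -> ModelConfig:
    """The packaged three-arm configuration.

    Cost inputs, utilities, discount rate and willingness-to-pay equal
    the published per-cycle figures exactly; survival parameters and
    hazard ratios are synthetic placeholders (see module docstring).
    """
    arms = [
        ArmConfig(
            arm_id="eve_exe",
            label="everolimus + exemestane",
            pre_progression_cycle_costs={
                "drug_acquisition": 2447.75,
                "administration": 0.0,
                "pretreatment": 0.0,
                "lab_tests": 42.82,
                "monitoring": 52.34,
                "prophylaxis": 0.0,
            },
            relative_dose_intensity=0.86,
            post_progression_cycle_cost=1057.41,
            end_of_life_cost=823.60,
            ae_profile=_aggregate_ae("EVE+EXE", 62.0, 0.029),
        ),
        ArmConfig(
            arm_id="bev_pacl",
            label="bevacizumab + paclitaxel",
            pre_progression_cycle_costs={
                "drug_acquisition": 3806.42,
                "administration": 260.89,
                "pretreatment": 82.58,
                "lab_tests": 52.41,
                "monitoring": 52.34,
                "prophylaxis": 274.72,
            },
            relative_dose_intensity=0.86,
            post_progression_cycle_cost=1057.41,
            end_of_life_cost=823.60,
            ae_profile=_aggregate_ae("BEV+PACL", 5.14, 0.027),
            hr_pfs=HazardRatioChain.single(
                _PLACEHOLDER_HRS["bev_pacl"]["pfs"], "indirect comparison (synthetic)"),
            hr_os=HazardRatioChain.single(
                _PLACEHOLDER_HRS["bev_pacl"]["os"], "indirect comparison (synthetic)"),
        ),
        ArmConfig(
            arm_id="bev_cape",
            label="bevacizumab + capecitabine",
            pre_progression_cycle_costs={
                "drug_acquisition": 3510.97,
                "administration": 115.95,
                "pretreatment": 36.69,
                "lab_tests": 48.25,
                "monitoring": 52.34,
                "prophylaxis": 416.77,
            },
            relative_dose_intensity=0.86,
            post_progression_cycle_cost=1057.41,
            end_of_life_cost=823.60,
            ae_profile=_aggregate_ae("BEV+CAPE", 1.00, 0.0031),
            hr_pfs=HazardRatioChain.single(
                _PLACEHOLDER_HRS["bev_cape"]["pfs"], "indirect comparison (synthetic)"),
            hr_os=HazardRatioChain.single(
                _PLACEHOLDER_HRS["bev_cape"]["os"], "indirect comparison (synthetic)"),
        ),
    ]

    def spec(endpoint, placeholder):
        params = {k: v for k, v in placeholder.items() if k != "family"}
        return SurvivalSpec(endpoint=endpoint, family=placeholder["family"],
                            params=params)

    config = ModelConfig(
        arms=arms,
        reference_arm_id="eve_exe",
        utilities=UtilitySet(u_pre=0.7733, u_post=0.4964),
        survival={"pfs": spec("PFS", _PLACEHOLDER_PFS),
                  "os": spec("OS", _PLACEHOLDER_OS)},
        annual_discount_rate=0.035,
        cycle_length_months=1.0,
        # long enough that <0.1% of the cohort survives the horizon
        # under the placeholder curves
        horizon_months=240.0,
        wtp_threshold=36000.0,
        scenario_flags=ScenarioFlags(),
        owsa_specs=[
            OwsaSpec("utilities.pre_progression", 0.36, 0.90),
            OwsaSpec("utilities.post_progression", 0.20, 0.97),
            OwsaSpec("arms.bev_pacl.post_progression_cycle_cost", 500.0, 1500.0),
            OwsaSpec("arms.eve_exe.pre_progression_cycle_costs.drug_acquisition",
                     2000.0, 5000.0),
            OwsaSpec("arms.bev_pacl.hr_pfs", 0.725, 2.175),
            OwsaSpec("survival.os.hazard_scale", 0.5, 1.5),
        ],
    )
    config.validate()
    return config


# Published base-case components (discounted euros / QALYs / life years)
# for the three regimens; the worked-example inputs for the
# incremental-analysis stage.
_PUBLISHED = {
    "eve_exe": {
        "costs": (25727.0, 62.0, 1000.0, 27495.0, 737.51),
        "qalys": (0.648, 1.076),
        "ly_disc": (0.876, 2.167),
        "ly_undisc": (0.899, 2.422),
    },
    "bev_pacl": {
        "costs": (32960.0, 5.0, 3744.0, 30534.0, 736.41),
        "qalys": (0.494, 1.195),
        "ly_disc": (0.675, 2.406),
        "ly_undisc": (0.689, 2.679),
    },
    "bev_cape": {
        "costs": (25832.0, 1.0, 3946.0, 32308.0, 734.77),
        "qalys": (0.456, 1.264),
        "ly_disc": (0.594, 2.546),
        "ly_undisc": (0.604, 2.833),
    },
}


def published_base_case() -> dict:
    """Published per-arm component values assembled into ArmResult objects.

    These are the printed base-case components of the evaluation this
    package reimplements, used as worked-example inputs to the
    incremental-analysis stage (totals are recomputed from the
    components, not copied).
    """
    results = {}
    for arm_id, values in _PUBLISHED.items():
        treat, ae, pre_bg, post_bg, terminal = values["costs"]
        q_pre, q_post = values["qalys"]
        lyd_pre, lyd_post = values["ly_disc"]
        lyu_pre, lyu_post = values["ly_undisc"]
        results[arm_id] = ArmResult(
            arm_id=arm_id,
            cost_treatment_and_administration=treat,
            cost_adverse_events=ae,
            cost_pre_progression_background=pre_bg,
            cost_post_progression_background=post_bg,
            cost_terminal_care=terminal,
            qalys_pre=q_pre,
            qalys_post=q_post,
            ly_pre_discounted=lyd_pre,
            ly_post_discounted=lyd_post,
            ly_pre_undiscounted=lyu_pre,
            ly_post_undiscounted=lyu_post,
        )
    return results
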
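"""Probabilistic sensitivity analysis and acceptability curves.

Each uncertain parameter is sampled independently from a distribution
matched to its central value and dispersion by the method of moments:

* beta for [0, 1]-valued parameters (utilities),
* gamma for non-negative parameters (costs),
* lognormal for positive ratios (hazard ratios).

The source evaluation reports no standard errors, so the default
dispersions are a conventional choice, overridable per parameter:
coefficient of variation 20% for costs and hazard ratios, standard
error 0.05 for utilities. A dispersion of exactly zero degenerates the
distribution to its central value, which makes a zero-dispersion PSA
reproduce the deterministic run draw for draw.

Every draw re-runs the full deterministic pipeline; draws whose sampled
values violate a model invariant (e.g. a post-progression utility
sampled above the pre-progression one) are excluded and counted, and
the run fails if more than 1% of draws are lost.
"""
from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cea import resolve_reference_curves, run_model
from .config import ModelConfig, get_parameter, set_parameter
from .costing import COST_COMPONENTS
from .errors import CeaModelError, PsaError, TruncationWarning, ValidationError

__all__ = [
    "UncertainParameter",
    "PsaDraws",
    "moment_match",
    "sample_parameter",
    "default_uncertain_parameters",
    "run_psa",
    "incremental_cloud",
    "ceac",
    "default_wtp_grid",
]

_PSA_FAMILIES = ("beta", "gamma", "lognormal")


@dataclass(frozen=True)
class UncertainParameter:
    """A sampled model input: config path, family, central value, dispersion.

    ``dispersion`` is a standard deviation if ``dispersion_kind`` is
    ``"sd"``, or a coefficient of variation if ``"cv"``. Zero dispersion
    is the degenerate (deterministic) case.
    """

    path: str
    family: str
    central: float
    dispersion: float
    dispersion_kind: str = "sd"

    def __post_init__(self):
        if self.family not in _PSA_FAMILIES:
            raise ValidationError(
                f"PSA family must be one of {_PSA_FAMILIES}, got {self.family!r}"
            )
        if self.dispersion < 0:
            raise ValidationError(
                f"{self.path}: dispersion must be >= 0, got {self.dispersion}"
            )
        if self.dispersion_kind not in ("sd", "cv"):
            raise ValidationError(
                f"{self.path}: dispersion_kind must be 'sd' or 'cv'"
            )

    @property
    def sd(self) -> float:
        if self.dispersion_kind == "sd":
            return self.dispersion
        return self.dispersion * abs(self.central)


def moment_match(family: str, mean: float, sd: float) -> dict:
    """Distribution parameters matching a mean and standard deviation.

    beta -> alpha/beta from mean and variance; gamma -> shape/rate;
    lognormal -> mu/sigma of the log scale matching the natural-scale
    mean and variance.
    """
    if sd <= 0:
        raise ValidationError(f"moment matching requires sd > 0, got {sd}")
    var = sd * sd
    if family == "beta":
        if not 0.0 < mean < 1.0:
            raise ValidationError(f"beta mean must lie in (0, 1), got {mean}")
        if var >= mean * (1.0 - mean):
            raise ValidationError(
                f"infeasible beta variance {var} for mean {mean}: must be below "
                f"mean*(1-mean) = {mean * (1 - mean)}"
            )
        alpha = mean * (mean * (1.0 - mean) / var - 1.0)
        return {"alpha": alpha, "beta": alpha * (1.0 - mean) / mean}
    if family == "gamma":
        if mean <= 0:
            raise ValidationError(f"gamma mean must be > 0, got {mean}")
        return {"shape": mean * mean / var, "rate": mean / var}
    if family == "lognormal":
        if mean <= 0:
            raise ValidationError(f"lognormal mean must be > 0, got {mean}")
        sigma2 = math.log1p(var / (mean * mean))
        return {"mu": math.log(mean) - sigma2 / 2.0, "sigma": math.sqrt(sigma2)}
    raise ValidationError(f"unknown PSA family {family!r}")


def sample_parameter(param: UncertainParameter, rng: np.random.Generator,
                     size: int) -> np.ndarray:
    """Draw ``size`` values; zero dispersion yields the central value."""
    if param.sd == 0.0:
        return np.full(size, param.central, dtype=float)
    p = moment_match(param.family, param.central, param.sd)
    if param.family == "beta":
        return rng.beta(p["alpha"], p["beta"], size)
    if param.family == "gamma":
        return rng.gamma(p["shape"], 1.0 / p["rate"], size)
    return rng.lognormal(p["mu"], p["sigma"], size)


def default_uncertain_parameters(
    config: ModelConfig,
    *,
    cost_cv: float = 0.20,
    hr_cv: float = 0.20,
    utility_sd: float = 0.05,
) -> list:
    """The full default parameter set: every cost, utility and hazard ratio."""
    params = [
        UncertainParameter("utilities.pre_progression", "beta",
                           config.utilities.u_pre, utility_sd),
        UncertainParameter("utilities.post_progression", "beta",
                           config.utilities.u_post, utility_sd),
    ]
    for arm in config.arms:
        prefix = f"arms.{arm.arm_id}"
        for component in COST_COMPONENTS:
            central = arm.pre_progression_cycle_costs[component]
            if central > 0:
                params.append(UncertainParameter(
                    f"{prefix}.pre_progression_cycle_costs.{component}",
                    "gamma", central, cost_cv, "cv"))
        params.append(UncertainParameter(
            f"{prefix}.post_progression_cycle_cost", "gamma",
            arm.post_progression_cycle_cost, cost_cv, "cv"))
        params.append(UncertainParameter(
            f"{prefix}.end_of_life_cost", "gamma",
            arm.end_of_life_cost, cost_cv, "cv"))
        ae_cost = get_parameter(config, f"{prefix}.ae_total_cost")
        if ae_cost > 0:
            params.append(UncertainParameter(
                f"{prefix}.ae_total_cost", "gamma", ae_cost, cost_cv, "cv"))
        if arm.arm_id != config.reference_arm_id:
            for endpoint in ("pfs", "os"):
                hr = get_parameter(config, f"{prefix}.hr_{endpoint}")
                params.append(UncertainParameter(
                    f"{prefix}.hr_{endpoint}", "lognormal", hr, hr_cv, "cv"))
    return params


@dataclass
class PsaDraws:
    """Per-draw, per-arm totals from a Monte-Carlo run."""

    frame: pd.DataFrame  # columns: draw, arm_id, cost, qalys, lys
    seed: int
    n_draws: int
    n_failed: int = 0
    failed_draws: list = field(default_factory=list)

    def arm_ids(self):
        return list(self.frame["arm_id"].unique())


def run_psa(
    config: ModelConfig,
    uncertain=None,
    n_draws: int = 1000,
    seed: int = 0,
    max_failure_fraction: float = 0.01,
) -> PsaDraws:
    """Monte-Carlo propagation of parameter uncertainty.

    Fully reproducible given ``(seed, n_draws, config)``: all sampling
    comes from one seeded generator, drawn up front parameter by
    parameter.
    """
    if n_draws < 1:
        raise ValidationError(f"n_draws must be >= 1, got {n_draws}")
    config.validate()
    if uncertain is None:
        uncertain = default_uncertain_parameters(config)

    rng = np.random.default_rng(seed)
    samples = {p.path: sample_parameter(p, rng, n_draws) for p in uncertain}

    # reference curves can be resolved once unless the survival spec is sampled
    touches_survival = any(p.path.startswith("survival.") for p in uncertain)
    curves = None if touches_survival else resolve_reference_curves(config)[0]

    records = []
    failed = []
    first_error = None
    for draw in range(n_draws):
        varied = copy.deepcopy(config)
        try:
            for p in uncertain:
                set_parameter(varied, p.path, float(samples[p.path][draw]))
            varied.validate()
            with warnings.catch_warnings():
                # extreme sampled hazard ratios routinely trip the
                # horizon-truncation check; the base case already reports it
                warnings.simplefilter("ignore", TruncationWarning)
                run = run_model(varied, reference_curves=curves)
        except CeaModelError as exc:
            failed.append(draw)
            if first_error is None:
                first_error = exc
            continue
        for arm_id, result in run.arm_results.items():
            records.append({
                "draw": draw,
                "arm_id": arm_id,
                "cost": result.total_cost,
                "qalys": result.total_qalys,
                "lys": result.ly_total_discounted,
            })

    if len(failed) > max_failure_fraction * n_draws:
        raise PsaError(
            f"{len(failed)} of {n_draws} draws failed (> "
            f"{max_failure_fraction:.0%} allowed); first failure: {first_error}"
        )
    return PsaDraws(
        frame=pd.DataFrame(records),
        seed=seed,
        n_draws=n_draws,
        n_failed=len(failed),
        failed_draws=failed,
    )


def incremental_cloud(draws: PsaDraws, pair) -> pd.DataFrame:
    """Per-draw incremental cost and effect for a pair ``(a, b)`` (a - b)."""
    a, b = pair
    present = set(draws.arm_ids())
    for arm in pair:
        if arm not in present:
            raise ValidationError(f"arm {arm!r} not present in the PSA draws")
    wide = draws.frame.pivot(index="draw", columns="arm_id",
                             values=["cost", "qalys"])
    return pd.DataFrame({
        "draw": wide.index,
        "delta_cost": (wide[("cost", a)] - wide[("cost", b)]).to_numpy(),
        "delta_qalys": (wide[("qalys", a)] - wide[("qalys", b)]).to_numpy(),
    }).reset_index(drop=True)


def default_wtp_grid() -> np.ndarray:
    """0 to 100,000 euros in 1,000-euro steps (includes the 36,000 threshold)."""
    return np.arange(0.0, 100001.0, 1000.0)


def ceac(draws: PsaDraws, pair, wtp_grid=None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve for ``pair = (a, b)``.

    At each willingness-to-pay, the probability that ``a`` is
    cost-effective against ``b`` is the fraction of draws with strictly
    positive incremental net monetary benefit (ties count as not
    cost-effective). Deterministic given the draws: no re-sampling.
    """
    if wtp_grid is None:
        wtp_grid = default_wtp_grid()
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size == 0:
        raise ValidationError("the willingness-to-pay grid must be non-empty")
    cloud = incremental_cloud(draws, pair)
    delta_cost = cloud["delta_cost"].to_numpy()
    delta_qalys = cloud["delta_qalys"].to_numpy()
    probabilities = [
        float(np.mean(wtp * delta_qalys - delta_cost > 0.0)) for wtp in wtp_grid
    ]
    return pd.DataFrame({"wtp": wtp_grid, "probability": probabilities})
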
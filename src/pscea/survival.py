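"""Parametric survival curves for time-to-event extrapolation.

Implements the four distribution families used to extrapolate
progression-free survival (PFS) and overall survival (OS) beyond trial
follow-up — exponential, Weibull, Gompertz and log-logistic — together
with maximum-likelihood fitting under right-censoring, AIC-based model
selection, and the proportional-hazards transform used to derive
comparator curves from a reference arm via a chain of hazard ratios.

Conventions
-----------
* Time is measured in months throughout; 1 year = 12 months exactly.
* Survival forms:
    exponential   S(t) = exp(-rate * t)
    weibull       S(t) = exp(-(t/scale)^shape)
    gompertz      S(t) = exp(-(rate/shape) * (e^(shape*t) - 1)), shape > 0
    loglogistic   S(t) = 1 / (1 + (t/scale)^shape)
* The Gompertz shape is restricted to be strictly positive so that
  S(t) -> 0: a lifetime-horizon cohort model requires eventual death,
  and negative-shape (cure-fraction) extrapolations are rejected.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import ConvergenceError, FittingError

__all__ = [
    "FAMILY_ORDER",
    "PARAM_NAMES",
    "SurvivalCurve",
    "ParametricSurvival",
    "PowerSurvival",
    "MinimumSurvival",
    "HazardRatioChain",
    "FitResult",
    "survival_at",
    "fit_parametric",
    "fit_all_families",
    "select_best_fit",
    "apply_hazard_ratio",
    "exponential_from_landmark",
    "fit_exponential_endpoint",
]

#: Declared family order; also the tie-break order in model selection.
FAMILY_ORDER = ("exponential", "weibull", "gompertz", "loglogistic")

PARAM_NAMES = {
    "exponential": ("rate",),
    "weibull": ("shape", "scale"),
    "gompertz": ("shape", "rate"),
    "loglogistic": ("shape", "scale"),
}


def _as_time_array(t):
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise ValueError("survival time must be non-negative")
    return arr


class SurvivalCurve:
    """Minimal survival-function interface: ``sf(t)`` for t >= 0 months."""

    def sf(self, t):
        raise NotImplementedError

    def median(self) -> float:
        """Time at which S(t) = 0.5, by bracketed root finding."""
        hi = 1.0
        for _ in range(256):
            if self.sf(hi) <= 0.5:
                break
            hi *= 2.0
        else:  # pragma: no cover - pathological curve
            raise ValueError("median not reached within bracketing range")
        return float(optimize.brentq(lambda x: self.sf(x) - 0.5, 0.0, hi, xtol=1e-12))


@dataclass(frozen=True)
class ParametricSurvival(SurvivalCurve):
    """A survival distribution identified by family and positive parameters.

    ``params`` is an ordered tuple following :data:`PARAM_NAMES`.
    ``endpoint_label`` optionally tags the curve as "PFS" or "OS".
    """

    family: str
    params: tuple
    endpoint_label: str | None = None

    def __post_init__(self):
        if self.family not in PARAM_NAMES:
            raise ValueError(
                f"unknown family {self.family!r}; expected one of {FAMILY_ORDER}"
            )
        params = tuple(float(p) for p in np.atleast_1d(self.params))
        names = PARAM_NAMES[self.family]
        if len(params) != len(names):
            raise ValueError(
                f"{self.family} takes parameters {names}, got {len(params)} values"
            )
        for name, value in zip(names, params):
            if not math.isfinite(value) or value <= 0:
                raise ValueError(
                    f"{self.family} parameter {name!r} must be a positive finite "
                    f"number, got {value!r}"
                )
        object.__setattr__(self, "params", params)

    # -- constructors -----------------------------------------------------
    @classmethod
    def exponential(cls, rate, endpoint_label=None):
        return cls("exponential", (rate,), endpoint_label)

    @classmethod
    def weibull(cls, shape, scale, endpoint_label=None):
        return cls("weibull", (shape, scale), endpoint_label)

    @classmethod
    def gompertz(cls, shape, rate, endpoint_label=None):
        return cls("gompertz", (shape, rate), endpoint_label)

    @classmethod
    def loglogistic(cls, shape, scale, endpoint_label=None):
        return cls("loglogistic", (shape, scale), endpoint_label)

    # -- interface --------------------------------------------------------
    @property
    def n_params(self) -> int:
        return len(self.params)

    @property
    def param_dict(self) -> dict:
        return dict(zip(PARAM_NAMES[self.family], self.params))

    def sf(self, t):
        t_arr = _as_time_array(t)
        with np.errstate(over="ignore"):
            if self.family == "exponential":
                (rate,) = self.params
                s = np.exp(-rate * t_arr)
            elif self.family == "weibull":
                shape, scale = self.params
                s = np.exp(-np.power(t_arr / scale, shape))
            elif self.family == "gompertz":
                shape, rate = self.params
                s = np.exp(-(rate / shape) * np.expm1(shape * t_arr))
            else:  # loglogistic
                shape, scale = self.params
                s = 1.0 / (1.0 + np.power(t_arr / scale, shape))
        s = np.clip(np.nan_to_num(s, nan=0.0), 0.0, 1.0)
        return float(s) if np.ndim(t) == 0 else s

    def hazard(self, t):
        """Instantaneous hazard h(t)."""
        t_arr = _as_time_array(t)
        if self.family == "exponential":
            (rate,) = self.params
            h = np.full_like(t_arr, rate)
        elif self.family == "weibull":
            shape, scale = self.params
            h = (shape / scale) * np.power(t_arr / scale, shape - 1.0)
        elif self.family == "gompertz":
            shape, rate = self.params
            h = rate * np.exp(shape * t_arr)
        else:
            shape, scale = self.params
            z = np.power(t_arr / scale, shape)
            h = (shape / t_arr) * z / (1.0 + z)
        return float(h) if np.ndim(t) == 0 else h

    def median(self) -> float:
        ln2 = math.log(2.0)
        if self.family == "exponential":
            return ln2 / self.params[0]
        if self.family == "weibull":
            shape, scale = self.params
            return scale * ln2 ** (1.0 / shape)
        if self.family == "gompertz":
            shape, rate = self.params
            return math.log1p(shape * ln2 / rate) / shape
        shape, scale = self.params
        return scale


@dataclass(frozen=True)
class PowerSurvival(SurvivalCurve):
    """S(t) = S_base(t)^power — a proportional-hazards transform.

    Used where the base family is not closed under the transform
    (log-logistic) or where the base is itself a composite curve.
    """

    base: SurvivalCurve
    power: float

    def __post_init__(self):
        if not math.isfinite(self.power) or self.power <= 0:
            raise ValueError(f"power must be positive and finite, got {self.power!r}")
        # flatten nested powers so repeated transforms stay cheap
        if isinstance(self.base, PowerSurvival):
            object.__setattr__(self, "power", self.power * self.base.power)
            object.__setattr__(self, "base", self.base.base)

    def sf(self, t):
        s = np.clip(np.asarray(self.base.sf(t), dtype=float), 0.0, 1.0)
        out = np.power(s, self.power)
        return float(out) if np.ndim(t) == 0 else out


@dataclass(frozen=True)
class MinimumSurvival(SurvivalCurve):
    """Point-wise minimum of two survival functions.

    Clamps a PFS curve at or below its companion OS curve: progression
    precedes or coincides with death, but independently derived
    hazard-ratio chains can otherwise make the curves cross.
    """

    first: SurvivalCurve
    second: SurvivalCurve

    def sf(self, t):
        out = np.minimum(self.first.sf(t), self.second.sf(t))
        return float(out) if np.ndim(t) == 0 else out


@dataclass(frozen=True)
class HazardRatioChain:
    """An ordered chain of labelled hazard ratios vs a reference arm.

    The combined hazard ratio is the product of the links; an empty
    chain is the identity (combined HR = 1). Chains encode indirect
    treatment comparisons in which each link is one published HR.
    """

    links: tuple = ()

    def __post_init__(self):
        links = tuple((str(label), float(hr)) for label, hr in self.links)
        for label, hr in links:
            if not math.isfinite(hr) or hr <= 0:
                raise ValueError(f"hazard ratio {label!r} must be > 0, got {hr!r}")
        object.__setattr__(self, "links", links)

    @property
    def combined_hr(self) -> float:
        return float(math.prod(hr for _, hr in self.links)) if self.links else 1.0

    def with_link(self, label: str, hr: float) -> "HazardRatioChain":
        return HazardRatioChain(self.links + ((label, hr),))

    @classmethod
    def identity(cls) -> "HazardRatioChain":
        return cls(())

    @classmethod
    def single(cls, hr: float, label: str = "hr") -> "HazardRatioChain":
        return cls(((label, hr),))


def survival_at(curve: SurvivalCurve, t) -> float:
    """Evaluate S(t); raises ``ValueError`` for negative times."""
    return curve.sf(t)


def apply_hazard_ratio(base: SurvivalCurve, chain) -> SurvivalCurve:
    """Proportional-hazards transform ``S_new(t) = S_base(t)^HR``.

    ``chain`` may be a :class:`HazardRatioChain` or a bare positive float.
    Families closed under the transform (exponential, Weibull, Gompertz)
    return a closed-form :class:`ParametricSurvival`; anything else
    returns a :class:`PowerSurvival` wrapper.
    """
    hr = chain.combined_hr if isinstance(chain, HazardRatioChain) else float(chain)
    if not math.isfinite(hr) or hr <= 0:
        raise ValueError(f"combined hazard ratio must be > 0, got {hr!r}")
    if hr == 1.0:
        return base
    if isinstance(base, ParametricSurvival):
        label = base.endpoint_label
        if base.family == "exponential":
            return ParametricSurvival.exponential(base.params[0] * hr, label)
        if base.family == "weibull":
            shape, scale = base.params
            return ParametricSurvival.weibull(shape, scale * hr ** (-1.0 / shape), label)
        if base.family == "gompertz":
            shape, rate = base.params
            return ParametricSurvival.gompertz(shape, rate * hr, label)
    return PowerSurvival(base, hr)


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting under right-censoring
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitResult:
    """A fitted curve with its likelihood-based fit statistics."""

    curve: ParametricSurvival
    log_likelihood: float
    aic: float
    bic: float
    n_events: int
    n_censored: int

    @property
    def n(self) -> int:
        return self.n_events + self.n_censored


def _extract(ipd):
    """Accept an IPDTable, a (time, event) pair, or a two-column frame."""
    if hasattr(ipd, "time") and hasattr(ipd, "event"):
        time, event = ipd.time, ipd.event
    elif isinstance(ipd, tuple) and len(ipd) == 2:
        time, event = ipd
    else:
        raise TypeError("expected an IPDTable or a (time, event) pair")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.shape != event.shape:
        raise ValueError("time and event must have equal length")
    if np.any(time <= 0):
        raise FittingError("all event/censoring times must be strictly positive")
    if not np.isin(event, (0, 1)).all():
        raise FittingError("event flags must be 0 (censored) or 1 (event)")
    return time, event


def _loglik(family, params, time, event):
    """Right-censored log-likelihood: events contribute log f, censored log S."""
    if family == "exponential":
        (rate,) = params
        return float(event.sum() * np.log(rate) - rate * time.sum())
    if family == "weibull":
        shape, scale = params
        z = time / scale
        cum = np.power(z, shape)
        ev = np.log(shape) - np.log(scale) + (shape - 1.0) * np.log(z)
        return float(np.sum(event * ev) - cum.sum())
    if family == "gompertz":
        shape, rate = params
        cum = (rate / shape) * np.expm1(shape * time)
        ev = np.log(rate) + shape * time
        return float(np.sum(event * ev) - cum.sum())
    # loglogistic
    shape, scale = params
    z = np.power(time / scale, shape)
    log1pz = np.log1p(z)
    ev = np.log(shape) - np.log(scale) + (shape - 1.0) * np.log(time / scale) - log1pz
    return float(np.sum(event * ev) - log1pz.sum())


_LOG_BOUNDS = {
    "weibull": [(-6.0, 5.0), (-10.0, 15.0)],
    "gompertz": [(-12.0, 3.0), (-20.0, 10.0)],
    "loglogistic": [(-6.0, 5.0), (-10.0, 15.0)],
}


def _initial_log_params(family, time, event):
    """Deterministic method-of-moments-style starting values (log scale)."""
    d = max(int(event.sum()), 1)
    exp_scale = time.sum() / d  # exponential MLE mean
    if family == "weibull":
        return np.log([1.0, exp_scale])
    if family == "gompertz":
        return np.log([0.01, 1.0 / exp_scale])
    event_times = time[event == 1]
    med = np.median(event_times) if event_times.size else np.median(time)
    return np.log([1.5, med])


def fit_parametric(ipd, family: str) -> FitResult:
    """Maximum-likelihood fit of one family to right-censored data.

    Deterministic: fixed starting values, no randomness. Requires at
    least two observed events. Raises :class:`FittingError` on all-censored
    data and :class:`ConvergenceError` if the optimiser fails.
    """
    if family not in PARAM_NAMES:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILY_ORDER}")
    time, event = _extract(ipd)
    d = int(event.sum())
    if d == 0:
        raise FittingError("cannot fit a survival model to all-censored data")
    if d < 2:
        raise FittingError(f"at least 2 observed events are required, got {d}")

    endpoint = getattr(ipd, "endpoint", None)

    if family == "exponential":
        rate = d / time.sum()
        params = (rate,)
    else:
        def nll(x):
            with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                ll = _loglik(family, np.exp(x), time, event)
            return -ll if np.isfinite(ll) else 1e12

        x0 = _initial_log_params(family, time, event)
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B", bounds=_LOG_BOUNDS[family]
        )
        if not res.success or res.fun >= 1e11:
            res = optimize.minimize(
                nll, x0, method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 5000},
            )
        if not res.success or res.fun >= 1e11:
            raise ConvergenceError(
                f"{family} fit did not converge (n={time.size}, events={d}): "
                f"{getattr(res, 'message', 'optimizer failure')}"
            )
        params = tuple(np.exp(res.x))

    ll = _loglik(family, params, time, event)
    k = len(params)
    n = time.size
    curve = ParametricSurvival(family, params, endpoint_label=endpoint)
    return FitResult(
        curve=curve,
        log_likelihood=ll,
        aic=2.0 * k - 2.0 * ll,
        bic=k * math.log(n) - 2.0 * ll,
        n_events=d,
        n_censored=n - d,
    )


def fit_all_families(ipd, families=FAMILY_ORDER):
    """Fit every requested family to the same data, in declared order."""
    return [fit_parametric(ipd, family) for family in families]


def select_best_fit(fits) -> FitResult:
    """Pick the minimum-AIC fit.

    Ties are broken by fewer parameters, then by declared family order.
    All fits must come from the same dataset (equal sample sizes).
    """
    fits = list(fits)
    if not fits:
        raise ValueError("select_best_fit requires at least one fit")
    sizes = {(f.n_events, f.n_censored) for f in fits}
    if len(sizes) > 1:
        raise FittingError(
            f"fits come from different datasets (event/censor counts {sorted(sizes)})"
        )
    order = {family: i for i, family in enumerate(FAMILY_ORDER)}
    return min(
        fits,
        key=lambda f: (f.aic, f.curve.n_params, order.get(f.curve.family, len(order))),
    )


def exponential_from_landmark(landmark_months: float, survival_prob: float,
                              endpoint_label: str | None = None) -> ParametricSurvival:
    """Exponential curve whose S(landmark) equals a stated probability.

    The "endpoint" reading of exponential extrapolation: the constant
    hazard is matched to a single landmark survival probability instead
    of being fit to the whole follow-up (rate = -ln S / t).
    """
    if landmark_months <= 0:
        raise ValueError("landmark time must be positive")
    if not 0.0 < survival_prob < 1.0:
        raise ValueError("landmark survival probability must lie strictly in (0, 1)")
    rate = -math.log(survival_prob) / landmark_months
    return ParametricSurvival.exponential(rate, endpoint_label)


def fit_exponential_endpoint(ipd, landmark_months: float | None = None) -> FitResult:
    """Exponential fit matched to the Kaplan-Meier estimate at a landmark.

    Defaults to the latest time at which the Kaplan-Meier estimate is
    still positive. The returned :class:`FitResult` carries the
    log-likelihood of the matched rate so it can sit alongside ML fits
    in model-selection tables (it is not itself an ML estimate).
    """
    from lifelines import KaplanMeierFitter

    time, event = _extract(ipd)
    d = int(event.sum())
    if d == 0:
        raise FittingError("cannot fit a survival model to all-censored data")

    km = KaplanMeierFitter().fit(time, event)
    surv = km.survival_function_.iloc[:, 0]
    if landmark_months is None:
        positive = surv[surv > 0.0]
        landmark_months = float(positive.index[-1])
    s_hat = float(km.predict(landmark_months))
    if not 0.0 < s_hat < 1.0:
        raise FittingError(
            f"Kaplan-Meier survival at landmark {landmark_months} months is {s_hat}; "
            "choose a landmark where the estimate lies strictly in (0, 1)"
        )
    curve = exponential_from_landmark(landmark_months, s_hat,
                                      getattr(ipd, "endpoint", None))
    ll = _loglik("exponential", curve.params, time, event)
    n = time.size
    return FitResult(
        curve=curve,
        log_likelihood=ll,
        aic=2.0 - 2.0 * ll,
        bic=math.log(n) - 2.0 * ll,
        n_events=d,
        n_censored=n - d,
    )
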
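"""Three-state cohort trace built by partitioned survival.

State occupancy is read directly off the PFS and OS curves each cycle:

    pre-progression(t)  = PFS(t)
    dead(t)             = 1 - OS(t)
    post-progression(t) = OS(t) - PFS(t)

The cohort enters pre-progression at cycle 0 and death is absorbing.
Cycle ``t`` covers the interval ``(t-1, t]`` months; events within a
cycle are attributed to its end. No explicit transition matrix exists —
occupancy is fully determined by the two curves, which is the standard
construction when a model is specified through PFS/OS plus hazard
ratios rather than through per-cycle transition probabilities.

Discounting. Costs and outcomes beyond one year are discounted at an
annual rate (3.5% default). Two conventions are provided:

* annual step (default): months 0-12 undiscounted, then
  ``(1+r)^(-floor(month/12))`` — the literal "beyond one year" reading;
* from-start (``from_start=True``): continuous ``(1+r)^(-month/12)``
  from time zero, the more common textbook convention.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConsistencyError, TruncationWarning, ValidationError

__all__ = ["CohortTrace", "build_trace", "discount_factor"]

#: Residual alive fraction at the horizon above which a truncation warning fires.
TRUNCATION_TOLERANCE = 1e-3


def discount_factor(month, annual_rate: float, from_start: bool = False):
    """Discount factor for a time point given in months.

    ``from_start=False`` (default) applies annual step discounting with
    the first year (months 0-12 inclusive) undiscounted; ``True``
    discounts continuously from time zero.
    """
    if annual_rate < 0:
        raise ValueError(f"annual discount rate must be >= 0, got {annual_rate}")
    m = np.asarray(month, dtype=float)
    if np.any(m < 0):
        raise ValueError("month index must be >= 0")
    if from_start:
        out = (1.0 + annual_rate) ** (-m / 12.0)
    else:
        out = np.where(m <= 12.0, 1.0, (1.0 + annual_rate) ** (-np.floor(m / 12.0)))
    return float(out) if np.ndim(month) == 0 else out


@dataclass
class CohortTrace:
    """Per-cycle occupancy, incident events and discount factors.

    All arrays are indexed by cycle 0..H. ``new_progressions`` counts
    the per-cycle decline in pre-progression occupancy (in a partitioned
    survival model, exits to post-progression and direct deaths from the
    pre-progression state are not separately identified).
    """

    cycle_length: float
    pre: np.ndarray
    post: np.ndarray
    dead: np.ndarray
    new_deaths: np.ndarray
    new_progressions: np.ndarray
    df_outcomes: np.ndarray
    df_costs: np.ndarray

    @property
    def n_cycles(self) -> int:
        return len(self.pre) - 1

    @property
    def months(self) -> np.ndarray:
        return np.arange(len(self.pre)) * self.cycle_length

    def check_conservation(self, atol: float = 1e-9) -> None:
        total = self.pre + self.post + self.dead
        worst = float(np.abs(total - 1.0).max())
        if worst > atol:
            raise ConsistencyError(
                f"state occupancy does not sum to 1 (max deviation {worst:.3e})"
            )
        if np.any(np.diff(self.dead) < -atol):
            raise ConsistencyError("death occupancy must be non-decreasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": np.arange(len(self.pre)),
                "month": self.months,
                "pre_progression": self.pre,
                "post_progression": self.post,
                "dead": self.dead,
                "new_deaths": self.new_deaths,
                "new_progressions": self.new_progressions,
                "df_outcomes": self.df_outcomes,
                "df_costs": self.df_costs,
            }
        )


def _evaluate(curve_or_fn, t):
    fn = curve_or_fn.sf if hasattr(curve_or_fn, "sf") else curve_or_fn
    s = np.asarray(fn(t), dtype=float)
    return s


def build_trace(
    pfs,
    os_curve,
    horizon: float,
    *,
    fixed_pps: float | None = None,
    annual_rate: float = 0.035,
    from_start: bool = False,
    cycle_length: float = 1.0,
    conservation_atol: float = 1e-9,
) -> CohortTrace:
    """Build the monthly-cycle cohort trace from PFS and OS curves.

    ``pfs`` and ``os_curve`` are survival curves (anything exposing
    ``sf(t)`` or a plain callable); PFS must lie at or below OS on the
    whole grid — clamp upstream (see ``MinimumSurvival``) if hazard-ratio
    chains can cross the curves.

    ``fixed_pps`` switches to the fixed post-progression survival
    scenario: every cohort fraction leaving the pre-progression state is
    treated as a progression and dies exactly ``fixed_pps`` months later,
    overriding the OS curve.

    Emits a :class:`TruncationWarning` when more than 0.1% of the cohort
    is still alive at the horizon.
    """
    if horizon < cycle_length:
        raise ValueError(
            f"horizon ({horizon} months) must cover at least one cycle "
            f"of {cycle_length} months"
        )
    n_cycles = int(round(horizon / cycle_length))
    t = np.arange(n_cycles + 1) * cycle_length

    s_pfs = _evaluate(pfs, t)
    s_os = _evaluate(os_curve, t)
    for name, s in (("PFS", s_pfs), ("OS", s_os)):
        if np.any(s < -1e-12) or np.any(s > 1.0 + 1e-12):
            raise ValidationError(f"{name} values must lie in [0, 1]")
        if abs(s[0] - 1.0) > 1e-9:
            raise ValidationError(f"{name} must start at S(0) = 1, got {s[0]}")
        if np.any(np.diff(s) > 1e-9):
            raise ValidationError(f"{name} must be non-increasing over the grid")
    if np.any(s_pfs > s_os + 1e-9):
        raise ConsistencyError(
            "PFS exceeds OS on the cycle grid; clamp PFS <= OS upstream"
        )
    s_pfs = np.minimum(np.clip(s_pfs, 0.0, 1.0), np.clip(s_os, 0.0, 1.0))
    s_os = np.clip(s_os, 0.0, 1.0)

    pre = s_pfs.copy()
    new_prog = np.maximum(-np.diff(pre, prepend=pre[0]), 0.0)

    if fixed_pps is None:
        dead = 1.0 - s_os
        post = np.maximum(s_os - s_pfs, 0.0)
        new_deaths = np.maximum(np.diff(dead, prepend=dead[0]), 0.0)
    else:
        if fixed_pps < 0:
            raise ValueError("fixed post-progression survival must be >= 0 months")
        lag = int(round(fixed_pps / cycle_length))
        cum_prog = np.cumsum(new_prog)
        shifted = np.concatenate([np.zeros(min(lag, n_cycles + 1)), cum_prog])[: n_cycles + 1]
        post = cum_prog - shifted
        dead = shifted
        new_deaths = np.maximum(np.diff(dead, prepend=dead[0]), 0.0)

    df_out = discount_factor(t, annual_rate, from_start)
    df_cost = discount_factor(t, annual_rate, from_start)

    trace = CohortTrace(
        cycle_length=cycle_length,
        pre=pre,
        post=post,
        dead=dead,
        new_deaths=new_deaths,
        new_progressions=new_prog,
        df_outcomes=np.atleast_1d(df_out),
        df_costs=np.atleast_1d(df_cost),
    )
    trace.check_conservation(conservation_atol)

    alive_at_horizon = float(pre[-1] + post[-1])
    if alive_at_horizon >= TRUNCATION_TOLERANCE:
        warnings.warn(
            f"{alive_at_horizon:.2%} of the cohort is still alive at the "
            f"{horizon}-month horizon; extend the horizon for a lifetime model",
            TruncationWarning,
            stacklevel=2,
        )
    return trace
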
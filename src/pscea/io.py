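"""Tabular input/output: pseudo-IPD tables, result files, trace exports.

All files are delimited text (CSV dialect, UTF-8, '.' decimal
separator). Result files round euros to 2 decimals and QALYs/life years
to 3, matching the presentation of the published base-case table.
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "IPDTable",
    "read_ipd",
    "write_ipd",
    "write_results",
    "read_results",
    "export_trace",
    "round_half_up_euro",
]

IPD_COLUMNS = ("time_months", "event")


def round_half_up_euro(value: float) -> int:
    """Round to the nearest euro with ties going up, for printed outputs."""
    return int(Decimal(repr(float(value))).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class IPDTable:
    """Pseudo individual-patient time-to-event data.

    ``time`` holds strictly positive follow-up times in months and
    ``event`` binary flags (1 = event observed, 0 = right-censored).
    """

    time: np.ndarray
    event: np.ndarray
    endpoint: str | None = None

    def __post_init__(self):
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event, dtype=int)
        if time.ndim != 1 or time.shape != event.shape:
            raise ValidationError("time and event must be equal-length 1-d arrays")
        if time.size < 1:
            raise ValidationError("IPD table must contain at least one record")
        if np.any(time <= 0):
            raise ValidationError("all times must be strictly positive")
        original = np.asarray(self.event)
        if not np.isin(original, (0, 1)).all():
            raise ValidationError("event flags must be 0 or 1")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event)

    @property
    def n(self) -> int:
        return int(self.time.size)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @property
    def n_censored(self) -> int:
        return self.n - self.n_events

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_months": self.time, "event": self.event})


def read_ipd(path, endpoint: str | None = None) -> IPDTable:
    """Read a two-column delimited IPD file (header row required)."""
    frame = pd.read_csv(path)
    missing = [c for c in IPD_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"IPD file {path} is missing required column(s) {missing}; "
            f"expected header with columns {IPD_COLUMNS}"
        )
    return IPDTable(frame["time_months"].to_numpy(),
                    frame["event"].to_numpy(), endpoint)


def write_ipd(table: IPDTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


_ARM_OUTCOMES = (
    ("cost_treatment_and_administration", "euro"),
    ("cost_adverse_events", "euro"),
    ("cost_pre_progression_background", "euro"),
    ("cost_post_progression_background", "euro"),
    ("cost_terminal_care", "euro"),
    ("total_cost", "euro"),
    ("qalys_pre", "qaly"),
    ("qalys_post", "qaly"),
    ("total_qalys", "qaly"),
    ("ly_pre_discounted", "qaly"),
    ("ly_post_discounted", "qaly"),
    ("ly_total_discounted", "qaly"),
    ("ly_pre_undiscounted", "qaly"),
    ("ly_post_undiscounted", "qaly"),
    ("ly_total_undiscounted", "qaly"),
)

_FORMATS = {"euro": "{:.2f}", "qaly": "{:.3f}"}


def _format(value, kind):
    if value is None:
        return ""
    return _FORMATS[kind].format(value)


def write_results(run, path) -> None:
    """Write a deterministic run as a long delimited table.

    One row per (arm, outcome) mirroring the base-case table's row
    structure, followed by one block per incremental comparison.
    """
    arm_results = getattr(run, "arm_results", None)
    incrementals = getattr(run, "incrementals", None)
    if not arm_results:
        raise ValidationError("cannot write an empty result set")
    rows = []
    for arm_id, result in arm_results.items():
        for outcome, kind in _ARM_OUTCOMES:
            rows.append(
                {"block": "arm", "name": arm_id, "outcome": outcome,
                 "value": _format(getattr(result, outcome), kind)}
            )
    for inc in incrementals or ():
        name = f"{inc.intervention}_vs_{inc.comparator}_{inc.effect_measure}"
        icer = "" if inc.icer is None else _FORMATS["euro"].format(inc.icer)
        rows += [
            {"block": "incremental", "name": name, "outcome": "delta_cost",
             "value": _FORMATS["euro"].format(inc.delta_cost)},
            {"block": "incremental", "name": name, "outcome": "delta_effect",
             "value": _FORMATS["qaly"].format(inc.delta_effect)},
            {"block": "incremental", "name": name, "outcome": "icer", "value": icer},
            {"block": "incremental", "name": name, "outcome": "label",
             "value": inc.label},
            {"block": "incremental", "name": name, "outcome": "quadrant",
             "value": inc.quadrant or ""},
        ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_results(path) -> pd.DataFrame:
    """Read a results file back; numeric values are parsed where possible."""
    frame = pd.read_csv(path, dtype={"value": str}, keep_default_na=False)
    missing = {"block", "name", "outcome", "value"} - set(frame.columns)
    if missing:
        raise SchemaError(f"results file {path} is missing columns {sorted(missing)}")
    frame["numeric"] = pd.to_numeric(frame["value"], errors="coerce")
    return frame


def export_trace(trace, path) -> None:
    """Dump a cohort trace as delimited text for audit."""
    trace.to_frame().to_csv(path, index=False)
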
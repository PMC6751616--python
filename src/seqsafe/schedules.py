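"""Per-analysis decision-threshold schedules.

Four families of decreasing threshold curves over the analysis index
``l = 1..L``, each (except the constant one) anchored so that the curve
passes exactly through ``(1, tau_first)`` and ``(L, tau_final)``:

- ``uniform``:      tau_l = tau_final for every l
- ``linear``:       tau_l = a*l + b
- ``exponential``:  tau_l = a*exp(l) + b
- ``logarithmic``:  tau_l = a*log(l) + b

Raw (unrounded) values are the decision contract; 3-decimal rounding is
presentation only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FAMILIES", "ThresholdSchedule", "ScheduleTable", "solve_schedule", "schedule_table"]

FAMILIES = ("uniform", "linear", "exponential", "logarithmic")


class IncreasingScheduleWarning(UserWarning):
    pass


@dataclass(frozen=True)
class ThresholdSchedule:
    family: str
    L: int
    tau_first: float
    tau_final: float
    values: tuple
    coefficients: tuple | None = None

    def __post_init__(self) -> None:
        values = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", values)
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if len(values) != self.L:
            raise ValueError("values length must equal L")
        if self.family != "uniform":
            if abs(values[0] - self.tau_first) > 1e-12:
                raise ValueError("first value must equal tau_first")
            if abs(values[-1] - self.tau_final) > 1e-12:
                raise ValueError("last value must equal tau_final")
            if self.tau_final < self.tau_first:
                diffs = np.diff(values)
                if np.any(diffs >= 0):
                    raise ValueError("decreasing schedule must be strictly decreasing")

    @property
    def rounded(self) -> tuple:
        """3-decimal presentation values (matches printed tables)."""
        return tuple(float(v) for v in np.round(self.values, 3))


def solve_schedule(
    family: str, L: int, tau_first: float, tau_final: float
) -> ThresholdSchedule:
    """Solve one family's coefficients through the two anchors and tabulate it."""
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    if L < 2:
        raise ValueError("need at least 2 analyses")
    for name, v in (("tau_first", tau_first), ("tau_final", tau_final)):
        if not 0.0 < v < 1.0:
            raise ValueError(f"{name} must lie strictly inside (0, 1)")
    if tau_final > tau_first:
        warnings.warn(
            "tau_final exceeds tau_first: schedule is increasing",
            IncreasingScheduleWarning,
        )
    l = np.arange(1, L + 1, dtype=float)
    if family == "uniform":
        values = np.full(L, tau_final)
        coefficients = None
    else:
        if family == "linear":
            basis = l
        elif family == "exponential":
            basis = np.exp(l)
        else:  # logarithmic
            basis = np.log(l)
        a = (tau_final - tau_first) / (basis[-1] - basis[0])
        b = tau_first - a * basis[0]
        values = a * basis + b
        values[0] = tau_first
        values[-1] = tau_final
        coefficients = (float(a), float(b))
    return ThresholdSchedule(
        family=family,
        L=L,
        tau_first=float(tau_first),
        tau_final=float(tau_final),
        values=tuple(values),
        coefficients=coefficients,
    )


@dataclass(frozen=True)
class ScheduleTable:
    """One solved schedule per event, same family/L/first anchor."""

    family: str
    L: int
    tau_first: float
    schedules: dict  # event_id -> ThresholdSchedule

    @property
    def event_ids(self) -> tuple:
        return tuple(self.schedules)

    def to_frame(self, rounded: bool = True) -> pd.DataFrame:
        data = {
            event: (s.rounded if rounded else s.values)
            for event, s in self.schedules.items()
        }
        frame = pd.DataFrame(data, index=pd.RangeIndex(1, self.L + 1, name="analysis"))
        return frame

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "L": self.L,
            "tau_first": self.tau_first,
            "tau_final_per_event": {
                event: s.tau_final for event, s in self.schedules.items()
            },
            "values": {event: list(s.values) for event, s in self.schedules.items()},
        }


def schedule_table(
    events, family: str = "exponential", L: int = 11, tau_first: float = 0.95
) -> ScheduleTable:
    """Solve one schedule per ``(event_id, tau_final)`` pair.

    Raises on duplicate event ids.
    """
    events = list(events)
    if not events:
        raise ValueError("need at least one event")
    ids = [e for e, _ in events]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate event_id in schedule table")
    schedules = {
        event: solve_schedule(family, L, tau_first, tau_final)
        for event, tau_final in events
    }
    return ScheduleTable(family=family, L=L, tau_first=float(tau_first), schedules=schedules)
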
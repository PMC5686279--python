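"""Dosing regimens: timed oral dose events in mg/kg.

A regimen is a sorted sequence of ``(time, dose)`` events with a compound
label.  Times are in days, doses in mg/kg body weight (the weight-normalized
convention usual for rodent oral gavage studies).  Clinical regimens given in
absolute mg are converted with :func:`regimen_from_mg`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError

__all__ = [
    "DosingRegimen",
    "daily_regimen",
    "repeated_cycle",
    "regimen_from_mg",
    "regimen_from_config",
    "regimen_to_config",
]


@dataclass(frozen=True)
class DosingRegimen:
    """Oral dose events ``(time [d], dose [mg/kg])`` for one subject.

    The empty event list is a valid regimen (vehicle arm).
    """

    events: tuple = field(default_factory=tuple)
    compound: str = "generic"

    def __post_init__(self):
        events = tuple((float(t), float(d)) for t, d in self.events)
        times = [t for t, _ in events]
        if any(t < 0 for t in times):
            raise InputError("dose event times must be non-negative")
        if any(d < 0 for _, d in events):
            raise InputError("doses must be non-negative")
        if sorted(times) != times:
            events = tuple(sorted(events, key=lambda e: e[0]))
        object.__setattr__(self, "events", events)

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.events], dtype=float)

    @property
    def doses(self) -> np.ndarray:
        return np.array([d for _, d in self.events], dtype=float)

    @property
    def total_dose(self) -> float:
        """Cumulative administered dose [mg/kg]."""
        return float(sum(d for _, d in self.events))

    def __len__(self) -> int:
        return len(self.events)

    def grouped_events(self) -> list:
        """Events with simultaneous doses summed into a single event."""
        merged: dict = {}
        for t, d in self.events:
            merged[t] = merged.get(t, 0.0) + d
        return sorted(merged.items())

    def shifted(self, dt: float) -> "DosingRegimen":
        return DosingRegimen(tuple((t + dt, d) for t, d in self.events), self.compound)

    def __add__(self, other: "DosingRegimen") -> "DosingRegimen":
        if other.compound != self.compound:
            raise InputError("cannot combine regimens of different compounds")
        return DosingRegimen(self.events + other.events, self.compound)


def daily_regimen(start_day: float, n_doses: int, dose: float,
                  interval: float = 1.0, compound: str = "generic") -> DosingRegimen:
    """``n_doses`` doses of ``dose`` mg/kg, one every ``interval`` days."""
    if n_doses < 0:
        raise InputError("n_doses must be >= 0")
    events = tuple((start_day + i * interval, dose) for i in range(n_doses))
    return DosingRegimen(events, compound)


def repeated_cycle(day_doses, n_cycles: int, cycle_length: float,
                   start_day: float = 0.0, compound: str = "generic") -> DosingRegimen:
    """Repeat a within-cycle schedule ``[(day_in_cycle, dose), ...]``.

    Used for pulsed schedules such as one loading dose followed by low
    daily doses in a fixed-length cycle.
    """
    events = []
    for c in range(n_cycles):
        for day, dose in day_doses:
            events.append((start_day + c * cycle_length + day, dose))
    return DosingRegimen(tuple(events), compound)


def regimen_from_mg(events_mg, body_weight: float, compound: str = "generic") -> DosingRegimen:
    """Convert absolute ``(time, dose [mg])`` events to mg/kg with a body weight [kg]."""
    if body_weight <= 0:
        raise InputError("body_weight must be positive")
    return DosingRegimen(tuple((t, mg / body_weight) for t, mg in events_mg), compound)


def regimen_from_config(block: dict) -> DosingRegimen:
    """Build a regimen from a config block.

    Two forms are accepted::

        {"events": [[t, dose], ...], "compound": "erlotinib"}
        {"start_day": 3, "n_doses": 14, "interval_days": 1, "dose_mg_per_kg": 100,
         "compound": "erlotinib"}
    """
    block = dict(block)
    compound = block.pop("compound", "generic")
    if "events" in block:
        events = block.pop("events")
        if block:
            raise InputError(f"unknown regimen keys: {sorted(block)}")
        return DosingRegimen(tuple((t, d) for t, d in events), compound)
    keys = {"start_day", "n_doses", "interval_days", "dose_mg_per_kg"}
    missing = keys - set(block)
    extra = set(block) - keys
    if missing or extra:
        raise InputError(
            f"regimen block needs keys {sorted(keys)}; missing {sorted(missing)}, "
            f"unknown {sorted(extra)}")
    return daily_regimen(block["start_day"], int(block["n_doses"]),
                         block["dose_mg_per_kg"], block["interval_days"], compound)


def regimen_to_config(regimen: DosingRegimen) -> dict:
    """Serialize a regimen to the explicit-events config form (round-trips)."""
    return {"events": [[t, d] for t, d in regimen.events],
            "compound": regimen.compound}
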
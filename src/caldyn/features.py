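"""Per-neuron, per-phase activity features: firing count, ISI mean, ISI CV.

The interspike interval (ISI) is the gap between consecutive detected events.
ISI mean = (1/n) * sum(ISI_i); ISI CV = sigma_ISI / mu_ISI with sigma_ISI the
population standard deviation (divisor n). The CV is scale-invariant and
measures firing irregularity: 0 for perfectly regular trains, ~1 for
Poisson-like trains.

Neurons with fewer than two events in a window have no defined ISI; such rows
are flagged ``isi_valid = False`` and carry documented sentinels (ISI mean =
window duration, CV = 0) so that near-silent neurons occupy their own region
of feature space when clustered rather than being dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .traces import EventTable

FEATURE_COLUMNS = ["f", "isi_mean_s", "isi_cv"]


@dataclass
class PhaseWindows:
    """Ordered analysis windows (phase_id, start_s, end_s), one per phase."""

    phases: list[tuple[str, float, float]]

    def __post_init__(self) -> None:
        prev_end = -np.inf
        ids = [p for p, _, _ in self.phases]
        if len(set(ids)) != len(ids):
            raise ValueError("phase ids must be unique")
        for pid, start, end in self.phases:
            if end <= start:
                raise ValueError(f"phase {pid}: end must exceed start")
            if start < prev_end:
                raise ValueError(f"phase {pid}: windows must be non-overlapping and increasing")
            prev_end = end

    @property
    def ids(self) -> list[str]:
        return [p for p, _, _ in self.phases]

    def to_json_obj(self) -> list[list]:
        return [[p, float(s), float(e)] for p, s, e in self.phases]

    @classmethod
    def from_json_obj(cls, obj) -> "PhaseWindows":
        return cls(phases=[(str(p), float(s), float(e)) for p, s, e in obj])


def _check_sorted(events: np.ndarray) -> np.ndarray:
    events = np.asarray(events, float)
    if events.size > 1 and np.any(np.diff(events) < 0):
        raise ValueError("event times must be sorted")
    return events


def firing_count(events: np.ndarray, window: tuple[float, float]) -> int:
    """Number of events in the half-open window [start, end).

    Half-open membership makes counts additive over a partition of a window.
    """
    events = _check_sorted(events)
    start, end = window
    if end <= start:
        raise ValueError("window end must exceed start")
    return int(np.searchsorted(events, end, side="left")
               - np.searchsorted(events, start, side="left"))


def isi_mean(events_in_window: np.ndarray, sentinel: float | None = None) -> tuple[float, bool]:
    """Mean inter-event interval; (value, valid).

    With < 2 events the ISI is undefined: returns ``sentinel`` (callers pass
    the window duration) with valid=False.
    """
    ev = _check_sorted(events_in_window)
    if ev.size < 2:
        return (float(sentinel) if sentinel is not None else float("nan")), False
    return float(np.mean(np.diff(ev))), True


def isi_cv(events_in_window: np.ndarray, ddof: int = 0) -> tuple[float, bool]:
    """Coefficient of variation of inter-event intervals; (value, valid).

    Standard deviation uses divisor n (``ddof=0``, population convention) so
    the two-event case is well-defined with CV 0. With < 2 events the CV is
    undefined: sentinel 0, valid=False.
    """
    ev = _check_sorted(events_in_window)
    if ev.size < 2:
        return 0.0, False
    isis = np.diff(ev)
    mu = float(np.mean(isis))
    if mu == 0:
        raise ValueError("coincident events: ISI mean is zero, CV undefined")
    return float(np.std(isis, ddof=ddof) / mu), True


def longest_interval(events_in_window: np.ndarray) -> tuple[float, bool]:
    """Longest inter-event interval (optional extra feature); (value, valid)."""
    ev = _check_sorted(events_in_window)
    if ev.size < 2:
        return 0.0, False
    return float(np.max(np.diff(ev))), True


def build_feature_table(events: EventTable, phases: PhaseWindows,
                        include_longest_interval: bool = False) -> pd.DataFrame:
    """One row per (neuron, phase) with firing count, ISI mean, ISI CV.

    All features are computed on events restricted to the phase's half-open
    window. Rows with < 2 events carry sentinels and ``isi_valid = False``.
    """
    rows = []
    for i, ev in enumerate(events.events):
        ev = _check_sorted(ev)
        for pid, start, end in phases.phases:
            lo = np.searchsorted(ev, start, side="left")
            hi = np.searchsorted(ev, end, side="left")
            sub = ev[lo:hi]
            f = int(hi - lo)
            mean_v, valid = isi_mean(sub, sentinel=end - start)
            cv_v, _ = isi_cv(sub)
            row = {"neuron_id": i, "phase": pid, "f": f,
                   "isi_mean_s": mean_v, "isi_cv": cv_v, "isi_valid": valid}
            if include_longest_interval:
                row["longest_interval_s"], _ = longest_interval(sub)
            rows.append(row)
    return pd.DataFrame(rows)
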
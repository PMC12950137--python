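"""Fluorescence trace processing: dF/F baseline normalization, calcium event
detection under a refractory rule, and region-level activity summaries."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks


@dataclass
class TraceMatrix:
    """A neurons x frames fluorescence matrix with its acquisition metadata.

    ``values`` holds raw fluorescence when ``is_dff`` is False (must be
    strictly positive so baseline division is defined) and fractional change
    (F - F0)/F0 when True. ``regions`` and ``mouse`` are optional per-neuron
    labels.
    """

    values: np.ndarray
    sampling_rate: float
    is_dff: bool = False
    regions: np.ndarray | None = None
    mouse: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] < 1:
            raise ValueError("values must be a neurons x frames matrix with >= 1 frame")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        for name in ("regions", "mouse"):
            lab = getattr(self, name)
            if lab is not None and len(lab) != self.n_neurons:
                raise ValueError(f"{name} must have one entry per neuron")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.sampling_rate


@dataclass
class EventTable:
    """Detected (or planted) event times, seconds, sorted per neuron."""

    events: list[np.ndarray]
    detection_params: dict = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return len(self.events)

    def counts(self) -> np.ndarray:
        return np.asarray([len(e) for e in self.events])

    def to_frame(self) -> pd.DataFrame:
        rows = [(i, t) for i, ev in enumerate(self.events) for t in ev]
        return pd.DataFrame(rows, columns=["neuron_id", "event_time_s"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, n_neurons: int,
                   detection_params: dict | None = None) -> "EventTable":
        events = [np.sort(df.loc[df["neuron_id"] == i, "event_time_s"].to_numpy(float))
                  for i in range(n_neurons)]
        return cls(events=events, detection_params=detection_params or {})


def compute_dff(traces: TraceMatrix, baseline_window_s: float = 100.0,
                baseline_percentile: float = 10.0) -> TraceMatrix:
    """dF/F = (F - F0)/F0 with a per-window percentile baseline.

    Frames are partitioned into consecutive non-overlapping windows of
    ``baseline_window_s`` aligned to frame 0 (a final partial window is
    allowed); within each window, F0 is the given percentile (linear
    interpolation between order statistics) of that neuron's fluorescence.
    """
    if traces.is_dff:
        raise ValueError("input is already dF/F")
    win = int(round(baseline_window_s * traces.sampling_rate))
    if win < 10:
        raise ValueError("baseline window must span at least 10 frames")
    F = traces.values
    out = np.empty_like(F)
    for start in range(0, traces.n_frames, win):
        chunk = F[:, start:start + win]
        f0 = np.percentile(chunk, baseline_percentile, axis=1, method="linear")
        bad = np.where(f0 <= 0)[0]
        if bad.size:
            raise ValueError(
                f"baseline F0 <= 0 for neuron {bad[0]} in window starting at frame "
                f"{start}; dF/F undefined for non-positive baselines"
            )
        out[:, start:start + win] = (chunk - f0[:, None]) / f0[:, None]
    return TraceMatrix(values=out, sampling_rate=traces.sampling_rate, is_dff=True,
                       regions=traces.regions, mouse=traces.mouse)


def _suppress_close_peaks(peaks: np.ndarray, heights: np.ndarray,
                          min_gap_frames: int) -> np.ndarray:
    """Greedy refractory suppression: visit peaks by descending height (ties ->
    earlier frame) and keep each one unless a kept peak lies closer than
    ``min_gap_frames``. Deterministic and order-independent."""
    order = np.lexsort((peaks, -heights))  # height desc, then frame asc
    kept: list[int] = []
    keep_mask = np.zeros(len(peaks), dtype=bool)
    for idx in order:
        p = peaks[idx]
        if all(abs(p - peaks[j]) >= min_gap_frames for j in kept):
            kept.append(idx)
            keep_mask[idx] = True
    return np.sort(peaks[keep_mask])


def detect_events(dff: TraceMatrix, min_separation_s: float = 0.8,
                  threshold_mad: float = 3.5) -> EventTable:
    """Peak-based calcium event detection with a refractory rule.

    Candidate events are local maxima of each neuron's dF/F trace exceeding
    ``median + threshold_mad * 1.4826 * MAD`` (a robust, per-neuron scale-free
    threshold). Peaks closer than ``min_separation_s`` are resolved greedily
    by descending amplitude, so at most one event is reported per refractory
    interval. Event time is the peak frame time.
    """
    if not dff.is_dff:
        raise ValueError("detect_events expects dF/F input; run compute_dff first")
    if dff.n_frames == 0:
        raise ValueError("empty trace")
    if min_separation_s < 1.0 / dff.sampling_rate:
        raise ValueError("min_separation_s must be at least one frame period")
    min_gap = int(np.ceil(min_separation_s * dff.sampling_rate))
    events: list[np.ndarray] = []
    for x in dff.values:
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        thr = med + threshold_mad * 1.4826 * mad
        peaks, props = find_peaks(x, height=thr)
        # `height` is an inclusive bound in find_peaks; require strict excess
        strict = props["peak_heights"] > thr
        peaks, heights = peaks[strict], props["peak_heights"][strict]
        kept = _suppress_close_peaks(peaks, heights, min_gap) if len(peaks) else peaks
        events.append(kept / dff.sampling_rate)
    return EventTable(
        events=events,
        detection_params={
            "threshold_rule": f"median + {threshold_mad} * 1.4826 * MAD",
            "threshold_mad": threshold_mad,
            "min_separation_s": min_separation_s,
        },
    )


def region_summary(dff: TraceMatrix, window_s: float = 100.0,
                   all_regions: list[str] | None = None) -> pd.DataFrame:
    """Mean dF/F per (region, time window).

    Windows are consecutive ``window_s`` blocks (``ceil(duration/window_s)``
    of them; e.g. a 1400-s recording at 100 s gives 14). Regions listed in
    ``all_regions`` but absent from the data yield NaN rows.
    """
    if dff.regions is None:
        raise ValueError("region labels required for region_summary")
    win = int(round(window_s * dff.sampling_rate))
    n_win = int(np.ceil(dff.n_frames / win))
    regions = np.asarray(dff.regions)
    uniq = list(dict.fromkeys(regions.tolist()))
    rows = {}
    for reg in uniq:
        mask = regions == reg
        rows[reg] = [float(dff.values[mask, s:s + win].mean())
                     for s in range(0, dff.n_frames, win)]
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=[f"window_{w}" for w in range(n_win)])
    df.index.name = "region"
    if all_regions is not None:
        df = df.reindex(all_regions)
    return df
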
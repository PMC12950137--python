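"""Readers and writers for the pipeline's on-disk formats.

TraceMatrix lives in HDF5 (`traces` float32 neurons x frames, `regions`,
`mouse`, attrs `sampling_rate_hz`, `is_dff`); events and feature/label tables
in CSV; segmentation results and phase windows in JSON. HDF5 objects are
created with ``track_times=False`` so identical runs produce byte-identical
files.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .features import PhaseWindows
from .segmentation import SegmentationResult
from .traces import EventTable, TraceMatrix


def write_traces_h5(traces: TraceMatrix, path) -> None:
    with h5py.File(path, "w") as fh:
        d = fh.create_dataset("traces", data=traces.values.astype(np.float32),
                              track_times=False)
        d.attrs["sampling_rate_hz"] = float(traces.sampling_rate)
        d.attrs["is_dff"] = bool(traces.is_dff)
        if traces.regions is not None:
            fh.create_dataset("regions",
                              data=np.asarray(traces.regions, dtype="S"),
                              track_times=False)
        if traces.mouse is not None:
            fh.create_dataset("mouse", data=np.asarray(traces.mouse, np.int32),
                              track_times=False)


def read_traces_h5(path) -> TraceMatrix:
    with h5py.File(path, "r") as fh:
        d = fh["traces"]
        values = d[()].astype(np.float64)
        fs = float(d.attrs["sampling_rate_hz"])
        is_dff = bool(d.attrs.get("is_dff", False))
        regions = (np.asarray([r.decode() for r in fh["regions"][()]], dtype=object)
                   if "regions" in fh else None)
        mouse = fh["mouse"][()].astype(int) if "mouse" in fh else None
    return TraceMatrix(values=values, sampling_rate=fs, is_dff=is_dff,
                       regions=regions, mouse=mouse)


def write_traces_csv(traces: TraceMatrix, path) -> None:
    """One row per neuron, frames as columns (wide; for small exports only)."""
    df = pd.DataFrame(traces.values)
    df.insert(0, "neuron_id", np.arange(traces.n_neurons))
    if traces.regions is not None:
        df.insert(1, "region", traces.regions)
    df.to_csv(path, index=False)


def write_events_csv(events: EventTable, path) -> None:
    events.to_frame().to_csv(path, index=False, float_format="%.6f")


def read_events_csv(path, n_neurons: int) -> EventTable:
    df = pd.read_csv(path)
    return EventTable.from_frame(df, n_neurons)


def write_events_json(events: EventTable, path) -> None:
    obj = {"detection_params": events.detection_params,
           "events": [list(map(float, ev)) for ev in events.events]}
    with open(path, "w") as fh:
        json.dump(obj, fh)


def write_segmentation_json(result: SegmentationResult, path) -> None:
    obj = {
        "k": int(result.k),
        "labels": [int(x) for x in result.labels],
        "merge_tree": [[int(a), int(b), float(h)] for a, b, h in result.merge_tree],
        "within_class_curve": {str(k): float(v)
                               for k, v in result.within_class_curve.items()},
        "selected_k_curve": result.selected_k_curve,
        "intercluster_means": (None if result.intercluster_means is None
                               else np.asarray(result.intercluster_means).tolist()),
        "intracluster_distances": {str(k): [float(x) for x in v]
                                   for k, v in result.intracluster_distances.items()},
    }
    with open(path, "w") as fh:
        json.dump(obj, fh)


def read_segmentation_json(path) -> SegmentationResult:
    with open(path) as fh:
        obj = json.load(fh)
    return SegmentationResult(
        labels=np.asarray(obj["labels"], int),
        k=int(obj["k"]),
        merge_tree=[(int(a), int(b), float(h)) for a, b, h in obj["merge_tree"]],
        within_class_curve={int(k): float(v)
                            for k, v in obj["within_class_curve"].items()},
        intercluster_means=(None if obj["intercluster_means"] is None
                            else np.asarray(obj["intercluster_means"], float)),
        intracluster_distances={int(k): np.asarray(v, float)
                                for k, v in obj["intracluster_distances"].items()},
        selected_k_curve=obj.get("selected_k_curve"),
    )


def write_phases_json(phases: PhaseWindows, path) -> None:
    with open(path, "w") as fh:
        json.dump(phases.to_json_obj(), fh)


def read_phases_json(path) -> PhaseWindows:
    with open(path) as fh:
        return PhaseWindows.from_json_obj(json.load(fh))


def write_distance_csv(D: np.ndarray, path) -> None:
    pd.DataFrame(np.asarray(D)).to_csv(path, index=False, float_format="%.10g")


def read_distance_csv(path) -> np.ndarray:
    return pd.read_csv(path).to_numpy(np.float64)
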
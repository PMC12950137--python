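"""End-to-end orchestration: simulate -> dF/F -> detect -> segment -> features
-> classify -> dynamics, with every intermediate persisted and a manifest
recording parameters, derived seeds, and per-file checksums.

A single global seed deterministically derives per-stage seeds through
``numpy.random.SeedSequence(global_seed, spawn_key=(stage_index,))`` so any
stage can be reproduced in isolation; two runs with the same config are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import classify, dynamics, io, segmentation
from .simulate import (GroundTruth, config_from_dict, config_to_dict,
                       simulate as run_simulation)
from .features import build_feature_table
from .traces import compute_dff, detect_events, region_summary

logger = logging.getLogger(__name__)

#: Stage order; indexes feed seed derivation.
STAGES = ("simulate", "dff", "detect", "segment", "features", "classify", "dynamics")


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run (archived beside its outputs)."""

    out_dir: str = "run"
    input_h5: str | None = None            # None -> simulate
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides
    baseline_window_s: float = 100.0
    baseline_percentile: float = 10.0
    min_separation_s: float = 0.8
    threshold_mad: float = 3.5
    window_frames: int = 100
    variance_target: float = 0.96
    dtw_band: int | None = None
    k_max: int = 10
    k_temporal: int | None = None          # None -> elbow choice
    phase_len_s: float = 100.0
    k_neuron: int = 3
    kmeans_restarts: int = 10
    kmeans_k_range: tuple[int, int] = (2, 8)
    n_membership_track: int = 500
    per_mouse_proportions: bool = True
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "kmeans_k_range" in d:
            d["kmeans_k_range"] = tuple(d["kmeans_k_range"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["kmeans_k_range"] = list(self.kmeans_k_range)
        return d

    def stage_seed(self, stage: str) -> int:
        idx = STAGES.index(stage)
        ss = np.random.SeedSequence(self.seed, spawn_key=(idx,))
        return int(ss.generate_state(1)[0] % (2 ** 31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig, resume: bool = False) -> Path:
    """Execute the full pipeline; returns the run directory.

    With ``resume``, stages whose output files already exist are loaded
    instead of recomputed; the final outputs are identical to a fresh run
    because every stage is deterministic given its inputs and derived seed.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def have(*names: str) -> bool:
        return resume and all((out / n).exists() for n in names)

    # -- stage 1: input traces (simulated or loaded) -------------------
    truth = None
    if config.input_h5 is not None:
        traces = io.read_traces_h5(config.input_h5)
    else:
        sim_cfg = config_from_dict(
            {"seed": config.stage_seed("simulate"), **config.simulation})
        if have("raw.h5", "truth.json"):
            traces = io.read_traces_h5(out / "raw.h5")
            truth = GroundTruth.from_json(out / "truth.json")
        else:
            traces, truth = run_simulation(sim_cfg)
            io.write_traces_h5(traces, out / "raw.h5")
            truth.to_json(out / "truth.json")
        (out / "sim_config.json").write_text(
            json.dumps(config_to_dict(sim_cfg), sort_keys=True))

    # -- stage 2: dF/F -------------------------------------------------
    try:
        if have("dff.h5"):
            dff = io.read_traces_h5(out / "dff.h5")
        else:
            dff = (traces if traces.is_dff
                   else compute_dff(traces, config.baseline_window_s,
                                    config.baseline_percentile))
            io.write_traces_h5(dff, out / "dff.h5")
        if dff.regions is not None:
            region_summary(dff).to_csv(out / "region_dff.csv", float_format="%.8g")
    except Exception as exc:
        raise RuntimeError(f"stage 'dff' failed ({exc})") from exc

    # -- stage 3: event detection --------------------------------------
    try:
        if have("events.csv"):
            events = io.read_events_csv(out / "events.csv", dff.n_neurons)
        else:
            events = detect_events(dff, config.min_separation_s, config.threshold_mad)
            io.write_events_csv(events, out / "events.csv")
    except Exception as exc:
        raise RuntimeError(f"stage 'detect' failed ({exc})") from exc

    # -- stage 4: temporal segmentation --------------------------------
    try:
        if have("segmentation.json", "dtw_distances.csv"):
            seg = io.read_segmentation_json(out / "segmentation.json")
            window_s = config.window_frames / dff.sampling_rate
        else:
            basis = segmentation.fit_projection(dff, config.variance_target)
            scores = segmentation.project(dff, basis)
            ws = segmentation.make_windows(scores, config.window_frames, dff.sampling_rate)
            window_s = ws.window_s
            dmat = segmentation.pairwise_dtw(ws, band=config.dtw_band)
            io.write_distance_csv(dmat.D, out / "dtw_distances.csv")
            curve, merges = segmentation.within_class_curve(dmat, k_max=config.k_max)
            k_rec = segmentation.select_k_elbow(curve)
            k_used = config.k_temporal or k_rec
            seg = segmentation.average_linkage(dmat, k_used)
            seg.within_class_curve = curve
            seg.selected_k_curve = k_rec
            inter, intra = segmentation.cluster_distance_summaries(dmat, seg.labels)
            seg.intercluster_means, seg.intracluster_distances = inter, intra
            io.write_segmentation_json(seg, out / "segmentation.json")
        phases = segmentation.select_phase_windows(
            seg.labels, window_s=window_s, phase_len_s=config.phase_len_s)
        io.write_phases_json(phases, out / "phases.json")
    except Exception as exc:
        raise RuntimeError(f"stage 'segment' failed ({exc})") from exc

    # -- stage 5: features ---------------------------------------------
    try:
        features = build_feature_table(events, phases)
        features.to_csv(out / "features.csv", index=False, float_format="%.8g")
    except Exception as exc:
        raise RuntimeError(f"stage 'features' failed ({exc})") from exc

    # -- stage 6: classification ---------------------------------------
    try:
        Z = classify.standardize(features)
        kseed = config.stage_seed("classify")
        lo, hi = config.kmeans_k_range
        k_rec_n, sse_curve, sil_curve = classify.select_k(
            Z, range(lo, hi + 1), n_restarts=config.kmeans_restarts, seed=kseed)
        km = classify.fit_kmeans(Z, config.k_neuron, n_restarts=config.kmeans_restarts,
                                 seed=kseed, compute_silhouette=True)
        semantic = classify.assign_semantic_labels(km, features)
        labels = classify.label_table(km, Z, semantic)
        if dff.mouse is not None:
            labels["mouse"] = dff.mouse[labels["neuron_id"].to_numpy()]
        if dff.regions is not None:
            labels["region"] = dff.regions[labels["neuron_id"].to_numpy()]
        labels.to_csv(out / "clusters.csv", index=False)
        (out / "kmeans.json").write_text(json.dumps({
            "k": km.k, "sse": km.sse, "silhouette": km.silhouette,
            "recommended_k_elbow": int(k_rec_n),
            "sse_curve": {str(k): v for k, v in sse_curve.items()},
            "silhouette_curve": {str(k): v for k, v in sil_curve.items()},
            "centroids_standardized": km.centroids.tolist(),
            "semantic": {str(c): s for c, s in semantic.items()},
            "seed": kseed, "n_restarts": km.n_restarts}, sort_keys=True))
    except Exception as exc:
        raise RuntimeError(f"stage 'classify' failed ({exc})") from exc

    # -- stage 7: phase dynamics ---------------------------------------
    try:
        per_mouse = config.per_mouse_proportions and "mouse" in labels.columns
        comp = dynamics.cluster_proportions(labels, per_mouse=per_mouse,
                                            cluster_col="semantic")
        comp.proportions.to_csv(out / "proportions.csv", float_format="%.8g")
        comp.counts.to_csv(out / "counts.csv")
        dynamics.relative_change_rates(comp).to_csv(out / "change_rates.csv",
                                                    float_format="%.8g")
        for (pa, pb), tm in dynamics.transition_matrices(labels).items():
            tm.T.to_csv(out / f"transitions_{pa}{pb}.csv", float_format="%.8g")
        if "region" in labels.columns:
            dynamics.region_proportions(labels, cluster_col="semantic").to_csv(
                out / "region_proportions.csv", index=False, float_format="%.8g")
        n_track = min(config.n_membership_track, labels["neuron_id"].nunique())
        dynamics.membership_track(labels, n_show=n_track,
                                  seed=config.stage_seed("dynamics"),
                                  cluster_col="cluster").to_csv(out / "membership_track.csv")
    except Exception as exc:
        raise RuntimeError(f"stage 'dynamics' failed ({exc})") from exc

    # -- manifest -------------------------------------------------------
    from . import __version__
    files = sorted(p.name for p in out.iterdir()
                   if p.is_file() and p.name != "manifest.json")
    manifest = {
        "caldyn_version": __version__,
        "config": config.to_dict(),
        "stage_seeds": {s: config.stage_seed(s) for s in STAGES},
        "checksums": {name: _sha256(out / name) for name in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return out


def render_report(run_dir) -> str:
    """Plain-text summary of a finished run (proportions, change rates,
    transition matrices)."""
    import pandas as pd
    run_dir = Path(run_dir)
    parts = ["caldyn run report", "=" * 60]
    prop = pd.read_csv(run_dir / "proportions.csv", index_col=0)
    parts += ["", "Cluster proportions per phase:", prop.round(4).to_string()]
    rates = pd.read_csv(run_dir / "change_rates.csv", index_col=0)
    parts += ["", "Relative change rate (%) vs P1:", rates.round(2).to_string()]
    for f in sorted(run_dir.glob("transitions_*.csv")):
        tm = pd.read_csv(f, index_col=0)
        parts += ["", f"Transition probabilities {f.stem.replace('transitions_', '')}:",
                  tm.round(3).to_string()]
    return "\n".join(parts) + "\n"
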
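"""Phase-wise cluster composition, relative change rates, transition matrices,
and region-wise composition.

Input is the long-format label table produced by the classifier: one row per
(neuron, phase) with a cluster assignment, plus optional per-neuron mouse and
region labels. Proportions can be pooled over all neurons or computed within
each mouse and then averaged (unweighted) across mice; the two differ whenever
mice contribute unequal neuron counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class PhaseComposition:
    proportions: pd.DataFrame   # phase x cluster fractions
    counts: pd.DataFrame        # phase x cluster neuron counts (pooled)
    per_mouse: bool


def _check_complete(labels: pd.DataFrame) -> tuple[list, list]:
    phases = list(dict.fromkeys(labels["phase"]))
    neurons = sorted(labels["neuron_id"].unique())
    pivot = labels.pivot_table(index="neuron_id", columns="phase",
                               values="cluster", aggfunc="count")
    missing = pivot.reindex(index=neurons, columns=phases).isna()
    if missing.to_numpy().any():
        bad = [int(i) for i in missing.index[missing.any(axis=1)][:10]]
        raise ValueError(f"neurons missing labels in some phase, e.g. {bad}")
    return phases, neurons


def cluster_proportions(labels: pd.DataFrame, per_mouse: bool = False,
                        cluster_col: str = "cluster") -> PhaseComposition:
    """Fraction of neurons per cluster per phase.

    With ``per_mouse`` the fraction is computed within each mouse and then
    averaged across mice with equal weight; the pooled counts are reported
    either way.
    """
    phases, _ = _check_complete(labels)
    clusters = sorted(labels[cluster_col].unique())
    counts = (labels.groupby(["phase", cluster_col]).size()
              .unstack(fill_value=0).reindex(index=phases, columns=clusters, fill_value=0))
    if per_mouse:
        if "mouse" not in labels.columns:
            raise ValueError("per_mouse proportions require a 'mouse' column")
        per = (labels.groupby(["mouse", "phase", cluster_col]).size()
               .unstack(fill_value=0).reindex(columns=clusters, fill_value=0))
        frac = per.div(per.sum(axis=1), axis=0)
        prop = frac.groupby("phase").mean().reindex(phases)
    else:
        prop = counts.div(counts.sum(axis=1), axis=0)
    prop.index.name = counts.index.name = "phase"
    return PhaseComposition(proportions=prop, counts=counts, per_mouse=per_mouse)


def relative_change_rate(pn: float, p1: float) -> float:
    """Percent change of a cluster's proportion vs the baseline phase:
    100 * (Pn - P1) / P1. Undefined (raises) for P1 = 0."""
    if p1 <= 0:
        raise ValueError("relative change rate undefined for zero baseline proportion")
    return 100.0 * (pn - p1) / p1


def relative_change_rates(composition: PhaseComposition,
                          baseline_phase: str | None = None) -> pd.DataFrame:
    """Per-cluster percent change vs the baseline (first) phase for every
    later phase. Clusters absent at baseline yield NaN with a flag column
    convention (NaN), not +/-inf."""
    prop = composition.proportions
    phases = list(prop.index)
    base = baseline_phase or phases[0]
    rows = {}
    for cluster in prop.columns:
        p1 = prop.loc[base, cluster]
        vals = {}
        for ph in phases:
            if ph == base:
                continue
            vals[ph] = (relative_change_rate(prop.loc[ph, cluster], p1)
                        if p1 > 0 else np.nan)
        rows[cluster] = vals
    out = pd.DataFrame(rows).T
    out.index.name = "cluster"
    return out


@dataclass
class TransitionMatrix:
    T: pd.DataFrame          # from-cluster x to-cluster probabilities
    counts: pd.DataFrame     # from-cluster x to-cluster neuron counts
    empty_rows: list         # from-clusters with zero neurons (not normalized)
    phase_from: str
    phase_to: str


def transition_matrix(labels_a: pd.Series | np.ndarray, labels_b,
                      clusters: list | None = None,
                      phase_from: str = "a", phase_to: str = "b") -> TransitionMatrix:
    """Empirical one-step cluster transition probabilities between two phases.

    ``counts[i, j]`` is the number of neurons labeled i in the first phase and
    j in the second (same neuron order in both inputs); rows are normalized to
    probabilities, except zero-count rows which are flagged and left at zero.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if len(a) != len(b):
        raise ValueError("both phases must label the same neuron set")
    if clusters is None:
        clusters = sorted(set(a.tolist()) | set(b.tolist()))
    counts = pd.DataFrame(0, index=clusters, columns=clusters, dtype=int)
    for i, j in zip(a, b):
        counts.loc[i, j] += 1
    row_sums = counts.sum(axis=1)
    empty = [c for c in clusters if row_sums[c] == 0]
    T = counts.astype(float)
    nonzero = row_sums > 0
    T.loc[nonzero] = T.loc[nonzero].div(row_sums[nonzero], axis=0)
    return TransitionMatrix(T=T, counts=counts, empty_rows=empty,
                            phase_from=phase_from, phase_to=phase_to)


def transition_matrices(labels: pd.DataFrame,
                        cluster_col: str = "semantic") -> dict[tuple[str, str], TransitionMatrix]:
    """Transition matrix for every consecutive phase pair."""
    phases, neurons = _check_complete(labels)
    wide = labels.pivot(index="neuron_id", columns="phase", values=cluster_col).loc[neurons]
    clusters = sorted(labels[cluster_col].unique())
    out = {}
    for pa, pb in zip(phases[:-1], phases[1:]):
        out[(pa, pb)] = transition_matrix(wide[pa], wide[pb], clusters=clusters,
                                          phase_from=pa, phase_to=pb)
    return out


def region_proportions(labels: pd.DataFrame,
                       cluster_col: str = "cluster") -> pd.DataFrame:
    """Within-region cluster fractions per phase, with region neuron counts.

    Long format: region, phase, cluster, fraction, n_region. Regions with no
    neurons are simply absent (missing rows, not zeros).
    """
    if "region" not in labels.columns:
        raise ValueError("region labels required")
    rows = []
    for (region, phase), grp in labels.groupby(["region", "phase"], sort=False):
        n = len(grp)
        fr = grp[cluster_col].value_counts(normalize=True)
        for cluster, frac in fr.items():
            rows.append({"region": region, "phase": phase, "cluster": cluster,
                         "fraction": float(frac), "n_region": n})
    out = pd.DataFrame(rows)
    phase_order = {p: i for i, p in enumerate(dict.fromkeys(labels["phase"]))}
    return out.sort_values(["region", "phase", "cluster"],
                           key=lambda s: s.map(phase_order) if s.name == "phase" else s
                           ).reset_index(drop=True)


def membership_track(labels: pd.DataFrame, n_show: int = 500, seed: int = 0,
                     cluster_col: str = "cluster") -> pd.DataFrame:
    """Per-phase cluster track for a seeded uniform subsample of neurons,
    ordered by first-phase label then neuron id (the raster behind a
    membership-change heatmap)."""
    phases, neurons = _check_complete(labels)
    if n_show > len(neurons):
        raise ValueError("n_show exceeds neuron count")
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(neurons, size=n_show, replace=False))
    wide = labels.pivot(index="neuron_id", columns="phase", values=cluster_col)
    wide = wide.loc[chosen, phases]
    wide = wide.sort_values([phases[0], "neuron_id"], kind="stable")
    return wide
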
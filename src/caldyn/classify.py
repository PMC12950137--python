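"""K-means classification of (neuron, phase) feature vectors into activity classes.

All (neuron, phase) rows from every phase enter a single pooled fit so that
cluster identities are comparable across phases — a prerequisite for
transition-matrix analysis. Features (firing count, ISI mean, ISI CV) are
z-scored per column first; counts, seconds, and a dimensionless ratio are
incommensurate, and an unscaled fit would be dominated by whichever column
happens to have the largest variance. Near-silent rows keep their documented
ISI sentinels: they form a distinct stratum of feature space and the
low-activity cluster emerges from the clustering itself rather than from a
pre-assignment rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from .features import FEATURE_COLUMNS

SEMANTIC_NAMES = ("low-activity", "moderate-activity", "high-activity")


@dataclass
class StandardizedFeatures:
    """Per-column z-scored feature matrix with the transform stored for inversion."""

    X: np.ndarray                    # rows x 3
    index: pd.DataFrame              # neuron_id, phase per row
    means: np.ndarray
    sds: np.ndarray
    constant_columns: list[str] = field(default_factory=list)

    def inverse(self, Z: np.ndarray) -> np.ndarray:
        return Z * self.sds + self.means


def standardize(features: pd.DataFrame) -> StandardizedFeatures:
    """Z-score the three feature columns; constant columns are left at zero
    and flagged rather than divided by a zero SD."""
    if len(features) < 2:
        raise ValueError("need at least 2 rows to standardize")
    X = features[FEATURE_COLUMNS].to_numpy(np.float64)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    constant = [FEATURE_COLUMNS[j] for j in range(X.shape[1]) if sds[j] == 0]
    safe = np.where(sds == 0, 1.0, sds)
    Z = (X - means) / safe
    return StandardizedFeatures(X=Z, index=features[["neuron_id", "phase"]].copy(),
                                means=means, sds=np.where(sds == 0, 1.0, sds),
                                constant_columns=constant)


@dataclass
class KMeansResult:
    k: int
    centroids: np.ndarray            # k x n_features, standardized space
    labels: np.ndarray               # per-row cluster id, 0..k-1
    sse: float
    silhouette: float | None
    n_restarts: int
    seed: int


def _lloyd(X: np.ndarray, k: int, rng: np.random.Generator,
           max_iter: int = 300) -> tuple[np.ndarray, np.ndarray, float]:
    """One run of Lloyd's algorithm.

    Initialization samples k distinct rows uniformly; iteration stops when
    assignments no longer change; an emptied cluster is reseeded to the point
    farthest from its assigned centroid. The within-cluster SSE is verified to
    be non-increasing across iterations.
    """
    n = X.shape[0]
    centroids = X[rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1)
    prev_sse = np.inf
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        sse = float(d2[np.arange(n), new_labels].sum())
        if sse > prev_sse + 1e-8 * max(1.0, prev_sse):
            raise AssertionError("Lloyd SSE increased; implementation error")
        if np.array_equal(new_labels, labels):
            labels = new_labels
            break
        labels = new_labels
        prev_sse = sse
        for c in range(k):
            mask = labels == c
            if mask.any():
                centroids[c] = X[mask].mean(axis=0)
            else:
                far = int(d2[np.arange(n), labels].argmax())
                centroids[c] = X[far]
                labels[far] = c
    d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    sse = float(d2[np.arange(n), labels].sum())
    return labels, centroids, sse


def fit_kmeans(X: StandardizedFeatures | np.ndarray, k: int, n_restarts: int = 10,
               seed: int = 0, compute_silhouette: bool = False,
               silhouette_max_rows: int = 5000) -> KMeansResult:
    """Best of ``n_restarts`` Lloyd runs by SSE; deterministic given the seed.

    The silhouette, when requested, is computed on a seeded subsample of at
    most ``silhouette_max_rows`` rows to keep the O(n^2) cost bounded.
    """
    Z = X.X if isinstance(X, StandardizedFeatures) else np.asarray(X, np.float64)
    n = Z.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of rows {n}")
    ss = np.random.SeedSequence(seed)
    best = None
    for child in ss.spawn(n_restarts):
        labels, centroids, sse = _lloyd(Z, k, np.random.default_rng(child))
        if best is None or sse < best[2]:
            best = (labels, centroids, sse)
    labels, centroids, sse = best
    # invariant: labels are the nearest-centroid assignment at convergence
    d2 = ((Z[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    assert np.array_equal(labels, d2.argmin(axis=1))
    sil = None
    if compute_silhouette and k > 1:
        sample = min(silhouette_max_rows, n)
        sil = float(silhouette_score(
            Z, labels, sample_size=sample if sample < n else None,
            random_state=int(ss.generate_state(1)[0] % (2 ** 31))))
    return KMeansResult(k=k, centroids=centroids, labels=labels, sse=sse,
                        silhouette=sil, n_restarts=n_restarts, seed=seed)


def select_k(X: StandardizedFeatures | np.ndarray, k_range=range(2, 9),
             n_restarts: int = 10, seed: int = 0,
             override: int | None = None):
    """SSE and mean silhouette per k, with the SSE-elbow recommendation.

    The recommended k maximizes the discrete second difference of the SSE
    curve over interior k (ties -> smallest); the silhouette curve is
    reported alongside so a caller can override (silhouette often favors a
    coarser split than the elbow).
    Returns (k, sse_curve, silhouette_curve) as (int, dict, dict).
    """
    ks = sorted(k_range)
    if len(ks) < 3:
        raise ValueError("k_range must contain at least 3 values")
    sse_curve: dict[int, float] = {}
    sil_curve: dict[int, float] = {}
    for k in ks:
        res = fit_kmeans(X, k, n_restarts=n_restarts, seed=seed, compute_silhouette=True)
        sse_curve[k] = res.sse
        sil_curve[k] = res.silhouette
    if override is not None:
        return int(override), sse_curve, sil_curve
    W = np.asarray([sse_curve[k] for k in ks])
    d2 = W[:-2] - 2 * W[1:-1] + W[2:]
    rec = ks[1 + int(np.argmax(d2))]
    return rec, sse_curve, sil_curve


def assign_semantic_labels(result: KMeansResult,
                           features: pd.DataFrame) -> dict[int, str]:
    """Name the k=3 clusters low/moderate/high by mean firing count.

    Clusters are ranked by their mean firing count in original units (from
    the feature table rows assigned to each cluster); the ranking is invariant
    to cluster id permutations.
    """
    if result.k != 3:
        raise ValueError("semantic labels are defined only for k = 3")
    f = features["f"].to_numpy(np.float64)
    if len(f) != len(result.labels):
        raise ValueError("feature table and clustering have different row counts")
    mean_f = {c: float(f[result.labels == c].mean()) for c in range(3)}
    ranked = sorted(mean_f, key=lambda c: mean_f[c])
    return {c: SEMANTIC_NAMES[rank] for rank, c in enumerate(ranked)}


def label_table(result: KMeansResult, X: StandardizedFeatures,
                semantic: dict[int, str] | None = None) -> pd.DataFrame:
    """Long-format (neuron_id, phase, cluster, semantic) table; cluster ids 1-based."""
    df = X.index.copy()
    df["cluster"] = result.labels + 1
    if semantic is not None:
        df["semantic"] = [semantic[c] for c in result.labels]
    return df
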
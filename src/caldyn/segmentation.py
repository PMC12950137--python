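"""Unbiased temporal segmentation of population activity.

The recording is cut into fixed-length frame windows; population activity is
projected onto a shared principal-component basis fitted over the whole
recording (retaining enough components to explain a target fraction of
variance); dynamic time warping (DTW) quantifies dissimilarity between every
pair of projected windows; average-linkage agglomerative clustering of the
DTW distance matrix groups windows into activity classes; and the number of
classes is chosen at the knee (maximum discrete curvature) of the
within-class distance-sum curve.

A shared PCA basis is used (rather than one basis per window) so that every
window lives in the same coordinate system and inter-window DTW distances are
well-defined; an alternative "flat" mode that PCA-reduces flattened window
vectors and warps the scalar coefficient sequences is provided for
comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .features import PhaseWindows
from .traces import TraceMatrix

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# PCA projection
# --------------------------------------------------------------------------

@dataclass
class ProjectionBasis:
    """Shared principal-component basis over the neuron dimension."""

    loadings: np.ndarray          # neurons x C, orthonormal columns
    offsets: np.ndarray           # per-neuron centering means
    explained_variance_ratio: np.ndarray  # C values, of total variance
    variance_target: float

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def fit_projection(dff: TraceMatrix, variance_target: float = 0.96) -> ProjectionBasis:
    """Fit a shared PCA basis on frames x neurons data.

    Keeps the smallest number of leading components whose cumulative explained
    variance reaches ``variance_target``. Component signs are fixed by making
    each loading vector's largest-magnitude entry positive, so the basis is
    deterministic.
    """
    if not 0.0 < variance_target <= 1.0:
        raise ValueError("variance_target must be in (0, 1]")
    if dff.n_frames < 2:
        raise ValueError("need at least 2 frames to fit a projection")
    X = dff.values.T.astype(np.float64)            # frames x neurons
    offsets = X.mean(axis=0)
    Xc = X - offsets
    # economy SVD: Xc = U S Vt, loadings are rows of Vt
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s ** 2
    total = var.sum()
    if total == 0:
        raise ValueError("data has zero variance; nothing to project")
    ratio = var / total
    cum = np.cumsum(ratio)
    C = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    C = min(C, len(ratio))
    W = Vt[:C].T.copy()                            # neurons x C
    # sign convention: largest-magnitude loading entry positive
    for j in range(C):
        imax = int(np.argmax(np.abs(W[:, j])))
        if W[imax, j] < 0:
            W[:, j] = -W[:, j]
    return ProjectionBasis(loadings=W, offsets=offsets,
                           explained_variance_ratio=ratio[:C],
                           variance_target=variance_target)


def project(dff: TraceMatrix, basis: ProjectionBasis) -> np.ndarray:
    """Project traces onto the basis; returns frames x C component scores."""
    X = dff.values.T.astype(np.float64)
    return (X - basis.offsets) @ basis.loadings


@dataclass
class WindowSet:
    """Contiguous uniform-length windows of a projected recording.

    ``series`` has shape (n_windows, C, window_frames); trailing frames that
    do not fill a window are dropped. ``flat_mode`` marks windows built from
    PCA-reduced flattened window vectors instead of a shared basis.
    """

    series: np.ndarray
    window_frames: int
    sampling_rate: float
    flat_mode: bool = False

    @property
    def n_windows(self) -> int:
        return self.series.shape[0]

    @property
    def window_s(self) -> float:
        return self.window_frames / self.sampling_rate

    def frame_range(self, w: int) -> tuple[int, int]:
        return w * self.window_frames, (w + 1) * self.window_frames


def make_windows(scores: np.ndarray, window_frames: int,
                 sampling_rate: float) -> WindowSet:
    """Cut frames x C component scores into (n_windows, C, window_frames)."""
    n_frames, C = scores.shape
    n_win = n_frames // window_frames
    if n_win < 1:
        raise ValueError("recording shorter than one window")
    dropped = n_frames - n_win * window_frames
    if dropped:
        logger.info("dropping %d trailing frames not filling a window", dropped)
    trimmed = scores[: n_win * window_frames]
    series = trimmed.reshape(n_win, window_frames, C).transpose(0, 2, 1)
    return WindowSet(series=np.ascontiguousarray(series),
                     window_frames=window_frames, sampling_rate=sampling_rate)


def make_windows_flat(dff: TraceMatrix, window_frames: int,
                      variance_target: float = 0.96) -> WindowSet:
    """Alternative windowing: flatten each window (neurons*frames vector),
    PCA-reduce across windows, and treat each window's coefficient vector as a
    scalar sequence for DTW. Provided for comparison with the shared-basis
    default; the coefficient sequence has no temporal axis, so warping acts on
    component index instead of time."""
    n_frames = dff.n_frames
    n_win = n_frames // window_frames
    if n_win < 2:
        raise ValueError("need at least 2 windows")
    flat = dff.values[:, : n_win * window_frames]
    flat = flat.reshape(dff.n_neurons, n_win, window_frames)
    flat = flat.transpose(1, 0, 2).reshape(n_win, -1)   # windows x (neurons*frames)
    mu = flat.mean(axis=0)
    Xc = flat - mu
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s ** 2
    ratio = var / var.sum()
    C = int(np.searchsorted(np.cumsum(ratio), variance_target - 1e-12) + 1)
    C = min(C, len(ratio))
    coeffs = Xc @ Vt[:C].T                              # windows x C
    series = coeffs[:, None, :]                         # 1 channel, length C
    return WindowSet(series=np.ascontiguousarray(series), window_frames=window_frames,
                     sampling_rate=dff.sampling_rate, flat_mode=True)


# --------------------------------------------------------------------------
# DTW
# --------------------------------------------------------------------------

@njit(cache=False)
def _dtw_from_cost(cost: np.ndarray, band: int) -> float:  # pragma: no cover - jitted
    n, m = cost.shape
    INF = np.inf
    g = np.full((n, m), INF)
    for i in range(n):
        if band >= 0 and n > 1:
            center = i * (m - 1) / (n - 1) if n > 1 else 0.0
            jlo = max(0, int(np.ceil(center - band)))
            jhi = min(m - 1, int(np.floor(center + band)))
        else:
            jlo, jhi = 0, m - 1
        for j in range(jlo, jhi + 1):
            c = cost[i, j]
            if i == 0 and j == 0:
                g[i, j] = c
            else:
                best = INF
                if i > 0 and g[i - 1, j] < best:
                    best = g[i - 1, j]
                if j > 0 and g[i, j - 1] < best:
                    best = g[i, j - 1]
                if i > 0 and j > 0 and g[i - 1, j - 1] < best:
                    best = g[i - 1, j - 1]
                g[i, j] = c + best
    return g[n - 1, m - 1]


def _cost_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances between column vectors of a (C x La) and
    b (C x Lb)."""
    aa = np.sum(a * a, axis=0)
    bb = np.sum(b * b, axis=0)
    sq = aa[:, None] + bb[None, :] - 2.0 * (a.T @ b)
    # the expansion cancels catastrophically for (near-)identical columns;
    # clamp anything below float cancellation noise to an exact zero
    scale = aa[:, None] + bb[None, :]
    sq[sq < 1e-12 * scale] = 0.0
    np.maximum(sq, 0.0, out=sq)
    return np.sqrt(sq)


def dtw_distance(a: np.ndarray, b: np.ndarray, band: int | None = None) -> float:
    """Classic dynamic-programming DTW between multichannel series.

    ``a`` and ``b`` are channels x length arrays with matching channel count.
    Local cost is the Euclidean distance between column vectors; steps are the
    symmetric (1,1), (1,0), (0,1) pattern with no weighting and no path-length
    normalization. ``band`` is an optional Sakoe-Chiba half-width in samples
    (None = unconstrained). DTW is symmetric and nonnegative with
    dtw(x, x) = 0, but is not a metric: the triangle inequality can fail.
    """
    a = np.atleast_2d(np.asarray(a, np.float64))
    b = np.atleast_2d(np.asarray(b, np.float64))
    if a.shape[0] != b.shape[0]:
        raise ValueError(f"channel mismatch: {a.shape[0]} vs {b.shape[0]}")
    if a.shape[1] == 0 or b.shape[1] == 0:
        raise ValueError("empty series")
    cost = _cost_matrix(a, b)
    return float(_dtw_from_cost(cost, -1 if band is None else int(band)))


@dataclass
class SegmentDistanceMatrix:
    """Symmetric nonnegative windows x windows DTW distance matrix."""

    D: np.ndarray
    window_s: float

    def __post_init__(self) -> None:
        D = np.asarray(self.D, np.float64)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("D must be square")
        if not np.allclose(D, D.T, atol=1e-10):
            raise ValueError("D must be symmetric")
        if (D < 0).any():
            raise ValueError("D must be nonnegative")
        self.D = D

    @property
    def n_windows(self) -> int:
        return self.D.shape[0]


def pairwise_dtw(ws: WindowSet, band: int | None = None) -> SegmentDistanceMatrix:
    """DTW distance between every unordered pair of windows.

    Each pair is computed once; the diagonal is zero and the matrix symmetric
    by construction. For n windows this is n(n-1)/2 DTW evaluations (9,730
    for a 1400-s recording at 10 Hz with 100-frame windows).
    """
    n = ws.n_windows
    if n < 2:
        raise ValueError("need at least 2 windows")
    b = -1 if band is None else int(band)
    S = ws.series
    sq = np.sum(S * S, axis=1)                      # (n, L) squared column norms
    D = np.zeros((n, n), dtype=np.float64)
    for i in range(n):
        Ai = S[i]                                   # C x L
        for j in range(i + 1, n):
            g = Ai.T @ S[j]
            c2 = sq[i][:, None] + sq[j][None, :] - 2.0 * g
            scale = sq[i][:, None] + sq[j][None, :]
            c2[c2 < 1e-12 * scale] = 0.0
            np.maximum(c2, 0.0, out=c2)
            d = _dtw_from_cost(np.sqrt(c2), b)
            D[i, j] = D[j, i] = d
    return SegmentDistanceMatrix(D=D, window_s=ws.window_s)


# --------------------------------------------------------------------------
# Average-linkage agglomeration
# --------------------------------------------------------------------------

@dataclass
class SegmentationResult:
    labels: np.ndarray                       # per-window class id, 1..k
    k: int
    merge_tree: list[tuple[int, int, float]]  # (repr_a, repr_b, height) per merge
    within_class_curve: dict[int, float] = field(default_factory=dict)
    intercluster_means: np.ndarray | None = None
    intracluster_distances: dict[int, np.ndarray] = field(default_factory=dict)
    selected_k_curve: int | None = None


def _agglomerate(D: np.ndarray):
    """Full average-linkage merge sequence on a precomputed dissimilarity.

    Maintains exact pairwise-distance sums between clusters so the merge
    height is always the mean of the original D entries across the two
    clusters (UPGMA on an arbitrary dissimilarity). Ties are broken by the
    smallest (i, j) pair of cluster representatives, a cluster's
    representative being its smallest member index. Returns the merge list
    [(repr_a, repr_b, height)] and the list of membership snapshots (one per
    cluster count n..1).
    """
    n = D.shape[0]
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    sums = {(i, j): float(D[i, j]) for i in range(n) for j in range(i + 1, n)}
    merges: list[tuple[int, int, float]] = []
    snapshots: list[dict[int, list[int]]] = [{k: v[:] for k, v in members.items()}]
    while len(members) > 1:
        best = None
        for (a, b), s in sums.items():
            mean = s / (len(members[a]) * len(members[b]))
            key = (mean, a, b)
            if best is None or key < best:
                best = key
        mean, a, b = best
        merges.append((a, b, mean))
        # merge b into a (a < b by construction of representative keys)
        for c in members:
            if c in (a, b):
                continue
            sums[(min(a, c), max(a, c))] = (
                sums[(min(a, c), max(a, c))] + sums.pop((min(b, c), max(b, c)))
            )
        sums.pop((a, b))
        members[a] = members[a] + members[b]
        del members[b]
        snapshots.append({k: v[:] for k, v in members.items()})
    return merges, snapshots


def average_linkage(D: SegmentDistanceMatrix | np.ndarray, k: int) -> SegmentationResult:
    """Cut the average-linkage hierarchy at ``k`` clusters.

    Labels are 1..k, numbered by each cluster's smallest window index.
    """
    M = D.D if isinstance(D, SegmentDistanceMatrix) else np.asarray(D, float)
    if M.ndim != 2 or M.shape[0] != M.shape[1] or not np.allclose(M, M.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    if (M < 0).any():
        raise ValueError("distance matrix must be nonnegative")
    n = M.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}")
    merges, snapshots = _agglomerate(M)
    labels = _labels_from_snapshot(snapshots[n - k], n)
    return SegmentationResult(labels=labels, k=k, merge_tree=merges)


def _labels_from_snapshot(snapshot: dict[int, list[int]], n: int) -> np.ndarray:
    labels = np.zeros(n, dtype=int)
    for new_id, rep in enumerate(sorted(snapshot), start=1):
        labels[snapshot[rep]] = new_id
    return labels


def within_class_distance_sum(D: np.ndarray, labels: np.ndarray) -> float:
    """Sum over classes of all within-class pairwise distances (i < j)."""
    total = 0.0
    for lab in np.unique(labels):
        idx = np.where(labels == lab)[0]
        if len(idx) > 1:
            sub = D[np.ix_(idx, idx)]
            total += float(np.triu(sub, 1).sum())
    return total


def within_class_curve(D: SegmentDistanceMatrix | np.ndarray,
                       k_max: int = 10) -> tuple[dict[int, float], list[tuple[int, int, float]]]:
    """W(k) for k = 1..k_max from nested cuts of one agglomeration run.

    Nested cuts make the curve non-increasing in k by construction.
    """
    M = D.D if isinstance(D, SegmentDistanceMatrix) else np.asarray(D, float)
    n = M.shape[0]
    k_max = min(k_max, n)
    merges, snapshots = _agglomerate(M)
    curve = {}
    for k in range(1, k_max + 1):
        labels = _labels_from_snapshot(snapshots[n - k], n)
        curve[k] = within_class_distance_sum(M, labels)
    return curve, merges


def select_k_elbow(curve: dict[int, float], override: int | None = None) -> int:
    """Knee of the within-class distance curve: the interior k maximizing the
    discrete second difference W(k-1) - 2 W(k) + W(k+1); ties -> smallest k.

    ``override`` forces a manual choice (the curve is still validated).
    """
    ks = sorted(curve)
    if len(ks) < 3:
        raise ValueError("need the curve at k_max >= 3 (no interior point otherwise)")
    W = np.asarray([curve[k] for k in ks], float)
    if np.any(np.diff(W) > 1e-9 * max(1.0, abs(W[0]))):
        raise ValueError("within-class curve must be non-increasing in k")
    if override is not None:
        return int(override)
    d2 = W[:-2] - 2 * W[1:-1] + W[2:]
    best = int(np.argmax(d2))
    if np.allclose(d2, d2[0]):
        logger.warning("within-class curve has constant curvature; elbow degenerate, "
                       "returning smallest interior k")
    return ks[1 + best]


def cluster_distance_summaries(D: SegmentDistanceMatrix | np.ndarray,
                               labels: np.ndarray):
    """Mean between-class distances and within-class distance lists.

    ``intercluster_means[a-1, b-1]`` is the mean of D[i, j] over i in class a,
    j in class b (NaN on the diagonal); ``intracluster_distances[a]`` lists
    all D[i, j], i < j, within class a (empty for singletons).
    """
    M = D.D if isinstance(D, SegmentDistanceMatrix) else np.asarray(D, float)
    labs = sorted(np.unique(labels))
    k = len(labs)
    inter = np.full((k, k), np.nan)
    intra: dict[int, np.ndarray] = {}
    idx = {lab: np.where(labels == lab)[0] for lab in labs}
    for ai, a in enumerate(labs):
        ia = idx[a]
        sub = M[np.ix_(ia, ia)]
        iu = np.triu_indices(len(ia), 1)
        intra[int(a)] = sub[iu]
        for bi, b in enumerate(labs):
            if a == b:
                continue
            inter[ai, bi] = float(M[np.ix_(ia, idx[b])].mean())
    return inter, intra


def select_phase_windows(labels: np.ndarray, window_s: float = 10.0,
                         phase_len_s: float = 100.0,
                         min_purity: float = 0.5) -> PhaseWindows:
    """Pick one representative fixed-length block per temporal class.

    For each class, in order of first appearance, the contiguous run of
    ``phase_len_s / window_s`` windows with the highest fraction of that
    class's label is chosen (ties -> earliest). Blocks are then emitted as
    P1..Pk in temporal order. A class whose best block has purity <=
    ``min_purity`` triggers a warning but the best available block is still
    used.
    """
    m = phase_len_s / window_s
    if abs(m - round(m)) > 1e-9:
        raise ValueError("phase_len_s must be a multiple of window_s")
    m = int(round(m))
    labels = np.asarray(labels)
    if len(labels) < m:
        raise ValueError("fewer windows than one phase block")
    order = list(dict.fromkeys(labels.tolist()))
    blocks = []
    for lab in order:
        is_lab = (labels == lab).astype(float)
        frac = np.convolve(is_lab, np.ones(m), mode="valid") / m
        start = int(np.argmax(frac))  # argmax takes the earliest max
        purity = frac[start]
        if purity <= min_purity:
            logger.warning("class %s: best block purity %.2f <= %.2f", lab, purity, min_purity)
        blocks.append((start * window_s, (start + m) * window_s))
    blocks.sort()
    return PhaseWindows(phases=[(f"P{i + 1}", s, e) for i, (s, e) in enumerate(blocks)])
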
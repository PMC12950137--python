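"""PCA projection, DTW, average-linkage agglomeration, elbow selection, and
phase-window selection, each against independent oracles."""

from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

import caldyn
from caldyn.segmentation import (
    _agglomerate,
    cluster_distance_summaries,
    select_k_elbow,
    select_phase_windows,
    within_class_curve,
    within_class_distance_sum,
)
from caldyn.traces import TraceMatrix


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

def dtw_recursive_oracle(a, b):
    """Exhaustive warping-path minimum via memoized recursion."""
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)

    @lru_cache(maxsize=None)
    def g(i, j):
        c = float(np.linalg.norm(a[:, i] - b[:, j]))
        if i == 0 and j == 0:
            return c
        best = np.inf
        if i > 0:
            best = min(best, g(i - 1, j))
        if j > 0:
            best = min(best, g(i, j - 1))
        if i > 0 and j > 0:
            best = min(best, g(i - 1, j - 1))
        return c + best

    return g(a.shape[1] - 1, b.shape[1] - 1)


def naive_average_linkage(D):
    """O(n^3) agglomeration recomputing every cluster-pair mean from scratch."""
    n = D.shape[0]
    clusters = {i: [i] for i in range(n)}
    merges = []
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                tot = 0.0
                for i in clusters[a]:
                    for j in clusters[b]:
                        tot += D[i, j]
                mean = tot / (len(clusters[a]) * len(clusters[b]))
                key = (mean, a, b)
                if best is None or key < best:
                    best = key
        mean, a, b = best
        merges.append((a, b, mean))
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return merges


def random_distance_matrix(rng, n):
    M = rng.uniform(0.1, 10.0, size=(n, n))
    M = (M + M.T) / 2
    np.fill_diagonal(M, 0.0)
    return M


# --------------------------------------------------------------------------
# PCA projection
# --------------------------------------------------------------------------

class TestProjection:
    def make_traces(self, values, fs=10.0):
        return TraceMatrix(values=values, sampling_rate=fs, is_dff=True)

    def test_rank_two_data_needs_two_components(self):
        rng = np.random.default_rng(0)
        basisvecs = rng.normal(size=(2, 20))
        scores = rng.normal(size=(500, 2))
        X = (scores @ basisvecs).T  # 20 neurons x 500 frames, rank 2
        basis = caldyn.fit_projection(self.make_traces(X), 0.96)
        assert basis.n_components == 2
        assert basis.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_full_variance_target_needs_full_rank(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(5, 100))
        basis = caldyn.fit_projection(self.make_traces(X), 1.0)
        assert basis.n_components == 5

    def test_reconstruction_error_identity(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 400))
        tr = self.make_traces(X)
        basis = caldyn.fit_projection(tr, 0.8)
        scores = caldyn.project(tr, basis)
        recon = scores @ basis.loadings.T + basis.offsets
        resid = ((X.T - recon) ** 2).sum()
        total = ((X.T - X.T.mean(axis=0)) ** 2).sum()
        expected = (1 - basis.explained_variance_ratio.sum()) * total
        assert resid == pytest.approx(expected, abs=1e-6 * total)

    def test_loadings_orthonormal_and_sign_fixed(self):
        rng = np.random.default_rng(3)
        basis = caldyn.fit_projection(self.make_traces(rng.normal(size=(30, 300))), 0.9)
        W = basis.loadings
        assert np.allclose(W.T @ W, np.eye(W.shape[1]), atol=1e-8)
        for j in range(W.shape[1]):
            assert W[np.abs(W[:, j]).argmax(), j] > 0

    def test_invalid_target_rejected(self):
        rng = np.random.default_rng(4)
        tr = self.make_traces(rng.normal(size=(5, 50)))
        with pytest.raises(ValueError):
            caldyn.fit_projection(tr, 1.5)


# --------------------------------------------------------------------------
# DTW
# --------------------------------------------------------------------------

class TestDtw:
    def test_identical_series_distance_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(3, 20))
        assert caldyn.dtw_distance(x, x) == 0.0

    def test_pure_time_shift_absorbed(self):
        a = np.asarray([0.0, 0.0, 1.0, 0.0])
        b = np.asarray([0.0, 1.0, 0.0, 0.0])
        assert caldyn.dtw_distance(a, b) == 0.0

    def test_channel_mismatch_rejected(self):
        with pytest.raises(ValueError, match="channel"):
            caldyn.dtw_distance(np.zeros((2, 5)), np.zeros((3, 5)))

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            caldyn.dtw_distance(np.zeros((1, 0)), np.zeros((1, 5)))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(1, 8), st.integers(1, 8))
    def test_symmetry_nonnegativity_and_diagonal_bound(self, seed, la, lb):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(2, la))
        b = rng.normal(size=(2, lb))
        d = caldyn.dtw_distance(a, b)
        assert d >= 0
        assert d == pytest.approx(caldyn.dtw_distance(b, a), abs=1e-10)
        if la == lb:
            diag = sum(np.linalg.norm(a[:, t] - b[:, t]) for t in range(la))
            assert d <= diag + 1e-10

    def test_matches_recursive_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            ch = rng.integers(1, 4)
            a = rng.normal(size=(ch, rng.integers(1, 9)))
            b = rng.normal(size=(ch, rng.integers(1, 9)))
            assert caldyn.dtw_distance(a, b) == pytest.approx(
                dtw_recursive_oracle(a, b), abs=1e-12)

    def test_band_equals_full_when_wide(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=(2, 10))
        b = rng.normal(size=(2, 10))
        assert caldyn.dtw_distance(a, b, band=10) == pytest.approx(
            caldyn.dtw_distance(a, b))


class TestPairwiseDtw:
    def test_identical_windows_give_zero_matrix(self):
        x = np.random.default_rng(0).normal(size=(2, 10))
        ws = caldyn.WindowSet(series=np.stack([x, x, x]), window_frames=10,
                              sampling_rate=10.0)
        D = caldyn.pairwise_dtw(ws).D
        assert np.allclose(D, 0.0)

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(1)
        ws = caldyn.WindowSet(series=rng.normal(size=(6, 3, 12)),
                              window_frames=12, sampling_rate=10.0)
        D = caldyn.pairwise_dtw(ws).D
        assert np.array_equal(D, D.T)
        assert np.all(np.diag(D) == 0)

    def test_window_count_for_default_recording(self):
        scores = np.zeros((14000, 2))
        ws = caldyn.make_windows(scores, 100, 10.0)
        assert ws.n_windows == 140  # 9,730 unordered pairs

    def test_trailing_frames_dropped(self):
        ws = caldyn.make_windows(np.zeros((1050, 2)), 100, 10.0)
        assert ws.n_windows == 10


# --------------------------------------------------------------------------
# average linkage
# --------------------------------------------------------------------------

class TestAverageLinkage:
    def test_hand_worked_three_points(self):
        D = np.asarray([[0, 1, 5], [1, 0, 6], [5, 6, 0]], float)
        res = caldyn.average_linkage(D, 2)
        assert list(res.labels) == [1, 1, 2]
        assert res.merge_tree[-1][2] == pytest.approx(5.5)

    def test_k_equals_n_gives_singletons(self):
        rng = np.random.default_rng(0)
        D = random_distance_matrix(rng, 6)
        res = caldyn.average_linkage(D, 6)
        assert sorted(res.labels) == [1, 2, 3, 4, 5, 6]

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(3, 13))
            D = random_distance_matrix(rng, n)
            merges, _ = _agglomerate(D)
            oracle = naive_average_linkage(D)
            assert [(a, b) for a, b, _ in merges] == [(a, b) for a, b, _ in oracle]
            for (_, _, h1), (_, _, h2) in zip(merges, oracle):
                assert h1 == pytest.approx(h2, abs=1e-10)

    def test_heights_match_scipy_average_linkage(self):
        rng = np.random.default_rng(5)
        D = random_distance_matrix(rng, 15)
        merges, _ = _agglomerate(D)
        Z = linkage(squareform(D), method="average")
        assert np.allclose(sorted(h for _, _, h in merges), np.sort(Z[:, 2]),
                           atol=1e-8)

    def test_asymmetric_matrix_rejected(self):
        D = np.asarray([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError):
            caldyn.average_linkage(D, 1)

    def test_within_class_curve_non_increasing(self):
        rng = np.random.default_rng(6)
        D = random_distance_matrix(rng, 20)
        curve, _ = within_class_curve(D, k_max=10)
        vals = [curve[k] for k in sorted(curve)]
        assert all(a >= b - 1e-9 for a, b in zip(vals, vals[1:]))


class TestElbow:
    def test_piecewise_linear_knee(self):
        # slope -10 before k=5, -1 after: maximum curvature at 5
        curve = {}
        w = 100.0
        for k in range(1, 11):
            curve[k] = w
            w -= 10.0 if k < 5 else 1.0
        assert select_k_elbow(curve) == 5

    def test_exactly_linear_curve_returns_smallest_interior(self):
        curve = {k: 100.0 - 5.0 * k for k in range(1, 8)}
        assert select_k_elbow(curve) == 2

    def test_planted_knee_recovered_on_random_curves(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            k_star = int(rng.integers(2, 9))
            pre = rng.uniform(5.0, 10.0)
            post = rng.uniform(0.1, 0.5)
            w, curve = 1000.0, {}
            for k in range(1, 11):
                curve[k] = w
                w -= pre if k < k_star else post
            assert select_k_elbow(curve) == k_star

    def test_needs_interior_point(self):
        with pytest.raises(ValueError):
            select_k_elbow({1: 5.0, 2: 4.0})

    def test_override(self):
        curve = {k: 100.0 - 5.0 * k for k in range(1, 8)}
        assert select_k_elbow(curve, override=4) == 4


class TestDistanceSummaries:
    def test_two_singletons(self):
        D = np.asarray([[0, 3.0], [3.0, 0]])
        inter, intra = cluster_distance_summaries(D, np.asarray([1, 2]))
        assert inter[0, 1] == pytest.approx(3.0)
        assert len(intra[1]) == 0 and len(intra[2]) == 0

    def test_single_class(self):
        rng = np.random.default_rng(0)
        D = random_distance_matrix(rng, 5)
        inter, intra = cluster_distance_summaries(D, np.ones(5, int))
        assert np.isnan(inter).all()
        assert sorted(intra[1]) == sorted(D[np.triu_indices(5, 1)])

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(1)
        D = random_distance_matrix(rng, 12)
        labels = rng.integers(1, 4, size=12)
        inter, intra = cluster_distance_summaries(D, labels)
        labs = sorted(set(labels))
        for ai, a in enumerate(labs):
            for bi, b in enumerate(labs):
                if a == b:
                    continue
                vals = [D[i, j] for i in range(12) for j in range(12)
                        if labels[i] == a and labels[j] == b]
                assert inter[ai, bi] == pytest.approx(np.mean(vals))
            vals = [D[i, j] for i in range(12) for j in range(i + 1, 12)
                    if labels[i] == a and labels[j] == a]
            assert sorted(intra[a]) == pytest.approx(sorted(vals))


class TestPhaseWindowSelection:
    def test_pure_blocks_selected_exactly(self):
        labels = np.asarray([1] * 10 + [2] * 10 + [3] * 20)
        pw = select_phase_windows(labels, window_s=10.0, phase_len_s=100.0)
        assert pw.phases == [("P1", 0.0, 100.0), ("P2", 100.0, 200.0),
                             ("P3", 200.0, 300.0)]

    def test_single_stray_label_keeps_block(self):
        labels = np.asarray([1] * 10 + [2] * 10)
        labels[4] = 2
        pw = select_phase_windows(labels, window_s=10.0, phase_len_s=100.0)
        assert pw.phases[0] == ("P1", 0.0, 100.0)

    def test_phase_length_must_divide(self):
        with pytest.raises(ValueError):
            select_phase_windows(np.asarray([1] * 20), window_s=10.0,
                                 phase_len_s=95.0)

    def test_recovers_planted_state_spans(self, anesthesia_dataset,
                                          segmentation_products):
        cfg, _, truth, _ = anesthesia_dataset
        _, _, _, _, seg = segmentation_products
        pw = select_phase_windows(seg.labels, window_s=10.0, phase_len_s=100.0)
        assert len(pw.phases) == 5
        spans = {name: (s, e) for name, s, e in truth.state_bounds}
        for (_, start, end), state in zip(pw.phases, truth.states):
            lo, hi = spans[state]
            assert lo <= start and end <= hi
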
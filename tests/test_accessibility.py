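import logging

import numpy as np
import pytest
from scipy import sparse

from tecis.accessibility import (
    AnnotationMatrix,
    BackgroundPeakSets,
    BinaryAccessibilityMatrix,
    binarize,
    compute_deviations,
    expected_matrix,
    feature_variability,
    gc_fraction,
    sample_background_peaks,
)
from tests.conftest import brute_force_deviations


def _annotation(cols):
    mat = np.asarray(cols)
    return AnnotationMatrix(sparse.csr_matrix(mat),
                            [f"f{j}" for j in range(mat.shape[1])])


def _identity_bg(n_peaks, n_iter=5):
    return BackgroundPeakSets(
        np.tile(np.arange(n_peaks)[:, None], (1, n_iter)), n_iter)


class TestBinarize:
    def test_thresholds_counts(self):
        X = binarize(np.array([[0, 2], [2, 0], [1, 3]]))
        assert X.values.tolist() == [[0, 1], [1, 0], [1, 1]]

    def test_drops_all_zero_cell_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING):
            X = binarize(np.array([[1, 0], [1, 0]]))
        assert X.n_cells == 1
        assert "all-zero" in caplog.text

    def test_idempotent_on_binary(self):
        m = np.array([[0, 1], [1, 1]])
        assert (binarize(m).values == m).all()

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            binarize(np.array([[-1, 0]]))


class TestExpectedMatrix:
    def test_hand_example(self):
        X = BinaryAccessibilityMatrix(
            np.array([[1, 0], [1, 1], [0, 1]]), ["p0", "p1", "p2"], ["c0", "c1"])
        E = expected_matrix(X)
        assert E == pytest.approx(np.array([[0.5, 0.5], [1, 1], [0.5, 0.5]]))
        assert E.sum(axis=0) == pytest.approx(X.values.sum(axis=0))
        assert E.sum(axis=1) == pytest.approx(X.values.sum(axis=1))

    def test_single_cell_closure(self):
        X = BinaryAccessibilityMatrix(np.array([[1], [0], [1]]),
                                      ["a", "b", "c"], ["c0"])
        assert expected_matrix(X) == pytest.approx(X.values.astype(float))

    def test_uniform_matrix(self):
        X = BinaryAccessibilityMatrix(np.ones((3, 4), dtype=int),
                                      list("abc"), list("wxyz"))
        assert expected_matrix(X) == pytest.approx(np.ones((3, 4)))


class TestComputeDeviations:
    def test_hand_raw_example(self):
        # annotation {p0, p1}: raw = (2-1.5)/1.5, (1-1.5)/1.5
        X = BinaryAccessibilityMatrix(
            np.array([[1, 0], [1, 1], [0, 1]]), ["p0", "p1", "p2"], ["c0", "c1"])
        A = _annotation([[1], [1], [0]])
        bg = _identity_bg(3)
        res = compute_deviations(X, A, bg)
        # identity background: deviation 0; recover raw via the mean it removed
        assert res.deviation == pytest.approx(np.zeros((1, 2)), abs=1e-12)

    def test_all_peaks_annotation_raw_is_zero(self):
        # raw deviation of the all-peaks annotation is exactly 0 in every
        # cell; with the identity background this surfaces as Y = z = 0
        rng = np.random.default_rng(0)
        V = (rng.random((6, 5)) < 0.5).astype(int)
        V[:, V.sum(axis=0) == 0] = 1
        V[V.sum(axis=1) == 0, :] = 1
        X = BinaryAccessibilityMatrix(V, [f"p{i}" for i in range(6)],
                                      [f"c{j}" for j in range(5)])
        A = _annotation(np.ones((6, 1), dtype=int))
        res = compute_deviations(X, A, _identity_bg(6))
        assert res.deviation == pytest.approx(np.zeros((1, 5)), abs=1e-12)
        assert res.zscore == pytest.approx(np.zeros((1, 5)), abs=1e-12)

    def test_all_peaks_annotation_centered_under_resampling(self):
        # with-replacement background draws leave the all-peaks deviation
        # centered on zero (mean over iterations of a resampled statistic)
        rng = np.random.default_rng(0)
        V = (rng.random((30, 8)) < 0.5).astype(int)
        V[:, V.sum(axis=0) == 0] = 1
        V[V.sum(axis=1) == 0, :] = 1
        X = BinaryAccessibilityMatrix(V, [f"p{i}" for i in range(30)],
                                      [f"c{j}" for j in range(8)])
        A = _annotation(np.ones((30, 1), dtype=int))
        bg = BackgroundPeakSets(rng.integers(0, 30, size=(30, 400)), 400)
        res = compute_deviations(X, A, bg)
        assert np.abs(res.deviation).max() < 0.15

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            V = (rng.random((20, 10)) < 0.4).astype(int)
            V[:, V.sum(axis=0) == 0] = 1
            V[V.sum(axis=1) == 0, :] = 1
            X = BinaryAccessibilityMatrix(V, [f"p{i}" for i in range(20)],
                                          [f"c{j}" for j in range(10)])
            M = (rng.random((20, 3)) < 0.4).astype(int)
            M[0, M.sum(axis=0) == 0] = 1
            A = AnnotationMatrix(sparse.csr_matrix(M), ["f0", "f1", "f2"])
            bg = BackgroundPeakSets(rng.integers(0, 20, size=(20, 6)), 6)
            res = compute_deviations(X, A, bg)
            dev_o, z_o = brute_force_deviations(V, M, bg.index)
            assert res.deviation == pytest.approx(dev_o, abs=1e-10)
            finite = np.isfinite(z_o)
            assert res.zscore[finite] == pytest.approx(z_o[finite], abs=1e-10)
            assert (np.isfinite(res.zscore) == finite).all()

    def test_invariant_to_peak_permutation(self):
        rng = np.random.default_rng(3)
        V = (rng.random((12, 6)) < 0.5).astype(int)
        V[:, V.sum(axis=0) == 0] = 1
        M = (rng.random((12, 2)) < 0.5).astype(int)
        M[0, M.sum(axis=0) == 0] = 1
        bg_idx = rng.integers(0, 12, size=(12, 5))
        X = BinaryAccessibilityMatrix(V, [f"p{i}" for i in range(12)],
                                      [f"c{j}" for j in range(6)])
        res = compute_deviations(X, AnnotationMatrix(sparse.csr_matrix(M),
                                                     ["f0", "f1"]),
                                 BackgroundPeakSets(bg_idx, 5))
        perm = rng.permutation(12)
        inv = np.argsort(perm)
        Xp = BinaryAccessibilityMatrix(V[perm], [f"p{i}" for i in perm],
                                       [f"c{j}" for j in range(6)])
        res_p = compute_deviations(
            Xp, AnnotationMatrix(sparse.csr_matrix(M[perm]), ["f0", "f1"]),
            BackgroundPeakSets(inv[bg_idx[perm]], 5))
        assert res_p.deviation == pytest.approx(res.deviation, abs=1e-12)

    def test_empty_feature_dropped_with_warning(self, caplog):
        V = np.array([[1, 0], [0, 1]])
        X = BinaryAccessibilityMatrix(V, ["p0", "p1"], ["c0", "c1"])
        A = AnnotationMatrix(sparse.csr_matrix(np.array([[1, 0], [0, 0]])),
                             ["good", "empty"])
        with caplog.at_level(logging.WARNING):
            res = compute_deviations(X, A, _identity_bg(2))
        assert res.feature_ids == ["good"]


class TestBackgroundSampling:
    def test_deterministic_for_seed(self):
        gc = np.linspace(0.2, 0.8, 40)
        acc = np.linspace(0.1, 0.9, 40)
        a = sample_background_peaks(gc, acc, n_iterations=10, seed=5)
        b = sample_background_peaks(gc, acc, n_iterations=10, seed=5)
        assert (a.index == b.index).all()

    def test_separated_clusters_never_mix(self):
        # clusters at least as large as the minimum pool, so no ring
        # expansion across the covariate gap is needed
        gc = np.array([0.2] * 30 + [0.8] * 30)
        acc = np.array([0.1] * 30 + [0.9] * 30)
        bg = sample_background_peaks(gc, acc, n_iterations=20, seed=0,
                                     n_bins=5, min_pool=25)
        low = bg.index[:30]
        high = bg.index[30:]
        assert (low < 30).all()
        assert (high >= 30).all()

    def test_identical_covariates_single_bin(self):
        bg = sample_background_peaks(np.full(30, 0.5), np.full(30, 0.3),
                                     n_iterations=50, seed=1)
        assert set(np.unique(bg.index)) <= set(range(30))
        # with one bin every peak is reachable
        assert len(np.unique(bg.index)) > 20


class TestVariability:
    def test_constant_z_gives_zero(self):
        from tecis.accessibility import DeviationResult

        z = np.full((2, 10), 1.5)
        dev = DeviationResult(z.copy(), z, np.zeros(2), ["a", "b"],
                              [f"c{j}" for j in range(10)])
        assert feature_variability(dev) == pytest.approx([0.0, 0.0])

    def test_standard_normal_z_near_one(self):
        from tecis.accessibility import DeviationResult

        rng = np.random.default_rng(8)
        z = rng.normal(size=(3, 10_000))
        dev = DeviationResult(z.copy(), z, np.zeros(3), list("abc"),
                              [f"c{j}" for j in range(10_000)])
        assert feature_variability(dev) == pytest.approx(1.0, abs=0.03)


class TestGCFraction:
    def test_counts_gc_over_acgt(self):
        assert gc_fraction(["GGCC", "ATAT", "GANN"]) == pytest.approx(
            [1.0, 0.0, 0.5])
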
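import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from tffinder import (
    ExpressionMatrix,
    PenaltyParams,
    adaptive_soft_threshold,
    ascca_iterate,
    cv_select,
    initial_vectors,
    penalty_grid,
    standardize,
    svd_reference_vectors,
)
from tffinder.ascca import _grid_iterate


def _weights_and_init(K):
    w = svd_reference_vectors(K)
    u0, v0 = initial_vectors(K)
    return w, u0, v0


def _sign_match(a, b, atol):
    return np.allclose(a, b, atol=atol) or np.allclose(a, -b, atol=atol)


class TestSvdReferenceVectors:
    def test_rank_one_recovers_factors(self):
        a = np.array([3.0, 0.0, 4.0]) / 5.0
        b = np.array([1.0, 1.0]) / np.sqrt(2.0)
        w = svd_reference_vectors(0.7 * np.outer(a, b))
        assert _sign_match(w.u_svd, a, 1e-12)
        assert _sign_match(w.v_svd, b, 1e-12)
        # sign convention: largest-magnitude entry of u_svd positive
        assert w.u_svd[np.argmax(np.abs(w.u_svd))] > 0

    def test_diagonal_matrix(self):
        w = svd_reference_vectors(np.array([[1.0, 0.0], [0.0, 0.5]]))
        np.testing.assert_allclose(w.u_svd, [1.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(w.v_svd, [1.0, 0.0], atol=1e-12)

    def test_matches_eigendecomposition_oracle(self, rng):
        K = rng.standard_normal((5, 4))
        w = svd_reference_vectors(K)
        # independent route: leading eigenvectors of K K^T and K^T K
        eval_u, evec_u = np.linalg.eigh(K @ K.T)
        eval_v, evec_v = np.linalg.eigh(K.T @ K)
        u_ref = evec_u[:, np.argmax(eval_u)]
        v_ref = evec_v[:, np.argmax(eval_v)]
        assert _sign_match(w.u_svd, u_ref, 1e-8)
        assert _sign_match(w.v_svd, v_ref, 1e-8)

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            svd_reference_vectors(np.zeros((3, 2)))


class TestInitialVectors:
    def test_constant_matrix(self):
        u0, v0 = initial_vectors(np.full((3, 2), 0.5))
        np.testing.assert_allclose(u0, np.ones(3) / np.sqrt(3), atol=1e-12)
        np.testing.assert_allclose(v0, np.ones(2) / np.sqrt(2), atol=1e-12)

    def test_identity_row_means(self):
        u0, _ = initial_vectors(np.eye(2))
        np.testing.assert_allclose(u0, np.ones(2) / np.sqrt(2), atol=1e-12)

    def test_random_matrix_direct_arithmetic(self, rng):
        K = rng.standard_normal((4, 3))
        u0, v0 = initial_vectors(K)
        rm = K.mean(axis=1)
        cm = K.mean(axis=0)
        np.testing.assert_allclose(u0, rm / np.linalg.norm(rm), atol=1e-12)
        np.testing.assert_allclose(v0, cm / np.linalg.norm(cm), atol=1e-12)

    def test_zero_mean_falls_back_to_svd(self, caplog):
        # antisymmetric-ish K with zero row and column means
        K = np.array([[1.0, -1.0], [-1.0, 1.0]])
        with caplog.at_level("WARNING", logger="tffinder.ascca"):
            u0, v0 = initial_vectors(K)
        assert "falling back" in caplog.text
        w = svd_reference_vectors(K)
        assert _sign_match(u0, w.u_svd, 1e-12)
        assert _sign_match(v0, w.v_svd, 1e-12)


class TestAdaptiveSoftThreshold:
    def test_uniform_threshold_at_gamma_zero(self):
        out = adaptive_soft_threshold(
            np.array([0.5]), np.array([123.0]), lam=0.4, gamma=0.0
        )
        assert out[0] == pytest.approx(0.3, abs=1e-15)

    def test_zero_penalty_is_identity(self, rng):
        w = rng.standard_normal(10)
        ref = rng.standard_normal(10)
        np.testing.assert_array_equal(
            adaptive_soft_threshold(w, ref, 0.0, 1.5), w
        )

    def test_hand_arithmetic(self):
        # threshold = 0.5*0.2/0.5 = 0.2; out = -(0.3 - 0.2) = -0.1
        out = adaptive_soft_threshold(
            np.array([-0.3]), np.array([0.5]), lam=0.2, gamma=1.0
        )
        assert out[0] == pytest.approx(-0.1, abs=1e-15)

    def test_zero_reference_kills_coefficient(self):
        out = adaptive_soft_threshold(
            np.array([0.9, 0.9]), np.array([0.0, 1.0]), lam=0.1, gamma=1.0
        )
        assert out[0] == 0.0
        assert out[1] == pytest.approx(0.85)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="equal length"):
            adaptive_soft_threshold(np.ones(3), np.ones(2), 0.1, 1.0)

    @given(
        w=hnp.arrays(
            float, 8, elements=st.floats(-5, 5, allow_nan=False)
        ),
        ref=hnp.arrays(
            float, 8, elements=st.floats(-2, 2, allow_nan=False)
        ),
        lam=st.floats(0, 1),
        gamma=st.floats(0, 2),
    )
    @settings(max_examples=200, deadline=None)
    def test_shrinkage_and_sign_preserved(self, w, ref, lam, gamma):
        out = adaptive_soft_threshold(w, ref, lam, gamma)
        assert np.all(np.abs(out) <= np.abs(w) + 1e-12)
        nonzero = out != 0
        assert np.all(np.sign(out[nonzero]) == np.sign(w[nonzero]))


class TestAsccaIterate:
    def test_zero_penalty_reduces_to_svd(self, rng):
        K = rng.standard_normal((10, 6)) * 0.2
        w, u0, v0 = _weights_and_init(K)
        pair = ascca_iterate(
            K, PenaltyParams(0, 0, 0), w, u0, v0, tol=1e-10, max_iter=5000
        )
        assert pair.converged
        assert _sign_match(pair.u, w.u_svd, 1e-6)
        assert _sign_match(pair.v, w.v_svd, 1e-6)

    def test_rank_one_sparse_support_recovered(self):
        # K = sigma * a b^T with sparse unit a, b.  At zero penalty the fit is
        # exactly (a, b); penalties below the smallest rescaled nonzero entry
        # shrink but never remove the true support, and kill nothing else
        # because zero entries have zero reference (infinite threshold).
        a = np.array([0.8, 0.0, 0.6, 0.0, 0.0])
        b = np.array([0.0, 0.6, 0.0, 0.8])
        K = 0.9 * np.outer(a, b)
        w, u0, v0 = _weights_and_init(K)
        pair = ascca_iterate(K, PenaltyParams(0.1, 0.1, 1.0), w, u0, v0)
        assert pair.converged
        assert set(pair.support_u) == {0, 2}
        assert set(pair.support_v) == {1, 3}

    def test_total_shrinkage_gives_empty_support(self, rng):
        K = rng.standard_normal((6, 4)) * 0.1
        K = np.clip(K, -1, 1)
        w, u0, v0 = _weights_and_init(K)
        pair = ascca_iterate(K, PenaltyParams(50.0, 0.0, 0.0), w, u0, v0)
        assert not pair.converged
        assert pair.support_u == ()
        assert pair.support_v == ()

    def test_unit_norms_when_converged(self, rng):
        K = np.clip(rng.standard_normal((8, 5)) * 0.3, -1, 1)
        w, u0, v0 = _weights_and_init(K)
        pair = ascca_iterate(K, PenaltyParams(0.1, 0.1, 0.5), w, u0, v0)
        if pair.converged and pair.support_u:
            assert np.linalg.norm(pair.u) == pytest.approx(1.0, abs=1e-8)
            assert np.linalg.norm(pair.v) == pytest.approx(1.0, abs=1e-8)

    def test_nan_rejected(self):
        K = np.full((2, 2), np.nan)
        w = svd_reference_vectors(np.eye(2))
        with pytest.raises(ValueError, match="non-finite"):
            ascca_iterate(K, PenaltyParams(0, 0, 0), w, np.ones(2), np.ones(2))

    def test_transpose_symmetry(self, rng):
        K = np.clip(rng.standard_normal((7, 5)) * 0.3, -1, 1)
        params = PenaltyParams(0.08, 0.12, 1.0)
        w, u0, v0 = _weights_and_init(K)
        pair = ascca_iterate(K, params, w, u0, v0, tol=1e-10, max_iter=2000)

        wt = svd_reference_vectors(K.T)
        u0t, v0t = initial_vectors(K.T)
        swapped = PenaltyParams(params.lambda_v, params.lambda_u, params.gamma)
        pair_t = ascca_iterate(K.T, swapped, wt, u0t, v0t, tol=1e-10, max_iter=2000)

        assert _sign_match(pair_t.u, pair.v, 1e-8)
        assert _sign_match(pair_t.v, pair.u, 1e-8)

    def test_sparsity_monotone_in_lambda_u(self):
        # pointwise support monotonicity can fail for the alternating
        # algorithm near bifurcations of its fixed point (rare: ~1/30 random
        # K), so this asserts it on a fixed representative instance
        K = np.clip(np.random.default_rng(7).standard_normal((15, 8)) * 0.3, -1, 1)
        w, u0, v0 = _weights_and_init(K)
        sizes = []
        for lam in [i * 0.02 for i in range(21)]:
            pair = ascca_iterate(K, PenaltyParams(lam, 0.05, 1.0), w, u0, v0)
            sizes.append(len(pair.support_u))
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))


class TestGridIterateConsistency:
    def test_batch_equals_single_fit(self, rng):
        K = np.clip(rng.standard_normal((12, 6)) * 0.3, -1, 1)
        w, u0, v0 = _weights_and_init(K)
        grid = penalty_grid(0.2, 0.1, 0.2, 0.1, 1.0, 0.5)
        U, V = _grid_iterate(K, w, u0, v0, grid, 1e-6, 500)
        for g, params in enumerate(grid):
            pair = ascca_iterate(K, params, w, u0, v0)
            np.testing.assert_allclose(U[:, g], pair.u, atol=1e-10)
            np.testing.assert_allclose(V[:, g], pair.v, atol=1e-10)


class TestPenaltyGrid:
    def test_default_cardinality(self):
        assert len(penalty_grid()) == 35301

    def test_degenerate_grid(self):
        grid = penalty_grid(0.0, 0.01, 0.0, 0.01, 0.0, 0.1)
        assert grid == [PenaltyParams(0.0, 0.0, 0.0)]

    def test_small_enumeration(self):
        grid = penalty_grid(0.02, 0.01, 0.02, 0.01, 0.1, 0.1)
        assert len(grid) == 3 * 3 * 2
        assert grid[0] == PenaltyParams(0.0, 0.0, 0.0)
        assert grid[-1] == PenaltyParams(0.02, 0.02, 0.1)

    def test_no_accumulation_drift(self):
        lus = sorted({p.lambda_u for p in penalty_grid()})
        assert lus[7] == 7 * 0.01

    def test_bad_step(self):
        with pytest.raises(ValueError, match="lu_step"):
            penalty_grid(lu_step=0.0)


class TestCvSelect:
    def _blocks(self, rng, n=24, p=4, q=3):
        raw = rng.standard_normal((n, p + q))
        matrix = ExpressionMatrix(
            tuple(f"s{i}" for i in range(n)),
            tuple(f"g{j}" for j in range(p + q)),
            raw,
        )
        std = standardize(matrix)
        return std.select([f"g{j}" for j in range(p)]), std.select(
            [f"g{j}" for j in range(p, p + q)]
        )

    def test_single_triple_returned(self, rng):
        X, Y = self._blocks(rng)
        only = PenaltyParams(0.3, 0.3, 2.0)
        best, results = cv_select(X, Y, [only], k=3, seed=0)
        assert best == only
        assert len(results) == 1

    def test_duplicate_blocks_perfect_correlation(self, rng):
        X, _ = self._blocks(rng)
        Y = ExpressionMatrix(
            X.sample_ids,
            tuple(f"y{j}" for j in range(X.n_genes)),
            X.values.copy(),
            standardized=True,
        )
        _, results = cv_select(X, Y, [PenaltyParams(0, 0, 0)], k=3, seed=1)
        assert results[0].delta_cor == pytest.approx(1.0, abs=1e-6)

    def test_deterministic_given_seed(self, standardized_blocks):
        X, Y, _ = standardized_blocks
        grid = penalty_grid(0.2, 0.2, 0.2, 0.2, 1.0, 1.0)
        best1, res1 = cv_select(X, Y, grid, k=5, seed=42)
        best2, res2 = cv_select(X, Y, grid, k=5, seed=42)
        assert best1 == best2
        assert [r.delta_cor for r in res1] == [r.delta_cor for r in res2]

    def test_delta_cor_matches_fold_mean(self, standardized_blocks):
        X, Y, _ = standardized_blocks
        _, results = cv_select(X, Y, [PenaltyParams(0.1, 0.1, 1.0)], k=4, seed=3)
        r = results[0]
        assert r.delta_cor == pytest.approx(
            float(np.mean(np.abs(r.fold_correlations))), abs=1e-12
        )

    def test_empty_grid_rejected(self, standardized_blocks):
        X, Y, _ = standardized_blocks
        with pytest.raises(ValueError, match="grid"):
            cv_select(X, Y, [], k=3, seed=0)

    def test_k_larger_than_n_rejected(self, rng):
        X, Y = self._blocks(rng, n=6)
        with pytest.raises(ValueError, match="exceeds"):
            cv_select(X, Y, [PenaltyParams(0, 0, 0)], k=7, seed=0)
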
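import numpy as np
import pytest

from scai import (FactorModel, aggregate_epigenome, fit_scai, initialize_model,
                  multiplicative_step, objective, select_rank)
from scai._utils import column_normalize


def random_instance(seed, max_dim=30):
    """Random small paired matrices + masked model for update tests."""
    rng = np.random.default_rng(seed)
    p, q, n = rng.integers(5, max_dim + 1, 3)
    K = int(rng.integers(2, 5))
    X1 = rng.random((p, n)) * rng.poisson(2, (p, n))
    X2 = (rng.random((q, n)) < 0.3).astype(float)
    return X1, X2, K


def fixed_point_model(n=2, p=3, q=3):
    """Exact-factorization configuration: X1=W1H, X2(ZoR)=W2H, Z=H^T H.

    With H = I (row-stochastic), Z = I and R all-ones, every
    multiplicative ratio equals one when gamma = 0.
    """
    rng = np.random.default_rng(5)
    K = n
    H = np.eye(K)
    W1 = rng.random((p, K)) + 0.5
    W2 = rng.random((q, K)) + 0.5
    Z = H.T @ H
    R = np.ones((n, n))
    X1 = W1 @ H
    X2 = W2  # X2 @ colnorm(Z o R) = X2 = W2 H
    model = FactorModel(W1=W1, W2=W2, H=H, Z=Z, R=R, K=K, gamma=0.0)
    return model, X1, X2


class TestInitialize:
    def test_defaults_are_paper_values(self, rng):
        X1, X2, _ = random_instance(1)
        m = initialize_model(X1, X2, K=2, seed=0)
        assert (m.s, m.alpha, m.lam, m.gamma) == (0.25, 1.0, 10_000.0, 1.0)

    def test_same_seed_bit_identical(self):
        X1, X2, K = random_instance(2)
        a = initialize_model(X1, X2, K, seed=42)
        b = initialize_model(X1, X2, K, seed=42)
        for name in ("W1", "W2", "H", "Z", "R"):
            assert np.array_equal(getattr(a, name), getattr(b, name))

    @pytest.mark.parametrize("s,expect", [(1.0, 1.0), (0.0, 0.0)])
    def test_degenerate_bernoulli(self, s, expect):
        X1, X2, K = random_instance(3)
        m = initialize_model(X1, X2, K, s=s, seed=0)
        assert np.all(m.R == expect)

    def test_invalid_rank_and_mask_probability(self):
        X1, X2, _ = random_instance(4)
        with pytest.raises(ValueError, match="rank"):
            initialize_model(X1, X2, K=min(X1.shape[0], X2.shape[0], X1.shape[1]) + 1)
        with pytest.raises(ValueError, match="s="):
            initialize_model(X1, X2, K=2, s=1.5)


class TestObjective:
    def test_exact_factorization_is_zero(self):
        model, X1, X2 = fixed_point_model()
        total, terms = objective(model, X1, X2)
        assert total == pytest.approx(0.0, abs=1e-20)

    def test_sparsity_penalty_hand_computed(self):
        # 2x2 H: gamma * sum_j (sum_k H_kj)^2 = (0.1+0.3)^2 + (0.2+0.4)^2
        H = np.array([[0.1, 0.2], [0.3, 0.4]])
        model = FactorModel(W1=np.zeros((2, 2)), W2=np.zeros((2, 2)), H=H,
                            Z=np.zeros((2, 2)), R=np.ones((2, 2)), K=2,
                            alpha=0.0, lam=0.0, gamma=1.0)
        total, terms = objective(model, np.zeros((2, 2)), np.zeros((2, 2)))
        assert terms["sparsity"] == pytest.approx(0.4 ** 2 + 0.6 ** 2)

    def test_lambda_scales_similarity_term_only(self):
        X1, X2, K = random_instance(6)
        m1 = initialize_model(X1, X2, K, lam=100.0, seed=0)
        m2 = initialize_model(X1, X2, K, lam=200.0, seed=0)
        _, t1 = objective(m1, X1, X2)
        _, t2 = objective(m2, X1, X2)
        assert t2["similarity"] == pytest.approx(2 * t1["similarity"])
        for k in ("expression", "epigenome", "sparsity"):
            assert t2[k] == pytest.approx(t1[k])

    def test_nan_rejected(self):
        model, X1, X2 = fixed_point_model()
        model.Z = model.Z.copy()
        model.Z[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            objective(model, X1, X2)


class TestMultiplicativeStep:
    def test_fixed_point_invariance(self):
        model, X1, X2 = fixed_point_model()
        new = multiplicative_step(model, X1, X2)
        for name in ("W1", "W2", "H", "Z"):
            assert np.max(np.abs(getattr(new, name) - getattr(model, name))) < 1e-8

    def test_matches_straight_line_recomputation(self):
        """One step equals an independent dense evaluation of the printed
        elementwise ratio rules on a 3-gene x 4-cell x 3-locus toy."""
        rng = np.random.default_rng(11)
        X1 = rng.random((3, 4))
        X2 = (rng.random((3, 4)) < 0.5).astype(float)
        m = initialize_model(X1, X2, K=2, seed=3)
        W1, W2, H, Z, R = (m.W1.copy(), m.W2.copy(), m.H.copy(), m.Z.copy(), m.R)
        al, lam, ga = m.alpha, m.lam, m.gamma
        # oracle: scalar loops over the printed formulas
        ZR = Z * R
        ZRn = ZR / np.where(ZR.sum(0) > 0, ZR.sum(0), 1.0)
        A = X2 @ ZRn
        W1o = np.array([[W1[i, j] * (X1 @ H.T)[i, j] / (W1 @ H @ H.T)[i, j]
                         for j in range(2)] for i in range(3)])
        W2o = np.array([[W2[i, j] * (A @ H.T)[i, j] / (W2 @ H @ H.T)[i, j]
                         for j in range(2)] for i in range(3)])
        numH = al * W1o.T @ X1 + W2o.T @ A + lam * H @ (Z + Z.T)
        denH = (al * W1o.T @ W1o + W2o.T @ W2o + 2 * lam * H @ H.T
                + ga * np.ones((2, 2))) @ H
        Ho = H * numH / denH
        numZ = (X2.T @ (W2o @ Ho)) * R + lam * Ho.T @ Ho
        denZ = (X2.T @ (X2 @ ZRn)) * R + lam * Z
        Zo = Z * numZ / denZ
        stepped = multiplicative_step(m, X1, X2)
        assert np.allclose(stepped.raw_W1, W1o)
        assert np.allclose(stepped.raw_W2, W2o)
        assert np.allclose(stepped.raw_H, Ho)
        assert np.allclose(stepped.Z, Zo)

    def test_objective_decreases_and_h_row_stochastic(self):
        X1, X2, K = random_instance(12)
        m = initialize_model(X1, X2, K, seed=1)
        before, _ = objective(m, X1, X2)
        after = multiplicative_step(m, X1, X2)
        assert after.objective_trace[-1] <= before * (1 + 1e-9)
        assert np.allclose(after.H.sum(axis=1), 1.0, atol=1e-10)
        # the rescale is a pure reparameterization of the factorization
        assert np.allclose(after.W1 @ after.H, after.raw_W1 @ after.raw_H)

    def test_nonnegativity_preserved(self):
        X1, X2, K = random_instance(13)
        m = initialize_model(X1, X2, K, seed=2)
        for _ in range(5):
            m = multiplicative_step(m, X1, X2)
            for name in ("W1", "W2", "H", "Z"):
                assert np.all(getattr(m, name) >= 0)


class TestFit:
    def test_determinism(self, small_discrete):
        data, truth, X1 = small_discrete
        a = fit_scai(X1, data.X2, K=3, seed=9, max_iter=20, tol=0)
        b = fit_scai(X1, data.X2, K=9 // 3, seed=9, max_iter=20, tol=0)
        assert np.array_equal(a.objective_trace, b.objective_trace)
        assert np.array_equal(a.H, b.H)

    def test_infinite_tol_stops_after_one_iteration(self, small_discrete):
        data, truth, X1 = small_discrete
        m = fit_scai(X1, data.X2, K=3, seed=0, tol=np.inf)
        assert m.n_iter == 1 and m.converged

    def test_nonconvergence_warns_but_returns(self, small_discrete):
        data, truth, X1 = small_discrete
        with pytest.warns(UserWarning, match="did not converge"):
            m = fit_scai(X1, data.X2, K=3, seed=0, max_iter=3, tol=1e-12)
        assert m.converged is False and len(m.objective_trace) == 3

    def test_recovers_planted_clusters(self, small_discrete):
        from scai import cluster_cells, nmi
        data, truth, X1 = small_discrete
        m = fit_scai(X1, data.X2, K=3, seed=1)
        labels = cluster_cells(m.H, k=20, seed=1).labels
        assert nmi(labels, truth.labels) >= 0.9

    def test_serialization_roundtrip(self, small_discrete, tmp_path):
        data, truth, X1 = small_discrete
        m = fit_scai(X1, data.X2, K=3, seed=1, max_iter=10, tol=0)
        m.save(tmp_path / "model")
        back = FactorModel.load(tmp_path / "model")
        assert np.allclose(back.H, m.H)
        assert back.K == m.K and back.lam == m.lam
        assert back.objective_trace == pytest.approx(m.objective_trace)


class TestAggregate:
    def test_identity_similarity_returns_input(self, rng):
        X2 = (rng.random((6, 4)) < 0.5).astype(float)
        assert np.allclose(aggregate_epigenome(X2, np.eye(4), np.ones((4, 4))), X2)

    def test_constant_input_stays_constant(self, rng):
        X2 = np.full((5, 8), 3.7)
        Z = rng.random((8, 8))
        R = (rng.random((8, 8)) < 0.5).astype(float)
        R[np.diag_indices(8)] = 1  # keep every column non-empty
        agg = aggregate_epigenome(X2, Z, R)
        assert np.allclose(agg, 3.7)

    def test_three_cell_hand_computation(self):
        X2 = np.array([[1.0, 0.0, 2.0], [0.0, 4.0, 0.0]])
        Z = np.array([[0.5, 0.1, 0.0],
                      [0.1, 0.5, 0.2],
                      [0.0, 0.4, 0.3]])
        R = np.array([[1.0, 1.0, 0.0],
                      [0.0, 1.0, 1.0],
                      [1.0, 0.0, 1.0]])
        ZR = Z * R
        expected = X2 @ (ZR / ZR.sum(axis=0))
        assert np.allclose(aggregate_epigenome(X2, Z, R), expected)

    def test_convex_combination_bounds(self, rng):
        X2 = rng.random((10, 6)) * 5
        Z = rng.random((6, 6))
        R = np.ones((6, 6))
        agg = aggregate_epigenome(X2, Z, R)
        assert agg.min() >= X2.min() - 1e-12
        assert agg.max() <= X2.max() + 1e-12

    def test_cell_without_neighbors_rejected(self):
        Z = np.eye(3)
        R = np.ones((3, 3))
        R[:, 1] = 0
        with pytest.raises(ValueError, match="no sampled neighbors"):
            aggregate_epigenome(np.ones((2, 3)), Z, R)


class TestRankSelection:
    def test_recovers_planted_rank(self):
        from scai import generate_paired_dataset, normalize_expression
        # noisy, sparse 3-cluster data: duplicated factors are unstable
        # across seeds, so the cophenetic coefficient drops beyond K=3
        data, truth = generate_paired_dataset(
            "discrete", n_cells=100, n_genes=150, n_loci=300, n_clusters=3,
            rna_sparsity=0.93, atac_sparsity=0.97, noise_sd=0.8, seed=3)
        X1 = normalize_expression(data.X1)
        K, coph = select_rank(X1, data.X2, K_range=range(2, 7), n_seeds=6,
                              seed=0, max_iter=50)
        assert K == 3
        assert coph[5] < 0.95 < coph[3]

    def test_single_seed_rejected(self, small_discrete):
        data, truth, X1 = small_discrete
        with pytest.raises(ValueError, match="n_seeds"):
            select_rank(X1, data.X2, K_range=[2, 3], n_seeds=1)

    def test_rank_below_two_rejected(self, small_discrete):
        data, truth, X1 = small_discrete
        with pytest.raises(ValueError, match=">= 2"):
            select_rank(X1, data.X2, K_range=[1, 2], n_seeds=5)

    def test_pure_noise_warns_low_stability(self, rng):
        X1 = rng.random((25, 40))
        X2 = (rng.random((30, 40)) < 0.3).astype(float)
        with pytest.warns(UserWarning, match="low stability"):
            K, coph = select_rank(X1, X2, K_range=[2, 3, 4], n_seeds=5,
                                  seed=0, max_iter=30,
                                  stability_threshold=1.0 - 1e-12)
        assert K == 2
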
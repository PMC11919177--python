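"""Penalized precision estimation and EBIC network selection."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from cognet.ggm import (
    EDGE_EPS,
    WeightedNetwork,
    correlation_matrix,
    ebic,
    estimate_network,
    lambda_path,
    precision_to_partial,
)
from cognet.glasso import glasso_fit, glasso_objective, glasso_path
from cognet.synthetic import make_default_truth, sample_two_wave

from ._oracles import glasso_oracle_objective


def random_corr(rng, p, n=40):
    return np.corrcoef(rng.standard_normal((p, n)))


class TestGlassoFit:
    def test_unpenalized_2x2_closed_form(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        K = glasso_fit(S, 0.0)
        np.testing.assert_allclose(
            K, [[4 / 3, -2 / 3], [-2 / 3, 4 / 3]], atol=1e-12
        )

    def test_full_shrinkage_gives_diagonal(self):
        rng = np.random.default_rng(0)
        S = random_corr(rng, 5)
        lam = np.abs(S - np.diag(np.diag(S))).max()
        K = glasso_fit(S, lam)
        off = K - np.diag(np.diag(K))
        assert np.all(np.abs(off) <= 1e-10)
        np.testing.assert_allclose(np.diag(K), 1 / np.diag(S), atol=1e-10)

    @pytest.mark.parametrize("lam", [0.0, 0.05, 0.1, 0.3])
    def test_objective_matches_nelder_mead_oracle(self, lam):
        """On small problems the solver's penalized objective agrees
        with an independent derivative-free optimizer to 1e-6."""
        rng = np.random.default_rng(42)
        for _ in range(5):
            p = int(rng.integers(2, 4))
            S = random_corr(rng, p)
            K = glasso_fit(S, lam, tol=1e-10, max_iter=5000)
            ours = glasso_objective(K, S, lam)
            oracle = glasso_oracle_objective(S, lam)
            assert abs(ours - oracle) < 1e-6

    def test_matches_sklearn_on_larger_problems(self):
        """Cross-check against the reference coordinate-descent
        implementation at p=7."""
        from sklearn.covariance import graphical_lasso

        rng = np.random.default_rng(7)
        S = random_corr(rng, 7, n=200)
        for lam in (0.02, 0.1):
            K = glasso_fit(S, lam, tol=1e-9, max_iter=2000)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, Ksk = graphical_lasso(S, alpha=lam, tol=1e-8,
                                         max_iter=2000)
            assert abs(
                glasso_objective(K, S, lam)
                - glasso_objective(Ksk, S, lam)
            ) < 1e-5
            np.testing.assert_allclose(K, Ksk, atol=5e-4)

    def test_result_positive_definite_and_symmetric(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            S = random_corr(rng, int(rng.integers(2, 8)))
            K = glasso_fit(S, float(rng.uniform(0.01, 0.4)))
            np.testing.assert_allclose(K, K.T, atol=1e-10)
            assert np.linalg.eigvalsh(K).min() > 0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="symmetric"):
            glasso_fit(np.array([[1.0, 0.2], [0.4, 1.0]]), 0.1)
        with pytest.raises(ValueError, match=">= 0"):
            glasso_fit(np.eye(2), -0.1)

    def test_path_edge_count_monotone_in_penalty(self):
        """Edges can only appear as the penalty decreases."""
        rng = np.random.default_rng(5)
        X = sample_two_wave(make_default_truth(), 400, seed=8).t1
        S = correlation_matrix(X)
        lams = lambda_path(S, 40)
        Ks = glasso_path(S, lams)
        iu = np.triu_indices(S.shape[0], 1)
        counts = [int((np.abs(K[iu]) > EDGE_EPS).sum()) for K in Ks]
        assert counts[0] == 0  # lam_max gives the empty graph
        assert all(b >= a for a, b in zip(counts, counts[1:]))


class TestPartialCorrelation:
    def test_formula_2x2(self):
        K = np.array([[1.0, -0.5], [-0.5, 1.0]])
        P = precision_to_partial(K)
        assert P[0, 1] == pytest.approx(0.5)
        assert P[0, 0] == 0.0

    def test_diagonal_precision_gives_empty_network(self):
        P = precision_to_partial(np.diag([2.0, 3.0, 0.5]))
        assert np.all(P == 0)

    @given(arrays(np.float64, (4, 4),
                  elements=st.floats(-1, 1, allow_nan=False)))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_partials_bounded_for_any_pd_precision(self, A):
        K = A @ A.T + 1e-3 * np.eye(4)
        P = precision_to_partial(K)
        assert np.all(np.abs(P) < 1.0)
        np.testing.assert_allclose(P, P.T, atol=1e-12)


class TestEBIC:
    def test_arithmetic(self):
        # -2(-100) + 5 ln 100 + 4 * 0.5 * 5 * ln 7 = 242.485
        assert ebic(-100, 5, 100, 7, 0.5) == pytest.approx(242.485, abs=1e-3)

    def test_gamma_zero_is_bic_and_no_edges_is_deviance(self):
        assert ebic(-50, 3, 200, 7, 0.0) == pytest.approx(
            100 + 3 * np.log(200)
        )
        assert ebic(-50, 0, 200, 7, 0.5) == 100.0


class TestCorrelationMatrix:
    def test_hand_computed_toy(self):
        X = np.array([[1, 2, 0], [2, 4, 1], [3, 6, 1], [4, 8, 0]],
                     dtype=float)
        S = correlation_matrix(X)
        assert S[0, 1] == pytest.approx(1.0)  # exact linear dependence
        # r(col0, col2) by hand: cov = 0, sd products nonzero
        assert S[0, 2] == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(np.diag(S), 1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(9)
        S = correlation_matrix(rng.standard_normal((10000, 4)))
        off = S - np.eye(4)
        assert np.max(np.abs(off)) < 0.05

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            correlation_matrix(np.ones((10, 3)))
        with pytest.raises(ValueError, match="p\\+1"):
            correlation_matrix(np.random.default_rng(0).normal(size=(3, 5)))


class TestEstimateNetwork:
    def test_recovers_planted_support_at_large_n(self, latent_5000, truth):
        net = estimate_network(latent_5000.t1)
        P = truth.partial_corr1()
        for i in range(7):
            for j in range(i + 1, 7):
                if abs(P[i, j]) >= 0.2:
                    assert abs(net.W[i, j]) > EDGE_EPS, (i, j)
                if P[i, j] == 0:
                    assert abs(net.W[i, j]) < 0.05, (i, j)

    def test_independence_truth_gives_empty_network(self):
        rng = np.random.default_rng(13)
        X = pd.DataFrame(rng.standard_normal((3000, 7)))
        net = estimate_network(X)
        assert net.n_edges == 0
        assert net.density == 0.0

    def test_deterministic(self, latent_5000):
        scores = latent_5000.t1.iloc[:500]
        a = estimate_network(scores)
        b = estimate_network(scores)
        np.testing.assert_array_equal(a.W, b.W)
        assert a.meta == b.meta

    def test_density_bookkeeping(self):
        W = np.zeros((7, 7))
        W[0, 1] = W[1, 0] = 0.3
        W[2, 3] = W[3, 2] = -0.2
        net = WeightedNetwork(labels=list("ABCDEFG"), W=W)
        assert net.n_possible_edges == 21
        assert net.n_edges == 2
        assert net.density == pytest.approx(2 / 21)

    def test_network_io_round_trip(self, tmp_path, latent_5000):
        net = estimate_network(latent_5000.t1.iloc[:800])
        net.save(tmp_path / "net")
        M = pd.read_csv(tmp_path / "net.matrix.csv", index_col=0)
        np.testing.assert_allclose(M.to_numpy(), net.W, atol=1e-12)
        edges = pd.read_csv(tmp_path / "net.edges.tsv", sep="\t")
        assert len(edges) == net.n_edges
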
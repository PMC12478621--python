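"""EM estimation: gradient oracles, M-step maximization, ascent, recovery.

The finite-difference agreement of the analytic gradients and Hessian
diagonals with the expected complete-data log-likelihood is the anchor test
for the whole estimation machinery.
"""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.stats import poisson

from cmpirt import em
from cmpirt.quadrature import LatentCovariance, build_grid, e_step
from tests.conftest import make_dataset


def random_instance(rng, N=12, M=3, L=2, npd=3):
    Y = rng.poisson(3.0, size=(N, M))
    grid = build_grid(L, npd, LatentCovariance.identity(L), 0.0)
    params = em.ItemParameters(
        rng.normal(0, 0.3, (M, L)), rng.normal(1, 0.3, M), rng.normal(0, 0.3, M)
    )
    post = e_step(Y, params, grid)
    return Y, params, post, grid


class TestConstraints:
    @pytest.mark.parametrize(
        "L, M, expected",
        [(3, 9, 3), (1, 5, 0), (4, 20, 6)],
    )
    def test_echelon_count(self, L, M, expected):
        mask = em.apply_constraints(L, M)
        assert mask.n_constraints == expected == L * (L - 1) // 2

    def test_echelon_pattern(self):
        mask = em.apply_constraints(3, 9)
        assert mask.fixed_zero[0, 1] and mask.fixed_zero[0, 2] and mask.fixed_zero[1, 2]
        assert not mask.fixed_zero[1, 1] and not mask.fixed_zero[2:].any()

    def test_all_zero_column_rejected(self):
        bad = np.zeros((4, 2), dtype=bool)
        bad[:, 1] = True
        with pytest.raises(ValueError):
            em.apply_constraints(2, 4, bad)


class TestExpectedCdll:
    def test_single_node_poisson_reduction(self):
        grid = build_grid(1, 2, LatentCovariance.identity(1), 0.0)
        grid.nodes, grid.weights = np.zeros((1, 1)), np.array([1.0])
        grid.log_weights = np.log(grid.weights)
        params = em.ItemParameters(np.zeros((1, 1)), np.array([1.2]), np.zeros(1))
        Y = np.array([[2], [4], [1]])
        post = np.ones((3, 1))
        q = em.expected_cdll(Y, params, post, grid)
        assert q == pytest.approx(poisson.logpmf(Y[:, 0], np.exp(1.2)).sum(), abs=1e-8)

    def test_brute_force_triple_sum(self, rng):
        Y, params, post, grid = random_instance(rng, N=2, M=2, L=1, npd=4)
        from cmpirt.cmp import CMPParams, log_pmf

        total = 0.0
        for i in range(2):
            for k in range(grid.K):
                for j in range(2):
                    mu = np.exp(
                        params.intercepts[j] + params.slopes[j] @ grid.nodes[k]
                    )
                    p = CMPParams.from_mean(mu, params.nu[j])
                    total += post[i, k] * log_pmf(Y[i, j], p)
        assert em.expected_cdll(Y, params, post, grid) == pytest.approx(
            float(total), abs=1e-7
        )


class TestGradientOracle:
    def test_gradients_match_finite_differences(self, rng):
        """Analytic first derivatives of Q agree with central differences
        to <= 1e-5 relative error, second derivatives to <= 1e-4, across
        random small instances."""
        h, h2 = 1e-6, 1e-5
        for trial in range(20):
            N = int(rng.integers(5, 21))
            M = int(rng.integers(2, 5))
            L = int(rng.integers(1, 3))
            Y, params, post, grid = random_instance(rng, N=N, M=M, L=L, npd=3)
            g = em.gradients(Y, params, post, grid)

            def Q(p):
                return em.expected_cdll(Y, p, post, grid)

            def fd(bump):
                p1, p2 = params.copy(), params.copy()
                bump(p1, +h)
                bump(p2, -h)
                return (Q(p1) - Q(p2)) / (2 * h)

            for j in range(M):
                for l in range(L):
                    v = fd(lambda p, d, j=j, l=l: p.slopes.__setitem__((j, l), p.slopes[j, l] + d))
                    assert g.d_slopes[j, l] == pytest.approx(v, rel=1e-5, abs=1e-4)
                v = fd(lambda p, d, j=j: p.intercepts.__setitem__(j, p.intercepts[j] + d))
                assert g.d_intercepts[j] == pytest.approx(v, rel=1e-5, abs=1e-4)
                v = fd(lambda p, d, j=j: p.log_disp.__setitem__(j, p.log_disp[j] + d))
                assert g.d_logdisp[j] == pytest.approx(v, rel=1e-5, abs=1e-4)
                # Hessian diagonals via central differences of the gradient
                p1, p2 = params.copy(), params.copy()
                p1.intercepts[j] += h2
                p2.intercepts[j] -= h2
                v = (
                    em.gradients(Y, p1, post, grid).d_intercepts[j]
                    - em.gradients(Y, p2, post, grid).d_intercepts[j]
                ) / (2 * h2)
                assert g.h_intercepts[j] == pytest.approx(v, rel=1e-4, abs=1e-3)
                for l in range(L):
                    p1, p2 = params.copy(), params.copy()
                    p1.slopes[j, l] += h2
                    p2.slopes[j, l] -= h2
                    v = (
                        em.gradients(Y, p1, post, grid).d_slopes[j, l]
                        - em.gradients(Y, p2, post, grid).d_slopes[j, l]
                    ) / (2 * h2)
                    assert g.h_slopes[j, l] == pytest.approx(v, rel=1e-4, abs=1e-3)

    def test_poisson_reduction_of_slope_gradient(self, rng):
        # nu = 1: score reduces to the Poisson GLM score with log link
        Y, params, post, grid = random_instance(rng, N=8, M=2, L=2)
        params.log_disp[:] = 0.0
        g = em.gradients(Y, params, post, grid)
        mu = params.mu_nodes(grid)
        expected = np.einsum("ik,jk,kl->jl", post, -mu, grid.nodes) + np.einsum(
            "ik,ij,kl->jl", post, Y.astype(float), grid.nodes
        )
        np.testing.assert_allclose(g.d_slopes, expected, rtol=1e-8, atol=1e-8)

    def test_hessian_negative_at_interior(self, rng):
        Y, params, post, grid = random_instance(rng)
        g = em.gradients(Y, params, post, grid)
        assert (g.h_intercepts < 0).all()
        assert (g.h_slopes < 0).all()


class TestMStep:
    def test_saturated_mean_single_node(self):
        grid = build_grid(1, 2, LatentCovariance.identity(1), 0.0)
        grid.nodes, grid.weights = np.zeros((1, 1)), np.array([1.0])
        grid.log_weights = np.log(grid.weights)
        Y = np.full((6, 1), 4)
        mask = em.ConstraintMask(np.ones((1, 1), dtype=bool))
        params = em.ItemParameters(np.zeros((1, 1)), np.array([0.0]), np.array([0.2]))
        post = np.ones((6, 1))
        cfg = em.FitConfig(inner_max_iter=50, inner_tol=1e-10)
        out = em.m_step(Y, params, post, grid, mask, cfg)
        assert out.intercepts[0] == pytest.approx(np.log(4.0), abs=1e-6)

    def test_q_nondecreasing_and_fixed_point(self, rng):
        Y, params, post, grid = random_instance(rng, N=15, M=3, L=2)
        mask = em.apply_constraints(2, 3)
        cfg = em.FitConfig(inner_max_iter=60, inner_tol=1e-11, cd_tol=1e-10)
        q0 = em.expected_cdll(Y, params, post, grid)
        out = em.m_step(Y, params, post, grid, mask, cfg)
        q1 = em.expected_cdll(Y, out, post, grid)
        assert q1 >= q0 - 1e-9
        # applying the M-step again from the maximizer moves nothing
        again = em.m_step(Y, out, post, grid, mask, cfg)
        assert np.max(np.abs(again.flat() - out.flat())) < 1e-6

    def test_matches_blackbox_optimizer(self, rng):
        """Per-item M-step optimum agrees with scipy's BFGS on Q itself."""
        Y, params, post, grid = random_instance(rng, N=10, M=2, L=1, npd=4)
        mask = em.apply_constraints(1, 2)
        cfg = em.FitConfig(inner_max_iter=200, inner_tol=1e-12, cd_tol=1e-11)
        ours = em.m_step(Y, params, post, grid, mask, cfg)

        def negQ(x):
            p = em.ItemParameters(x[:2].reshape(2, 1), x[2:4], x[4:6])
            return -em.expected_cdll(Y, p, post, grid)

        x0 = np.concatenate(
            [params.slopes.ravel(), params.intercepts, params.log_disp]
        )
        ref = minimize(negQ, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        x = ref.x
        np.testing.assert_allclose(ours.slopes.ravel(), x[:2], atol=1e-5)
        np.testing.assert_allclose(ours.intercepts, x[2:4], atol=1e-5)
        np.testing.assert_allclose(ours.log_disp, x[4:6], atol=1e-4)


class TestPoissonStart:
    def test_equidispersed_data_near_zero_start(self):
        Y, truth, _ = make_dataset(L=1, m=4, N=1000, seed=3, nu_override=1.0)
        grid = build_grid(1, 7, LatentCovariance.identity(1), 0.0)
        mask = em.apply_constraints(1, 4)
        params = em.fit_poisson_start(Y, 1, mask, grid)
        assert np.abs(params.log_disp).max() < 0.15

    def test_overdispersed_data_negative_start(self):
        Y, truth, _ = make_dataset(L=1, m=4, N=600, seed=4, nu_override=0.5)
        grid = build_grid(1, 7, LatentCovariance.identity(1), 0.0)
        mask = em.apply_constraints(1, 4)
        params = em.fit_poisson_start(Y, 1, mask, grid)
        assert (params.log_disp < 0).all()


class TestFit:
    def test_loglik_ascent_and_convergence(self, small_dataset):
        Y, truth, _ = small_dataset
        cfg = em.FitConfig(nodes_per_dim=5, tol=1e-3)
        res = em.fit(Y, 2, config=cfg)
        assert res.converged
        tr = np.diff(res.loglik_trace)
        assert tr.min() > -1e-6

    def test_refit_from_solution_one_iteration(self, small_dataset):
        Y, truth, _ = small_dataset
        cfg = em.FitConfig(nodes_per_dim=5, tol=1e-3)
        res = em.fit(Y, 2, config=cfg)
        res2 = em.fit(Y, 2, config=cfg, start=res.params)
        assert res2.n_iter == 1
        assert res2.marginal_loglik == pytest.approx(res.marginal_loglik, abs=0.01)
        assert res2.marginal_loglik >= res.marginal_loglik - 1e-6

    def test_unidimensional_poisson_recovery(self):
        # L = 1, nu = 1 data: reduces to the two-parameter Poisson model
        Y, truth, _ = make_dataset(L=1, m=3, N=800, seed=9, nu_override=1.0)
        res = em.fit(Y, 1, config=em.FitConfig(nodes_per_dim=9, tol=5e-4))
        assert np.abs(res.params.intercepts - truth.intercepts).mean() < 0.05
        assert np.abs(res.params.log_disp).mean() < 0.15

    def test_input_validation(self):
        with pytest.raises(ValueError):
            em.fit(np.array([[1.5, 2.0], [1.0, 0.0]]), 1)
        with pytest.raises(ValueError):
            em.fit(np.array([[1, 2]]), 1)


class TestIO:
    def test_csv_round_trip(self, tmp_path):
        import pandas as pd

        Y = np.array([[1, 2, 3], [0, 5, 2]])
        f = tmp_path / "counts.csv"
        pd.DataFrame(Y, columns=["i1", "i2", "i3"]).to_csv(f, index=False)
        np.testing.assert_array_equal(em.read_counts_csv(f), Y)

    def test_non_integer_cell_rejected(self, tmp_path):
        f = tmp_path / "bad.csv"
        f.write_text("a,b\n1,2.5\n")
        with pytest.raises(ValueError):
            em.read_counts_csv(f)

    def test_fit_result_json(self, small_dataset):
        Y, _, _ = small_dataset
        res = em.fit(Y[:50], 2, config=em.FitConfig(nodes_per_dim=3, tol=1e-2, max_iter=20))
        import json

        payload = json.loads(res.to_json(em.FitConfig()))
        assert "params" in payload and "marginal_loglik" in payload
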
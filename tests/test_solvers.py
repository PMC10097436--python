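"""The regression solver family and the classical-MRA bootstrap."""

import itertools

import numpy as np
import pytest

from mrareg.core import (
    GlobalResponseMatrix,
    PerturbationDesign,
    RegressionSystem,
    build_regression_system,
    solve_mra_classical,
)
from mrareg.netgen import NetworkSpec, generate_network, simulate_responses
from mrareg.solvers import (
    bootstrap_mra,
    fit_lasso,
    fit_lse,
    fit_lse_ci,
    fit_network,
    fit_step,
    fit_tlr,
    tlr_threshold,
)

from conftest import random_connectivity


def noise_free_grm(n=6, seed=0, replicates=1, intensity=-1.0):
    # small test networks need a lower sparsity than the 0.85 benchmark default
    null_fraction = 0.85 if n >= 20 else 0.5
    r = generate_network(NetworkSpec(n_tf=n, null_fraction=null_fraction), seed=seed)
    return r, simulate_responses(
        r, PerturbationDesign.one_per_node(n, intensity), replicates=replicates
    )


def make_system(X, y, node=0):
    cols = list(range(1, X.shape[1] + 1))
    return RegressionSystem(node, X, y, cols, list(range(len(y))))


class TestLse:
    def test_square_noise_free_equals_classical(self):
        # formulation equivalence over seeded networks
        for seed in range(20):
            r, R = noise_free_grm(n=6, seed=seed)
            classical = solve_mra_classical(R)
            est, _ = fit_network(R, "lse")
            assert np.allclose(est.values, classical.values, atol=1e-8)

    def test_exact_single_predictor(self):
        rng = np.random.default_rng(0)
        X = np.zeros((8, 3))
        X[:, 1] = rng.normal(size=8)
        y = 2.5 * X[:, 1]
        fit = fit_lse(make_system(X[:, [1]], y))
        assert fit.coefficients[0] == pytest.approx(2.5)
        assert fit.residual_variance == pytest.approx(0.0, abs=1e-20)

    def test_ci_width_shrinks_with_rows(self):
        rng = np.random.default_rng(1)
        widths = []
        for n in (12, 120):
            X = rng.normal(size=(n, 3))
            y = X @ [1.0, -0.5, 0.2] + rng.normal(0, 0.3, n)
            fit = fit_lse(make_system(X, y))
            widths.append(np.mean(fit.ci_high - fit.ci_low))
        assert widths[1] < widths[0]

    def test_square_system_warns_no_ci(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(3, 3))
        with pytest.warns(UserWarning, match="point estimate only"):
            fit = fit_lse(make_system(X, X @ [1.0, 2.0, 3.0]))
        assert fit.ci_low is None and fit.dof == 0

    def test_rank_deficiency_reported(self):
        X = np.ones((6, 2))
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            fit_lse(make_system(X, np.ones(6)))

    def test_dof_bookkeeping_with_prior_null(self):
        _, R = noise_free_grm(n=6, replicates=2, seed=3)
        full = fit_lse(build_regression_system(R, 0))
        reduced = fit_lse(build_regression_system(R, 0, prior_null={1, 2}))
        assert reduced.dof == full.dof + 2


class TestLseCi:
    def test_noise_free_replicated_keeps_true_edges(self):
        r, R = noise_free_grm(n=6, seed=1, replicates=3)
        est, results = fit_network(R, "lse_ci")
        mask = ~np.eye(6, dtype=bool)
        true_nz = (r.values != 0) & mask
        assert np.all(est.values[true_nz] != 0)

    def test_zero_spanning_ci_eliminated(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 2))
        y = 1.5 * X[:, 0] + rng.normal(0, 1.0, 40)  # column 2 irrelevant
        fit = fit_lse_ci(make_system(X, y))
        assert fit.coefficients[1] == 0.0
        assert fit.coefficients[0] != 0.0


class TestTlr:
    def test_hand_percentile(self):
        # 25th percentile of {1,2,3,4} under linear interpolation
        assert tlr_threshold([np.array([1.0, 2.0, 3.0, 4.0])]) == pytest.approx(1.75)

    def test_threshold_zeroes_below(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 4))
        beta = np.array([1.0, 2.0, 3.0, 4.0])
        fit = fit_tlr(make_system(X, X @ beta), threshold=1.75)
        assert fit.coefficients[0] == 0.0
        assert np.allclose(fit.coefficients[1:], beta[1:], atol=1e-8)

    def test_all_equal_nothing_zeroed(self):
        # stacked-identity design: least squares returns the exact 0.7s,
        # so the strict < rule keeps every coefficient at the threshold
        th = tlr_threshold([np.full(5, 0.7)])
        X = np.vstack([np.eye(5)] * 4)
        fit = fit_tlr(make_system(X, X @ np.full(5, 0.7)), threshold=th)
        assert np.all(fit.coefficients == 0.7)

    def test_about_quarter_zeroed_network_wide(self):
        rng = np.random.default_rng(6)
        n = 20
        values = rng.normal(size=(n, n))
        np.fill_diagonal(values, -1)
        R = GlobalResponseMatrix(values, PerturbationDesign.one_per_node(n, -1.0))
        est, _ = fit_network(R, "tlr")
        mask = ~np.eye(n, dtype=bool)
        zeroed = int(np.sum(est.values[mask] == 0.0))
        expected = int(0.25 * n * (n - 1))
        assert abs(zeroed - expected) <= 2


class TestLasso:
    def test_tiny_penalty_matches_lse(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 4))
        y = X @ [1.0, 0.0, -2.0, 0.5] + rng.normal(0, 0.1, 40)
        system = make_system(X, y)
        lse = fit_lse(system)
        lasso = fit_lasso(system, lambda_grid=np.array([1e-10]))
        assert np.allclose(lasso.coefficients, lse.coefficients, atol=1e-4)

    def test_huge_penalty_shrinks_all(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 4))
        y = X @ [1.0, 0.0, -2.0, 0.5]
        lasso = fit_lasso(make_system(X, y), lambda_grid=np.array([1e6]))
        assert np.all(lasso.coefficients == 0.0)
        assert lasso.selected == set()

    def test_path_selection_non_increasing_in_penalty(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(60, 8))
        y = X @ [2.0, -1.5, 1.0, 0.5, 0.0, 0.0, 0.0, 0.0] + rng.normal(0, 0.5, 60)
        counts = []
        for lam in (1e-4, 1e-2, 0.1, 0.5, 2.0):
            fit = fit_lasso(make_system(X, y), lambda_grid=np.array([lam]))
            counts.append(len(fit.selected))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_all_zero_response(self):
        X = np.random.default_rng(10).normal(size=(20, 3))
        fit = fit_lasso(make_system(X, np.zeros(20)))
        assert np.all(fit.coefficients == 0.0)

    def test_cv_improves_specificity_over_raw_lse(self):
        # sparse network, noisy replicated data: LASSO support is cleaner
        # than the dense LSE estimate thresholded at exactly 0
        wins = 0
        for seed in range(10):
            r = generate_network(NetworkSpec(n_tf=30), seed=seed)
            R = simulate_responses(r, noise_k=0.1, seed=seed, replicates=3)
            mask = ~np.eye(30, dtype=bool)
            null_ref = (r.values == 0) & mask
            lasso_est, _ = fit_network(R, "lasso", seed=seed)
            lse_est, _ = fit_network(R, "lse")
            sp_lasso = np.mean(lasso_est.values[null_ref] == 0)
            sp_lse = np.mean(lse_est.values[null_ref] == 0)
            if sp_lasso > sp_lse:
                wins += 1
        assert wins >= 9


class TestStep:
    def test_forward_finds_single_strong_predictor(self):
        # consistent criterion (BIC) at large n: exactly the true
        # predictor survives in nearly every seeded replicate
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(500, 6))
            y = 2.0 * X[:, 3] + rng.normal(0, 0.5, 500)
            fit = fit_step(make_system(X, y), "forward", criterion="bic")
            if fit.selected == {make_system(X, y).column_index[3]}:
                hits += 1
        assert hits >= 9

    def test_backward_noise_free_keeps_true_support(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(30, 5))
        beta = np.array([1.0, 0.0, -2.0, 0.0, 0.5])
        fit = fit_step(make_system(X, beta @ X.T * 1.0), "backward")
        # RSS is 0 only on supersets of the true support
        cols = make_system(X, X @ beta).column_index
        assert {cols[0], cols[2], cols[4]} <= fit.selected

    @pytest.mark.parametrize("direction", ["forward", "backward"])
    def test_agrees_with_exhaustive_best_subset(self, direction):
        # N=5 toys with well-separated signal: greedy = brute force
        def brute_force(X, y, criterion="aic"):
            n, p = X.shape
            best, best_s = None, None
            for k in range(p + 1):
                for S in itertools.combinations(range(p), k):
                    if S:
                        b, *_ = np.linalg.lstsq(X[:, S], y, rcond=None)
                        rss = float(np.sum((y - X[:, S] @ b) ** 2))
                    else:
                        rss = float(y @ y)
                    s = n * np.log(max(rss, 1e-300) / n) + 2 * k
                    if best_s is None or s < best_s - 1e-10:
                        best_s, best = s, set(S)
            return best

        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(50, 4))
            beta = np.array([3.0, 0.0, -2.0, 0.0])
            y = X @ beta + rng.normal(0, 0.3, 50)
            system = make_system(X, y)
            fit = fit_step(system, direction)
            greedy = {system.column_index.index(j) for j in fit.selected}
            assert greedy == brute_force(X, y)

    def test_unselected_are_exact_zeros(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(60, 6))
        y = 1.5 * X[:, 0] + rng.normal(0, 0.4, 60)
        fit = fit_step(make_system(X, y), "both")
        unselected = [
            i for i, j in enumerate(make_system(X, y).column_index)
            if j not in fit.selected
        ]
        assert np.all(fit.coefficients[unselected] == 0.0)

    def test_bic_selects_no_more_than_aic(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(80, 8))
        y = X[:, 0] - X[:, 5] + rng.normal(0, 1.0, 80)
        aic = fit_step(make_system(X, y), "forward", criterion="aic")
        bic = fit_step(make_system(X, y), "forward", criterion="bic")
        assert len(bic.selected) <= len(aic.selected)


class TestFitNetwork:
    def test_diagonal_always_minus_one(self):
        _, R = noise_free_grm(n=8, seed=5, replicates=2)
        for method in ("lse", "lse_ci", "tlr", "step_fo"):
            est, _ = fit_network(R, method)
            assert np.all(np.diag(est.values) == -1.0)

    def test_prior_null_entries_forced_zero(self):
        r, R = noise_free_grm(n=8, seed=6, replicates=2)
        prior = {0: {3, 4}, 2: {5}}
        est, results = fit_network(R, "lse", prior_null=prior)
        assert est.values[0, 3] == 0.0 and est.values[0, 4] == 0.0
        assert est.values[2, 5] == 0.0
        assert results[0].dof == results[1].dof + 2

    def test_true_prior_never_hurts_sensitivity(self):
        # giving the solver the true null set keeps all real edges
        r = generate_network(NetworkSpec(n_tf=20), seed=7)
        R = simulate_responses(r, noise_k=0.05, seed=7, replicates=3)
        mask = ~np.eye(20, dtype=bool)
        prior = {
            i: {j for j in range(20) if j != i and r.values[i, j] == 0.0}
            for i in range(20)
        }
        est, _ = fit_network(R, "lse_ci", prior_null=prior)
        null_ref = (r.values == 0) & mask
        assert np.all(est.values[null_ref] == 0.0)  # specificity 1 by construction

    def test_unknown_method(self):
        _, R = noise_free_grm()
        with pytest.raises(ValueError, match="unknown method"):
            fit_network(R, "ridge")


class TestBootstrap:
    def test_identical_replicates_zero_width(self):
        r, R = noise_free_grm(n=5, seed=8, replicates=3)
        boot = bootstrap_mra(R, n_boot=25, seed=0)
        assert np.allclose(boot.ci_low, boot.ci_high, atol=1e-12)
        # nothing zeroed beyond exact zeros of the true network
        mask = ~np.eye(5, dtype=bool)
        true_nz = (r.values != 0) & mask
        assert np.all(boot.connectivity.values[true_nz] != 0.0)

    def test_default_repetitions(self):
        import inspect

        assert inspect.signature(bootstrap_mra).parameters["n_boot"].default == 100

    def test_ci_width_grows_with_noise(self):
        r = generate_network(NetworkSpec(n_tf=6, null_fraction=0.5), seed=9)
        widths = []
        for k in (0.001, 0.005):
            R = simulate_responses(r, noise_k=k, seed=10, replicates=4)
            boot = bootstrap_mra(R, n_boot=60, seed=1)
            widths.append(np.mean(boot.ci_high - boot.ci_low))
        assert widths[1] > widths[0]

    def test_needs_replicates(self):
        _, R = noise_free_grm(n=5, seed=10, replicates=1)
        with pytest.raises(ValueError, match="replicates"):
            bootstrap_mra(R, n_boot=10)
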
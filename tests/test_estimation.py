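"""EM estimation: monotonicity, oracles, recovery, covariance."""

import itertools

import numpy as np
import pytest

from dinadif.dina import (
    ItemParameterSet,
    QMatrix,
    draw_attribute_profiles,
    simulate_responses,
)
from dinadif.estimation import (
    EstimationError,
    FitOptions,
    FittedDina,
    LatentClassSpace,
    class_posteriors,
    em_fit,
    marginal_loglik_naive,
    multigroup_em_fit,
    parameter_covariance,
    studied_item_covariance,
)


def _simulate(q, params, n, rho, seed):
    alpha = draw_attribute_profiles(n, q.n_attributes, rho, seed=seed)
    return simulate_responses(alpha, q, params, seed=seed + 1)


class TestEmFit:
    def test_loglik_nondecreasing(self, small_design):
        q, params = small_design
        x = _simulate(q, params, 400, 0.5, seed=100)
        fit = em_fit(x, q)
        diffs = np.diff(fit.loglik_history)
        assert (diffs >= -1e-6).all()

    def test_estimates_respect_bounds_and_monotonicity(self, small_design):
        q, params = small_design
        fit = em_fit(_simulate(q, params, 300, 0.3, seed=101), q)
        s, g = fit.params.slipping, fit.params.guessing
        assert (s >= 0.001).all() and (s <= 0.5).all()
        assert (g >= 0.001).all() and (g <= 0.5).all()
        assert (g < 1 - s).all()

    def test_parameter_recovery_at_n5000(self, study_fixtures):
        """s and g recovered with RMSE below 0.02 from N=5000, correct Q."""
        q = study_fixtures.qmatrix
        params = study_fixtures.baseline_params
        x = _simulate(q, params, 5000, 0.5, seed=102)
        fit = em_fit(x, q)
        assert fit.converged
        rmse_s = np.sqrt(np.mean((fit.params.slipping - params.slipping) ** 2))
        rmse_g = np.sqrt(np.mean((fit.params.guessing - params.guessing) ** 2))
        assert rmse_s < 0.02 and rmse_g < 0.02

    def test_matches_bruteforce_grid_search_on_toy_problem(self):
        """EM attains (at least) the best likelihood on a coarse parameter grid."""
        q = QMatrix(np.array([[1], [1]]))
        true = ItemParameterSet(np.array([0.1, 0.3]), np.array([0.2, 0.15]))
        x = _simulate(q, true, 600, 0.0, seed=103)
        fit = em_fit(x, q)
        space = LatentClassSpace.full(1)
        grid = np.arange(0.05, 0.5, 0.05)
        pis = np.arange(0.05, 1.0, 0.05)
        best = -np.inf
        xm = x.responses.astype(float)
        n1 = xm.sum(axis=0)
        n0 = xm.shape[0] - n1
        both1 = (xm[:, 0] * xm[:, 1]).sum()
        # enumerate the coarse grid, evaluating the exact 2-class mixture
        for s1, g1, s2, g2, p in itertools.product(grid, grid, grid, grid, pis):
            pm = np.array([[g1, g2], [1 - s1, 1 - s2]])  # class x item success
            # likelihood per response pattern (4 patterns for 2 items)
            ll = 0.0
            for a, b, count in [
                (1, 1, both1),
                (1, 0, n1[0] - both1),
                (0, 1, n1[1] - both1),
                (0, 0, xm.shape[0] - n1[0] - n1[1] + both1),
            ]:
                lik = (1 - p) * (pm[0, 0] ** a) * ((1 - pm[0, 0]) ** (1 - a)) * (
                    pm[0, 1] ** b
                ) * ((1 - pm[0, 1]) ** (1 - b)) + p * (pm[1, 0] ** a) * (
                    (1 - pm[1, 0]) ** (1 - a)
                ) * (pm[1, 1] ** b) * ((1 - pm[1, 1]) ** (1 - b))
                ll += count * np.log(lik)
            best = max(best, ll)
        assert fit.loglik >= best - 1e-8
        assert np.allclose(fit.params.slipping, true.slipping, atol=0.1)

    def test_nonconvergence_is_flagged(self, small_design):
        q, params = small_design
        x = _simulate(q, params, 300, 0.5, seed=104)
        fit = em_fit(x, q, FitOptions(max_iter=2))
        assert not fit.converged and fit.n_iterations == 2

    def test_loglik_matches_naive_class_summation(self, small_design):
        """Vectorized marginal log-likelihood equals direct 2^K summation."""
        q, params = small_design
        x = _simulate(q, params, 25, 0.3, seed=105)
        space = LatentClassSpace.full(2, np.array([0.1, 0.2, 0.3, 0.4]))
        from dinadif.estimation import _class_eta, _estep

        ll, _ = _estep(
            x.responses.astype(float), _class_eta(q, space),
            params.slipping, params.guessing, space.mixing,
        )
        assert ll == pytest.approx(marginal_loglik_naive(x.responses, q, params, space), abs=1e-8)


class TestClassPosteriors:
    def test_bruteforce_bayes_small_instance(self, small_design):
        q, params = small_design
        x = _simulate(q, params, 10, 0.5, seed=106)
        space = LatentClassSpace.full(2, np.array([0.15, 0.25, 0.35, 0.25]))
        post = class_posteriors(x, q, params, space)
        assert np.allclose(post.sum(axis=1), 1.0)
        eta_c = np.array(
            [[1 if all(a >= qq for a, qq in zip(prof, row)) else 0 for row in q.entries]
             for prof in space.profiles]
        )
        for i in range(10):
            lik = np.zeros(4)
            for c in range(4):
                p = np.where(eta_c[c] == 1, 1 - params.slipping, params.guessing)
                lik[c] = space.mixing[c] * np.prod(
                    np.where(x.responses[i] == 1, p, 1 - p)
                )
            assert np.allclose(post[i], lik / lik.sum(), atol=1e-10)

    def test_deterministic_responses_pin_the_class(self):
        q = QMatrix(np.array([[1, 0], [0, 1], [1, 1]]))
        params = ItemParameterSet(np.zeros(3), np.zeros(3))
        space = LatentClassSpace.full(2)
        # responses consistent with profile (1, 0) only
        x = np.array([[1, 0, 0]])
        post = class_posteriors(x, q, params, space)
        target = np.flatnonzero((space.profiles == [1, 0]).all(axis=1))[0]
        assert post[0, target] == pytest.approx(1.0)

    def test_uninformative_items_return_prior(self):
        q = QMatrix(np.array([[1], [1]]))
        params = ItemParameterSet(np.array([0.4, 0.3]), np.array([0.6, 0.7]))  # g = 1 - s
        space = LatentClassSpace.full(1, np.array([0.35, 0.65]))
        post = class_posteriors(np.array([[1, 0], [0, 1]]), q, params, space)
        assert np.allclose(post, space.mixing, atol=1e-12)

    def test_impossible_responses_rejected(self):
        q = QMatrix(np.array([[1]]))
        params = ItemParameterSet(np.array([0.0]), np.array([0.0]))
        space = LatentClassSpace.full(1, np.array([0.0, 1.0]))  # masters only, s=0
        with pytest.raises(EstimationError, match="impossible"):
            class_posteriors(np.array([[0]]), q, params, space)


class TestParameterCovariance:
    def test_symmetric(self, small_design):
        q, params = small_design
        fit = em_fit(_simulate(q, params, 800, 0.5, seed=107), q)
        cov = parameter_covariance(fit)
        assert np.allclose(cov, cov.T, atol=1e-12)

    def test_known_class_single_item_reduces_to_binomial_variance(self):
        """With one item and a degenerate master-only class space, var(s_hat)
        is the binomial proportion variance p(1-p)/n."""
        q = QMatrix(np.array([[1]]))
        rng = np.random.default_rng(108)
        x = (rng.random((400, 1)) < 0.8).astype(np.int8)
        p_hat = x.mean()
        fit = FittedDina(
            params=ItemParameterSet(np.array([1 - p_hat]), np.array([0.2])),
            class_space=LatentClassSpace.full(1, np.array([0.0, 1.0])),
            loglik=0.0,
            loglik_history=np.array([0.0]),
            converged=True,
            n_iterations=1,
            q=q,
            responses=x,
        )
        cov = parameter_covariance(fit, free_mixing=False, allow_singular=True)
        assert cov[0, 0] == pytest.approx(p_hat * (1 - p_hat) / 400, rel=1e-8)

    def test_standard_errors_shrink_with_root_n(self, small_design):
        q, params = small_design
        ses = []
        for n in (1000, 4000):
            fit = em_fit(_simulate(q, params, n, 0.5, seed=109), q)
            cov = parameter_covariance(fit, allow_singular=True)
            ses.append(np.sqrt(np.diag(cov)[: q.n_items]).mean())
        assert ses[0] / ses[1] == pytest.approx(2.0, rel=0.25)

    def test_singular_information_rejected_with_diagnostics(self):
        q = QMatrix(np.array([[1]]))
        x = np.ones((50, 1), dtype=np.int8)
        fit = FittedDina(
            params=ItemParameterSet(np.array([0.1]), np.array([0.2])),
            class_space=LatentClassSpace.full(1, np.array([0.0, 1.0])),
            loglik=0.0,
            loglik_history=np.array([0.0]),
            converged=True,
            n_iterations=1,
            q=q,
            responses=x,
        )
        with pytest.raises(EstimationError, match="singular"):
            parameter_covariance(fit, free_mixing=False)


def test_fit_summary_table(small_design):
    from dinadif.estimation import fit_summary

    q, params = small_design
    fit = em_fit(_simulate(q, params, 600, 0.5, seed=119), q)
    frame = fit_summary(fit)
    assert list(frame["item_id"]) == list(q.item_ids)
    assert (frame["se_slipping"] > 0).all()
    assert frame["converged"].all() == fit.converged


class TestMultiGroupFit:
    def test_non_studied_items_shared_by_construction(self, small_design):
        q, params = small_design
        xr = _simulate(q, params, 500, 0.5, seed=110)
        xf = _simulate(q, params, 500, 0.5, seed=111)
        fit = multigroup_em_fit(xr, xf, q, studied_item=3)
        others = [i for i in range(q.n_items) if i != 2]
        assert np.array_equal(fit.slipping_ref[others], fit.slipping_foc[others])
        assert np.array_equal(fit.guessing_ref[others], fit.guessing_foc[others])

    def test_loglik_nondecreasing(self, small_design):
        q, params = small_design
        xr = _simulate(q, params, 400, 0.5, seed=112)
        xf = _simulate(q, params, 400, 0.5, seed=113)
        fit = multigroup_em_fit(xr, xf, q, studied_item=5)
        assert (np.diff(fit.loglik_history) >= -1e-6).all()

    def test_identical_groups_give_near_zero_differences(self, small_design):
        q, params = small_design
        x = _simulate(q, params, 2000, 0.5, seed=114)
        fit = multigroup_em_fit(x, x, q, studied_item=5)
        est = fit.studied_estimates()  # (s_R, g_R, s_F, g_F)
        assert abs(est[2] - est[0]) < 1e-3 and abs(est[3] - est[1]) < 1e-3

    def test_no_dif_fit_close_to_pooled_single_group_fit(self, small_design):
        q, params = small_design
        xr = _simulate(q, params, 1500, 0.5, seed=115)
        xf = _simulate(q, params, 1500, 0.5, seed=116)
        pooled = em_fit(np.vstack([xr.responses, xf.responses]), q)
        fit = multigroup_em_fit(xr, xf, q, studied_item=2)
        j0 = 1
        assert fit.slipping_ref[j0] == pytest.approx(pooled.params.slipping[j0], abs=0.05)
        assert fit.slipping_foc[j0] == pytest.approx(pooled.params.slipping[j0], abs=0.05)
        others = [i for i in range(q.n_items) if i != j0]
        assert np.allclose(fit.slipping_ref[others], pooled.params.slipping[others], atol=0.02)
        assert np.allclose(fit.guessing_ref[others], pooled.params.guessing[others], atol=0.02)

    def test_studied_item_covariance_positive_definite_block(self, small_design):
        q, params = small_design
        xr = _simulate(q, params, 800, 0.5, seed=117)
        xf = _simulate(q, params, 800, 0.5, seed=118)
        fit = multigroup_em_fit(xr, xf, q, studied_item=1)
        for info in ("item_block", "full"):
            cov4 = studied_item_covariance(fit, info)
            assert cov4.shape == (4, 4)
            assert np.allclose(cov4, cov4.T, atol=1e-10)
            assert (np.diag(cov4) > 0).all()
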
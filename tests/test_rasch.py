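"""Rasch model: closed forms, MML recovery, EAP scoring, score mapping."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm

from phcqual import (PhcqualError, UnidentifiableModelError, eap_abilities,
                     eap_theta, fit_rasch_mml, generate_rasch_responses,
                     map_score, marginal_loglik, rasch_prob)
from phcqual.rasch import RaschFit, gauss_hermite_prior


def _fit_for(difficulties):
    nodes, wts = gauss_hermite_prior(21)
    b = np.asarray(difficulties, dtype=float)
    return RaschFit(item_ids=[f"i{k}" for k in range(b.size)], difficulties=b,
                    quadrature_nodes=nodes, quadrature_weights=wts,
                    log_likelihood=0.0, n_iter=0, final_max_delta=0.0,
                    converged=True)


class TestRaschProb:
    @pytest.mark.parametrize("theta,b,expected", [
        (0.0, 0.0, 0.5),
        (1.0, 0.0, 0.7310586),
        (0.0, 2.0, 0.1192029),
    ])
    def test_logistic_closed_form(self, theta, b, expected):
        assert rasch_prob(theta, b) == pytest.approx(expected, abs=1e-7)

    def test_logit_consistency(self, rng):
        """logit(P) = theta - b to machine tolerance."""
        theta = rng.normal(size=50) * 3
        b = rng.normal(size=50) * 3
        p = rasch_prob(theta, b)
        assert np.allclose(np.log(p / (1 - p)), theta - b, atol=1e-9)

    def test_nonfinite_rejected(self):
        with pytest.raises(PhcqualError):
            rasch_prob(np.inf, 0.0)


class TestFitRaschMML:
    def test_difficulty_recovery_from_generative_model(self, rng):
        b_true = np.linspace(-2, 2, 10)
        theta = rng.standard_normal(2000)
        y = generate_rasch_responses(b_true, theta, rng).astype(float)
        fit = fit_rasch_mml(y)
        assert fit.converged
        assert np.corrcoef(fit.difficulties, b_true)[0, 1] > 0.98
        assert np.sqrt(np.mean((fit.difficulties - b_true) ** 2)) < 0.15

    def test_column_swap_swaps_difficulties(self, rng):
        y = generate_rasch_responses(np.array([-1.0, 0.5, 1.0]),
                                     rng.standard_normal(300), rng).astype(float)
        fit = fit_rasch_mml(y, score_abilities=False)
        swapped = fit_rasch_mml(y[:, [1, 0, 2]], score_abilities=False)
        assert np.allclose(fit.difficulties[[1, 0, 2]], swapped.difficulties,
                           atol=1e-8)

    def test_zero_variance_item_dropped(self, rng):
        y = generate_rasch_responses(np.array([0.0, 0.0]),
                                     rng.standard_normal(200), rng).astype(float)
        y = np.column_stack([y, np.ones(200)])
        with pytest.warns(UserWarning, match="dropped"):
            fit = fit_rasch_mml(y, score_abilities=False)
        assert fit.n_items == 2
        assert fit.dropped_items == [("item_3", "zero variance")]

    def test_all_zero_variance_unidentifiable(self):
        y = np.ones((10, 3))
        with pytest.raises(UnidentifiableModelError):
            fit_rasch_mml(y)

    def test_em_loglik_nondecreasing(self, rng):
        y = generate_rasch_responses(np.linspace(-1, 1, 5),
                                     rng.standard_normal(400), rng).astype(float)
        fit = fit_rasch_mml(y, score_abilities=False)
        assert np.all(np.diff(fit.loglik_path) >= -1e-8)

    def test_stored_loglik_matches_reevaluation(self, rng):
        y = generate_rasch_responses(np.linspace(-1, 1, 4),
                                     rng.standard_normal(200), rng).astype(float)
        fit = fit_rasch_mml(y, score_abilities=False)
        assert marginal_loglik(fit, y) == pytest.approx(fit.log_likelihood)

    def test_missing_cells_ignored_in_likelihood(self, rng):
        y = generate_rasch_responses(np.array([0.0, 0.5, -0.5]),
                                     rng.standard_normal(300), rng).astype(float)
        y_missing = y.copy()
        y_missing[rng.random(y.shape) < 0.2] = np.nan
        fit = fit_rasch_mml(y_missing, score_abilities=False)
        assert fit.converged and np.isfinite(fit.difficulties).all()

    def test_small_instance_direct_likelihood_oracle(self, rng):
        """MML estimates agree with a direct maximization of the marginal
        likelihood implemented independently of the EM path."""
        b_true = np.array([-0.8, 0.0, 0.9])
        y = generate_rasch_responses(b_true, rng.standard_normal(60), rng).astype(float)
        fit = fit_rasch_mml(y, tol=1e-10, score_abilities=False)

        # independent objective: Gauss-Hermite marginal likelihood from scratch
        gh_x, gh_w = np.polynomial.hermite.hermgauss(21)
        nodes, wts = gh_x * np.sqrt(2.0), gh_w / np.sqrt(np.pi)

        def neg_marg_loglik(b):
            p = 1.0 / (1.0 + np.exp(-(nodes[:, None] - b[None, :])))  # K x I
            like = np.prod(np.where(y[:, None, :] == 1, p[None, :, :],
                                    1 - p[None, :, :]), axis=2)  # J x K
            return -np.sum(np.log(like @ wts))

        res = minimize(neg_marg_loglik, x0=np.zeros(3), method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 5000})
        assert res.success
        assert np.max(np.abs(fit.difficulties - res.x)) < 1e-3

    def test_recovery_error_decreases_with_sample_size(self):
        """Bias and RMSE of the difficulty estimates shrink as n grows."""
        b_true = np.linspace(-1.5, 1.5, 6)
        rmse = {}
        for n in (250, 1000, 4000):
            errs = []
            for rep in range(20):
                rng = np.random.default_rng(1000 * n + rep)
                y = generate_rasch_responses(b_true, rng.standard_normal(n),
                                             rng).astype(float)
                fit = fit_rasch_mml(y, score_abilities=False)
                errs.append(fit.difficulties - b_true)
            rmse[n] = float(np.sqrt(np.mean(np.square(errs))))
        assert rmse[4000] < rmse[1000] < rmse[250]


class TestEAP:
    def test_identical_patterns_identical_theta(self):
        fit = _fit_for([-1.0, 0.0, 1.0])
        theta = eap_abilities(fit, np.array([[1., 0., 1.], [1., 0., 1.]]))
        assert theta[0] == theta[1]

    def test_all_zero_pattern_has_minimum_eap(self):
        fit = _fit_for([-1.0, 0.0, 1.0])
        patterns = np.array([[a, b, c] for a in (0, 1) for b in (0, 1)
                             for c in (0, 1)], dtype=float)
        theta = eap_abilities(fit, patterns)
        assert np.argmin(theta) == 0  # the (0,0,0) pattern

    def test_single_item_eap_matches_fine_grid_integration(self):
        fit = _fit_for([0.0])
        got = eap_theta(fit, [1.0])
        grid = np.linspace(-8, 8, 40001)
        w = expit(grid) * norm.pdf(grid)
        expected = np.trapezoid(grid * w, grid) / np.trapezoid(w, grid)
        assert got == pytest.approx(expected, abs=1e-6)

    def test_all_missing_undefined(self):
        fit = _fit_for([0.0, 1.0])
        with pytest.raises(PhcqualError):
            eap_theta(fit, [np.nan, np.nan])

    def test_eap_strictly_increasing_in_sum_score(self, rng):
        """On complete data the EAP is a strictly increasing function of the
        raw sum score (sum-score sufficiency of the Rasch model)."""
        b = np.linspace(-1, 1, 6)
        y = generate_rasch_responses(b, rng.standard_normal(500), rng).astype(float)
        fit = fit_rasch_mml(y)
        sums = y.sum(axis=1)
        theta = fit.ability_estimates
        means = {s: theta[sums == s].mean() for s in np.unique(sums)}
        # identical sum -> identical EAP
        for s in means:
            assert np.allclose(theta[sums == s], means[s])
        ordered = [means[s] for s in sorted(means)]
        assert np.all(np.diff(ordered) > 0)


class TestMapScore:
    def test_symmetric_pair(self):
        assert map_score(_fit_for([-1.0, 1.0]), 0.0) == pytest.approx(0.5)

    def test_single_item_symmetry_point(self):
        assert map_score(_fit_for([0.0]), 0.0) == pytest.approx(0.5)

    def test_three_item_closed_form(self):
        got = map_score(_fit_for([0.0, 0.0, 2.0]), 0.0)
        assert got == pytest.approx(0.3730676, abs=1e-6)

    def test_strictly_increasing_with_limits(self):
        fit = _fit_for([-1.0, 0.3, 2.0])
        thetas = np.linspace(-10, 10, 101)
        scores = map_score(fit, thetas)
        assert np.all(np.diff(scores) > 0)
        assert map_score(fit, -40.0) == pytest.approx(0.0, abs=1e-12)
        assert map_score(fit, 40.0) == pytest.approx(1.0, abs=1e-12)


class TestMarginalLoglik:
    def test_single_unit_single_item_symmetry(self):
        """With b=0 and response 1, the marginal likelihood is exactly 1/2."""
        fit = _fit_for([0.0])
        assert marginal_loglik(fit, np.array([[1.0]])) == pytest.approx(
            np.log(0.5), abs=1e-10)

    def test_empty_response_set_is_zero(self):
        fit = _fit_for([0.0, 1.0])
        assert marginal_loglik(fit, np.full((3, 2), np.nan)) == pytest.approx(0.0)
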
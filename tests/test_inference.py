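"""Cluster-robust subgroup summaries and the provider regression."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from phcqual import (DegenerateClusterError, cluster_robust_mean,
                     fit_provider_regression, subgroup_means, subgroup_test)


def _providers(rng, n=300, g=9, effects=(0.0, 0.20, 0.26), sigma=0.25):
    levels = ["village clinic", "township health centre", "county hospital"]
    facility = rng.choice(levels, size=n, p=[0.5, 0.3, 0.2])
    town = rng.integers(0, g, size=n)
    eff = dict(zip(levels, effects))
    log_comp = (-1.6 + np.array([eff[f] for f in facility])
                + rng.normal(0, 0.05, g)[town] + rng.normal(0, sigma, n))
    frame = pd.DataFrame({
        "provider_id": np.arange(n),
        "facility_level": facility,
        "town": [f"t{t}" for t in town],
        "gender": rng.choice(["female", "male"], n),
        "education": rng.choice(["college_or_above", "high_school_or_below"], n),
        "permanent_post": rng.choice(["yes", "no"], n),
        "passed_licensing_exam": rng.choice(["yes", "no"], n),
        "job_title": rng.choice(["yes", "no"], n),
        "administrative_role": rng.choice(["yes", "no"], n),
        "job_satisfaction": rng.choice(["satisfied", "not satisfied"], n),
    })
    return frame, np.exp(log_comp)


class TestClusterRobustMean:
    def test_single_cluster_degenerate(self):
        summaries = subgroup_means([0.8, 0.8, 0.8], ["a"] * 3, ["t1"] * 3,
                                   dimension="gender")
        assert summaries[0].mean == pytest.approx(0.8)
        assert summaries[0].degenerate

    def test_one_unit_per_cluster_equals_hc1(self, rng):
        """With singleton clusters the CR variance collapses to HC1."""
        y = rng.random(40)
        clusters = np.arange(40).astype(str)
        _, se, _, g = cluster_robust_mean(y, clusters)
        res = sm.OLS(y, np.ones((40, 1))).fit(cov_type="HC1")
        assert g == 40
        assert se == pytest.approx(float(res.bse[0]), rel=1e-10)

    def test_matches_statsmodels_cluster_ols(self, rng):
        y = rng.random(60)
        clusters = rng.integers(0, 6, size=60)
        _, se, _, _ = cluster_robust_mean(y, clusters)
        res = sm.OLS(y, np.ones((60, 1))).fit(
            cov_type="cluster", cov_kwds={"groups": clusters}, use_t=True)
        assert se == pytest.approx(float(res.bse[0]), rel=1e-10)

    def test_ci_brackets_mean(self, rng):
        y = rng.random(100)
        clusters = rng.integers(0, 9, size=100)
        mean, se, (lo, hi), _ = cluster_robust_mean(y, clusters)
        assert lo <= mean <= hi


class TestSubgroupTest:
    def test_identical_vectors_p_one(self):
        y = np.array([0.2, 0.5, 0.9, 0.4])
        cl = np.array(["a", "a", "b", "b"])
        assert subgroup_test(y, cl, y, cl) == 1.0

    def test_declined_below_two_clusters(self):
        with pytest.raises(DegenerateClusterError):
            subgroup_test([0.1, 0.2], ["a", "a"], [0.3, 0.4], ["b", "c"])

    def test_detects_large_difference(self, rng):
        g = rng.integers(0, 9, size=400)
        y_a = 0.9 + rng.normal(0, 0.05, 400)
        y_b = 0.3 + rng.normal(0, 0.05, 400)
        cl = np.array([f"t{i}" for i in g])
        assert subgroup_test(y_a, cl, y_b, cl) < 1e-4

    def test_power_for_small_true_difference(self):
        """A 0.05 score difference with within-SD 0.15 at n=1350 is detected
        with power above 0.8."""
        rejections = 0
        reps = 100
        for rep in range(reps):
            r = np.random.default_rng(600 + rep)
            towns = r.integers(0, 9, size=1350)
            cl = np.array([f"t{t}" for t in towns])
            grp = r.random(1350) < 0.5
            y = 0.70 + 0.05 * grp + r.normal(0, 0.15, 1350)
            if subgroup_test(y[grp], cl[grp], y[~grp], cl[~grp]) < 0.05:
                rejections += 1
        assert rejections / reps > 0.8

    def test_subgroup_means_reports_reference_pvalues(self, rng):
        scores = rng.random(200)
        groups = rng.choice(["f", "m"], 200)
        clusters = rng.integers(0, 9, 200).astype(str)
        out = subgroup_means(scores, groups, clusters, dimension="gender")
        assert [s.level for s in out] == ["f", "m"]
        assert out[0].p_vs_ref is None and 0 <= out[1].p_vs_ref <= 1

    def test_missing_scores_dropped(self, rng):
        scores = np.array([0.5, np.nan, 0.7, 0.9])
        out = subgroup_means(scores, ["a", "a", "a", "a"],
                             ["t1", "t1", "t2", "t2"], dimension="x")
        assert out[0].n == 3


class TestProviderRegression:
    def test_constant_response_flat_fit(self, rng):
        frame, _ = _providers(rng)
        competence = np.full(len(frame), 0.4)
        res = fit_provider_regression(frame, competence, model_id="model1")
        assert res.terms.loc["intercept", "coef"] == pytest.approx(np.log(0.4))
        slopes = res.terms.drop(index="intercept")["coef"]
        assert np.allclose(slopes, 0.0, atol=1e-12)

    def test_recovers_workplace_effects(self, rng):
        frame, competence = _providers(rng, n=2000)
        res = fit_provider_regression(frame, competence, model_id="model1")
        terms = res.terms
        assert terms.loc["facility_level[township health centre]", "coef"] == \
            pytest.approx(0.20, abs=0.08)
        assert terms.loc["facility_level[county hospital]", "coef"] == \
            pytest.approx(0.26, abs=0.08)

    def test_exact_collinearity_dropped_with_warning(self, rng):
        frame, competence = _providers(rng)
        frame["education"] = np.where(frame["facility_level"] == "village clinic",
                                      "high_school_or_below", "college_or_above")
        with pytest.warns(UserWarning, match="collinear"):
            res = fit_provider_regression(frame, competence, model_id="model2")
        assert res.dropped_terms
        assert np.isfinite(res.terms["se"]).all()

    def test_log_scale_rescaling_shifts_only_intercept(self, rng):
        frame, competence = _providers(rng)
        res1 = fit_provider_regression(frame, competence, model_id="model3")
        res2 = fit_provider_regression(frame, competence * 0.5, model_id="model3")
        assert res2.terms.loc["intercept", "coef"] - \
            res1.terms.loc["intercept", "coef"] == pytest.approx(np.log(0.5))
        a = res1.terms.drop(index="intercept")["coef"]
        b = res2.terms.drop(index="intercept")["coef"]
        assert np.allclose(a, b, atol=1e-10)

    def test_out_of_range_competence_rejected(self, rng):
        frame, _ = _providers(rng)
        with pytest.raises(Exception):
            fit_provider_regression(frame, np.full(len(frame), 1.2))

    def test_response_rate_weights_accepted(self, rng):
        frame, competence = _providers(rng)
        res = fit_provider_regression(
            frame, competence, model_id="model1",
            response_rate_weights={"village clinic": 0.899,
                                   "township health centre": 0.842,
                                   "county hospital": 0.94})
        assert res.weighted and np.isfinite(res.terms["coef"]).all()
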
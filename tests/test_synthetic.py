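"""Generator behaviour: determinism, marginal fidelity, missingness."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

from phcqual import (ConfigError, SyntheticConfig, default_catalog,
                     generate_patients, generate_rasch_responses,
                     generate_registry, generate_tables, inject_missingness,
                     binarize)
from phcqual.rasch import gauss_hermite_prior


def test_degenerate_probability_gives_all_ones(catalog):
    cfg = SyntheticConfig(n_patients=50, seed=0,
                          indicator_probs={s: 1.0 for s in
                                           SyntheticConfig().indicator_probs})
    patients = generate_patients(cfg, catalog)
    survey_cols = [e.indicator_id for e in catalog.entries_for(source="patient survey")]
    present = [c for c in survey_cols if c in patients.columns]
    assert present and (patients[present].to_numpy() == 1).all()


def test_seed_determinism_byte_identical(small_config, catalog):
    a = generate_tables(small_config, catalog)
    b = generate_tables(small_config, catalog)
    for name in a:
        assert a[name].to_csv(index=False) == b[name].to_csv(index=False)


def test_different_seeds_differ(small_config, catalog):
    other = SyntheticConfig(**{**small_config.to_dict(), "seed": small_config.seed + 1})
    a = generate_tables(small_config, catalog)["patients"]
    b = generate_tables(other, catalog)["patients"]
    assert not a.equals(b)


def test_indicator_mean_matches_binomial_oracle(catalog):
    p = 0.887
    cfg = SyntheticConfig(n_patients=5000, seed=2)
    patients = generate_patients(cfg, catalog)
    observed = patients["com_health_education"].mean()
    tol = 3 * np.sqrt(p * (1 - p) / 5000)
    assert abs(observed - p) < tol


def test_covariate_marginal_fidelity_chisquare(catalog):
    """Generated covariate frequencies match the configured marginals."""
    cfg = SyntheticConfig(n_patients=10000, seed=3)
    patients = generate_patients(cfg, catalog)
    for cov in ("gender", "disease_group", "income_quintile"):
        dist = cfg.covariate_marginals[cov]
        counts = patients[cov].value_counts()
        obs = np.array([counts.get(l, 0) for l in dist])
        exp = np.array([dist[l] for l in dist]) * len(patients)
        p = stats.chisquare(obs, exp).pvalue
        assert p > 0.01, f"marginal mismatch for {cov} (p={p:.4f})"


class TestRaschResponses:
    def test_half_rate_when_theta_equals_b(self, rng):
        y = generate_rasch_responses(np.zeros(1), np.zeros(10000), rng)
        assert abs(y.mean() - 0.5) < 3 * np.sqrt(0.25 / 10000)

    def test_saturation_at_extreme_difficulty(self, rng):
        y = generate_rasch_responses(np.array([-30.0]), rng.standard_normal(200), rng)
        assert (y == 1).all()

    def test_marginal_rate_matches_quadrature_oracle(self, rng):
        theta = rng.standard_normal(10000)
        y = generate_rasch_responses(np.zeros(1), theta, rng)
        nodes, wts = gauss_hermite_prior(41)
        truth = float(expit(nodes) @ wts)
        mc_se = np.sqrt(truth * (1 - truth) / 10000)
        assert abs(y.mean() - truth) < 3 * mc_se

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(Exception):
            generate_rasch_responses(np.zeros((2, 2)), np.zeros(3), rng)


class TestMissingness:
    def _matrix(self, catalog, n=500, seed=4):
        cfg = SyntheticConfig(n_patients=n, seed=seed)
        patients = generate_patients(cfg, catalog)
        patients["followups_per_year"] = 5
        return cfg, patients, binarize(patients, catalog, "patient")

    def test_zero_rate_identity(self, catalog):
        cfg, _, matrix = self._matrix(catalog)
        cfg = SyntheticConfig(**{**cfg.to_dict(), "missing_rate": 0.0})
        out = inject_missingness(matrix, cfg)
        assert np.array_equal(out.mask, matrix.mask)
        assert np.array_equal(out.values, matrix.values, equal_nan=True)

    def test_mcar_rate_binomial_oracle(self, catalog):
        cfg, _, matrix = self._matrix(catalog)
        cfg = SyntheticConfig(**{**cfg.to_dict(), "missing_rate": 0.2})
        out = inject_missingness(matrix, cfg)
        frac = out.mask.mean()
        n_cells = matrix.values.size
        assert n_cells >= 10000
        assert abs(frac - 0.2) < 3 * np.sqrt(0.2 * 0.8 / n_cells)

    def test_mar_rates_by_gender(self, catalog):
        cfg, patients, matrix = self._matrix(catalog, n=1000)
        cfg = SyntheticConfig(**{**cfg.to_dict(), "missing_rate": 0.2,
                                 "missing_mechanism": "MAR",
                                 "mar_rates": {"female": 0.1, "male": 0.3}})
        out = inject_missingness(matrix, cfg, covariate_values=patients["gender"])
        for level, rate in (("female", 0.1), ("male", 0.3)):
            rows = (patients["gender"] == level).to_numpy()
            frac = out.mask[rows].mean()
            n_cells = rows.sum() * matrix.n_indicators
            assert abs(frac - rate) < 3 * np.sqrt(rate * (1 - rate) / n_cells)

    def test_original_values_retained(self, catalog):
        cfg, _, matrix = self._matrix(catalog)
        cfg = SyntheticConfig(**{**cfg.to_dict(), "missing_rate": 0.3})
        out = inject_missingness(matrix, cfg)
        assert np.array_equal(out.original_values, matrix.values, equal_nan=True)
        # observed cells agree with the originals
        obs = ~out.mask
        assert np.array_equal(out.values[obs], matrix.values[obs])


def test_registry_dates_strictly_increasing(small_tables):
    registry = small_tables["registry"]
    for _, visits in registry.groupby("patient_id"):
        dates = pd.to_datetime(visits["visit_date"])
        assert dates.is_monotonic_increasing and dates.is_unique


def test_no_village_clinic_charts(small_tables):
    assert (small_tables["charts"]["facility_level"] != "village clinic").all()


@pytest.mark.parametrize("bad", [
    {"indicator_probs": {"continuity": 1.2}},
    {"missing_rate": 1.0},
    {"cluster_sizes": {}},
    {"cluster_sizes": {"counties": 0}},
    {"covariate_marginals": {"gender": {"female": 0.7, "male": 0.2}}},
    {"n_patients": -5},
])
def test_invalid_configuration_rejected(bad):
    with pytest.raises(ConfigError):
        SyntheticConfig(**bad)
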
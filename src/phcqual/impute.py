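"""Multiple imputation by chained equations (MICE) and Rubin pooling.

Each column with missing cells gets a per-column conditional model fitted
on the currently completed data: binary indicator columns use a logistic
model with a posterior draw of the coefficients (approximate proper
imputation), non-binary numeric columns use predictive mean matching.
Columns are visited in order of increasing missingness, ``cycles`` times
per completed dataset, ``m`` datasets in total; every draw flows from the
given seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .errors import ConfigError, ShapeError
from .matrix import IndicatorMatrix

DEFAULT_M = 10
DEFAULT_CYCLES = 10
_PMM_DONORS = 5


@dataclass
class ImputationSet:
    """``m`` completed copies of an indicator matrix."""

    m: int
    completed: list[IndicatorMatrix]
    models: dict[str, str]  # column -> model family used
    seed: int

    def pooled_column_means(self) -> pd.Series:
        """Across-imputation average of per-column means (Rubin Q-bar)."""
        stacked = np.stack([c.values for c in self.completed])
        return pd.Series(stacked.mean(axis=(0, 1)), index=self.completed[0].columns)


@dataclass
class PooledEstimate:
    """Rubin's-rules combination of per-imputation estimates."""

    estimate: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    m: int

    @property
    def se(self) -> float:
        return math.sqrt(self.total_var)


def pool_estimates(estimates, variances) -> PooledEstimate:
    """Combine per-imputation point estimates and variances.

    Q-bar = mean(estimates); B = sample variance of the estimates (n-1);
    T = W-bar + (1 + 1/m) B; degrees of freedom by Rubin's formula
    (infinite when B = 0 or m = 1).
    """
    q = np.asarray(list(estimates), dtype=float)
    u = np.asarray(list(variances), dtype=float)
    if q.shape != u.shape or q.ndim != 1 or q.size == 0:
        raise ShapeError("estimates and variances must be equal-length non-empty vectors")
    m = q.size
    qbar = float(q.mean())
    wbar = float(u.mean())
    if m == 1:
        return PooledEstimate(qbar, wbar, 0.0, wbar, float("inf"), 1)
    b = float(q.var(ddof=1))
    t = wbar + (1.0 + 1.0 / m) * b
    if b == 0.0:
        df = float("inf")
    else:
        df = (m - 1) * (1.0 + wbar / ((1.0 + 1.0 / m) * b)) ** 2
    return PooledEstimate(qbar, wbar, b, t, df, m)


def _encode_covariates(covariates: pd.DataFrame | None, n: int) -> np.ndarray:
    if covariates is None or covariates.shape[1] == 0:
        return np.empty((n, 0))
    if len(covariates) != n:
        raise ShapeError("covariates do not match the number of units")
    enc = pd.get_dummies(covariates, drop_first=True, dtype=float)
    return enc.to_numpy()


def _is_binary(col: np.ndarray) -> bool:
    obs = col[~np.isnan(col)]
    return obs.size > 0 and np.isin(obs, (0.0, 1.0)).all()


def _draw_binary(y_obs, x_obs, x_mis, rng):
    """Posterior-draw logistic imputation; Jeffreys-Bernoulli fallback."""
    if y_obs.min() != y_obs.max() and x_obs.shape[1] > 1:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y_obs, x_obs).fit(disp=0, maxiter=50)
            cov = np.asarray(res.cov_params(), dtype=float)
            beta = rng.multivariate_normal(res.params, cov, method="cholesky")
            p = expit(x_mis @ beta)
            if np.isfinite(p).all():
                return (rng.random(len(p)) < p).astype(float), "logistic"
        except Exception:
            pass
    # independence fallback: Beta(y+1/2, n-y+1/2) posterior draw of the rate
    p = rng.beta(y_obs.sum() + 0.5, len(y_obs) - y_obs.sum() + 0.5)
    return (rng.random(x_mis.shape[0]) < p).astype(float), "bernoulli-beta"


def _draw_pmm(y_obs, x_obs, x_mis, rng):
    """Predictive mean matching with posterior-perturbed linear predictions."""
    res = sm.OLS(y_obs, x_obs).fit()
    cov = np.asarray(res.cov_params(), dtype=float)
    beta = rng.multivariate_normal(res.params, cov, method="cholesky")
    pred_obs = x_obs @ res.params
    pred_mis = x_mis @ beta
    out = np.empty(len(pred_mis))
    k = min(_PMM_DONORS, len(y_obs))
    for j, pm in enumerate(pred_mis):
        donors = np.argsort(np.abs(pred_obs - pm))[:k]
        out[j] = y_obs[donors[rng.integers(0, k)]]
    return out, "pmm"


def mice_impute(
    matrix: IndicatorMatrix,
    covariates: pd.DataFrame | None = None,
    m: int = DEFAULT_M,
    cycles: int = DEFAULT_CYCLES,
    seed: int = 0,
    within_subdomain: bool = True,
) -> ImputationSet:
    """Chained-equations multiple imputation of an indicator matrix.

    Each column's model conditions on the (encoded) covariates plus, when
    ``within_subdomain`` is set, the other indicators of the same
    sub-domain — preserving the within-scale correlation the summative
    scores depend on.  Observed cells are never altered.
    """
    if m < 1:
        raise ConfigError("m must be >= 1")
    if cycles < 1:
        raise ConfigError("cycles must be >= 1")
    values = matrix.values
    n, k = values.shape
    fully_missing = [c for c, j in zip(matrix.columns, range(k))
                     if np.isnan(values[:, j]).all()]
    if fully_missing:
        raise ConfigError(
            f"columns with no observed cells cannot be imputed: {fully_missing}")
    base_x = _encode_covariates(covariates, n)
    missing_cols = [j for j in range(k) if np.isnan(values[:, j]).any()]
    order = sorted(missing_cols, key=lambda j: np.isnan(values[:, j]).sum())
    models: dict[str, str] = {}
    seeds = np.random.SeedSequence(seed).spawn(m)

    completed: list[IndicatorMatrix] = []
    for d in range(m):
        rng = np.random.default_rng(seeds[d])
        filled = values.copy()
        # initial fill: random draws from each column's observed values
        for j in order:
            miss = np.isnan(filled[:, j])
            obs = values[~np.isnan(values[:, j]), j]
            filled[miss, j] = rng.choice(obs, size=miss.sum())
        for _ in range(cycles if missing_cols else 0):
            for j in order:
                miss = np.isnan(values[:, j])
                if within_subdomain:
                    sub = matrix.sub_domain_of(matrix.columns[j])
                    peers = [jj for jj in range(k) if jj != j
                             and matrix.sub_domain_of(matrix.columns[jj]) == sub]
                else:
                    peers = [jj for jj in range(k) if jj != j]
                x = np.column_stack([np.ones(n), base_x, filled[:, peers]]) \
                    if peers or base_x.size else np.ones((n, 1))
                y_obs = values[~miss, j]
                if _is_binary(values[:, j]):
                    draw, family = _draw_binary(y_obs, x[~miss], x[miss], rng)
                else:
                    draw, family = _draw_pmm(y_obs, x[~miss], x[miss], rng)
                filled[miss, j] = draw
                models[matrix.columns[j]] = family
        completed.append(matrix.with_values(filled))
    return ImputationSet(m=m, completed=completed, models=models, seed=seed)
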
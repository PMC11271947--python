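"""Subgroup summaries and the provider-competence regression, with
cluster-robust variance at the town level.

Survey units within a town share unobserved context, so all standard
errors allow arbitrary within-town correlation: CR1 sandwich variance with
the small-sample factor G/(G-1) and a t reference distribution on G-1
degrees of freedom, where G is the number of clusters.  With one unit per
cluster these collapse to the classical heteroskedasticity-robust answers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DegenerateClusterError, ShapeError


@dataclass
class SubgroupSummary:
    dimension: str
    level: str
    n: int
    mean: float
    se: float
    ci_low: float
    ci_high: float
    n_clusters: int
    degenerate: bool = False
    p_vs_ref: float | None = None


def cluster_robust_mean(y, clusters, alpha: float = 0.05):
    """Mean with CR1 cluster-robust SE and a t(G-1) confidence interval."""
    y = np.asarray(y, dtype=float)
    clusters = np.asarray(clusters)
    if y.shape != clusters.shape:
        raise ShapeError("scores and cluster labels differ in length")
    keep = ~np.isnan(y)
    y, clusters = y[keep], clusters[keep]
    n = y.size
    if n == 0:
        raise DegenerateClusterError("no observations")
    mean = float(y.mean())
    labels = pd.unique(clusters)
    g = len(labels)
    if g < 2:
        return mean, float("nan"), (float("nan"), float("nan")), g
    resid = y - mean
    u = np.array([resid[clusters == c].sum() for c in labels])
    var = g / (g - 1) * float((u ** 2).sum()) / n ** 2
    se = math.sqrt(var)
    tcrit = stats.t.ppf(1 - alpha / 2, df=g - 1)
    return mean, se, (mean - tcrit * se, mean + tcrit * se), g


def subgroup_means(
    scores,
    groups,
    clusters,
    dimension: str = "",
    ref_level: str | None = None,
    alpha: float = 0.05,
) -> list[SubgroupSummary]:
    """Per-level score means with cluster-robust 95% CIs.

    Levels with zero (non-missing) units are omitted with a warning; levels
    whose units span fewer than two clusters are flagged degenerate.  When
    a reference level is given (default: the first level in sorted order),
    every other level gets a cluster-robust Wald p-value against it.
    """
    frame = pd.DataFrame({
        "score": np.asarray(scores, dtype=float),
        "group": np.asarray(groups).astype(str),
        "cluster": np.asarray(clusters).astype(str),
    }).dropna(subset=["score"])
    levels = sorted(frame["group"].unique())
    if not levels:
        raise DegenerateClusterError("no observed scores in any level")
    if ref_level is None:
        ref_level = levels[0]
    out = []
    for level in levels:
        sub = frame[frame["group"] == level]
        if sub.empty:
            warnings.warn(f"level {level!r} of {dimension!r} has no observations; omitted",
                          stacklevel=2)
            continue
        mean, se, (lo, hi), g = cluster_robust_mean(
            sub["score"].to_numpy(), sub["cluster"].to_numpy(), alpha)
        p = None
        if level != ref_level:
            ref = frame[frame["group"] == ref_level]
            try:
                p = subgroup_test(sub["score"].to_numpy(), sub["cluster"].to_numpy(),
                                  ref["score"].to_numpy(), ref["cluster"].to_numpy())
            except DegenerateClusterError:
                p = None
        out.append(SubgroupSummary(
            dimension=dimension, level=level, n=len(sub), mean=mean, se=se,
            ci_low=lo, ci_high=hi, n_clusters=g,
            degenerate=(g < 2 or not np.isfinite(se) or se == 0.0), p_vs_ref=p))
    return out


def subgroup_test(y_a, clusters_a, y_b, clusters_b) -> float:
    """Cluster-robust Wald t-test of the two-group mean difference.

    Fits the difference as a regression of the pooled scores on a group
    indicator with CR1 cluster variance and a t(G-1) reference.  Declined
    (raises) when either group spans fewer than two clusters.
    """
    y_a = np.asarray(y_a, dtype=float)
    y_b = np.asarray(y_b, dtype=float)
    clusters_a = np.asarray(clusters_a).astype(str)
    clusters_b = np.asarray(clusters_b).astype(str)
    for name, (y, cl) in {"a": (y_a, clusters_a), "b": (y_b, clusters_b)}.items():
        if y.shape != cl.shape:
            raise ShapeError(f"group {name}: scores and clusters differ in length")
        if len(pd.unique(cl[~np.isnan(y)])) < 2:
            raise DegenerateClusterError(
                f"group {name} spans fewer than two clusters; test declined")
    y = np.concatenate([y_a, y_b])
    keep = ~np.isnan(y)
    indicator = np.concatenate([np.ones(y_a.size), np.zeros(y_b.size)])[keep]
    clusters = np.concatenate([clusters_a, clusters_b])[keep]
    y = y[keep]
    if float(y_a[~np.isnan(y_a)].mean()) == float(y_b[~np.isnan(y_b)].mean()):
        return 1.0  # exactly zero difference (covers the zero-variance case)
    x = sm.add_constant(indicator)
    res = sm.OLS(y, x).fit(cov_type="cluster",
                           cov_kwds={"groups": pd.Categorical(clusters).codes},
                           use_t=True)
    return float(res.pvalues[1])


@dataclass
class RegressionResult:
    model_id: str
    terms: pd.DataFrame  # coef, se, ci_low, ci_high, p per predictor
    n: int
    n_clusters: int
    cluster_level: str
    dropped_terms: list[str]
    weighted: bool

    def to_frame(self) -> pd.DataFrame:
        out = self.terms.copy()
        out.insert(0, "model", self.model_id)
        return out


#: predictors entering each nested specification, with reference levels
MODEL_TERMS = {
    "model1": ["facility_level"],
    "model2": ["facility_level", "gender", "education"],
    "model3": ["facility_level", "gender", "education", "permanent_post",
               "passed_licensing_exam", "job_title", "administrative_role",
               "job_satisfaction"],
}

_REFERENCE_LEVELS = {
    "facility_level": "village clinic",
    "gender": "female",
    "education": "college_or_above",
    "permanent_post": "no",
    "passed_licensing_exam": "no",
    "job_title": "no",
    "administrative_role": "no",
    "job_satisfaction": "not satisfied",
}


def _design(providers: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    cols = {}
    for term in terms:
        if term not in providers.columns:
            raise ShapeError(f"provider table lacks predictor {term!r}")
        series = providers[term].astype(str)
        ref = _REFERENCE_LEVELS.get(term)
        levels = [l for l in sorted(series.unique()) if l != ref]
        for level in levels:
            cols[f"{term}[{level}]"] = (series == level).astype(float)
    x = pd.DataFrame(cols, index=providers.index)
    x.insert(0, "intercept", 1.0)
    return x


def fit_provider_regression(
    providers: pd.DataFrame,
    competence,
    model_id: str = "model3",
    cluster: str = "town",
    response_rate_weights: dict[str, float] | None = None,
) -> RegressionResult:
    """OLS of log provider competence on provider characteristics.

    Competence scores must lie strictly in (0, 1) (as produced by the Rasch
    test-characteristic-curve mapping); the response is their natural
    logarithm, so coefficients read as approximate proportional competence
    differences.  Standard errors are clustered at the town level.
    Optional inverse response-rate weights (per facility level) adjust for
    differential survey response.  Perfectly collinear columns are dropped
    with a warning and listed on the result.
    """
    if model_id not in MODEL_TERMS:
        raise KeyError(f"unknown model id {model_id!r}")
    competence = np.asarray(competence, dtype=float)
    if competence.shape[0] != len(providers):
        raise ShapeError("competence scores do not match the provider table")
    if np.nanmin(competence) <= 0.0 or np.nanmax(competence) >= 1.0:
        raise ShapeError("competence scores must lie strictly in (0, 1)")
    if cluster not in providers.columns:
        raise ShapeError(f"provider table lacks cluster column {cluster!r}")
    y = np.log(competence)
    x = _design(providers, MODEL_TERMS[model_id])

    # drop exactly collinear columns via a rank-revealing QR
    dropped: list[str] = []
    q, r = np.linalg.qr(x.to_numpy())
    diag = np.abs(np.diag(r))
    tol = diag.max() * len(x) * np.finfo(float).eps * 1e3
    for j, name in enumerate(x.columns):
        if j < len(diag) and diag[j] < tol:
            dropped.append(name)
    if dropped:
        warnings.warn(f"dropping perfectly collinear predictors: {dropped}",
                      stacklevel=2)
        x = x.drop(columns=dropped)

    groups = pd.Categorical(providers[cluster].astype(str)).codes
    n_clusters = len(np.unique(groups))
    if n_clusters < 2:
        raise DegenerateClusterError("regression needs at least two clusters")
    if response_rate_weights is not None:
        rates = providers["facility_level"].astype(str).map(response_rate_weights)
        if rates.isna().any():
            raise ShapeError("response rate missing for some facility level")
        w = 1.0 / rates.to_numpy(dtype=float)
        model = sm.WLS(y, x, weights=w)
    else:
        model = sm.OLS(y, x)
    res = model.fit(cov_type="cluster", cov_kwds={"groups": groups}, use_t=True)
    ci = res.conf_int()
    terms = pd.DataFrame({
        "coef": res.params,
        "se": res.bse,
        "ci_low": ci[0] if isinstance(ci, pd.DataFrame) else ci[:, 0],
        "ci_high": ci[1] if isinstance(ci, pd.DataFrame) else ci[:, 1],
        "p": res.pvalues,
    })
    terms.index.name = "term"
    return RegressionResult(
        model_id=model_id, terms=terms, n=len(providers),
        n_clusters=n_clusters, cluster_level=cluster, dropped_terms=dropped,
        weighted=response_rate_weights is not None,
    )
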
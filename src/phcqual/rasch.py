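"""Dichotomous Rasch (one-parameter logistic IRT) scoring.

The model: the probability that unit j endorses item i is

    P(Y_ij = 1 | theta_j) = exp(theta_j - b_i) / (1 + exp(theta_j - b_i)),

with person ability ``theta_j ~ N(0,1)`` (fixed, not estimated) and item
difficulty ``b_i``.  Item difficulties are estimated by marginal maximum
likelihood: the ability is integrated out under its standard-normal prior
by Gauss-Hermite quadrature and the marginal likelihood is maximised with
an EM algorithm (expected item-level counts in the E-step, one monotone
1-D root-solve per item in the M-step).  Person abilities are scored as
posterior means (EAP), and mapped onto the [0,1] quality scale through the
test characteristic curve: the expected proportion of the instrument's
items endorsed at that ability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logsumexp

from .errors import PhcqualError, ShapeError, UnidentifiableModelError
from .matrix import IndicatorMatrix

DEFAULT_QUADRATURE_NODES = 21
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 500


def rasch_prob(theta, b):
    """Endorsement probability ``sigma(theta - b)``, overflow-safe.

    ``logit(rasch_prob(theta, b)) == theta - b`` to machine tolerance.
    """
    theta = np.asarray(theta, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.isfinite(theta).all() and np.isfinite(b).all()):
        raise PhcqualError("rasch_prob requires finite ability and difficulty")
    out = expit(theta - b)
    return float(out) if out.ndim == 0 else out


def gauss_hermite_prior(n_nodes: int = DEFAULT_QUADRATURE_NODES):
    """Quadrature nodes/weights for integrals against the N(0,1) density."""
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    return x * np.sqrt(2.0), w / np.sqrt(np.pi)


@dataclass
class RaschFit:
    """Result of a marginal-maximum-likelihood Rasch fit."""

    item_ids: list[str]
    difficulties: np.ndarray
    quadrature_nodes: np.ndarray
    quadrature_weights: np.ndarray
    log_likelihood: float
    n_iter: int
    final_max_delta: float
    converged: bool
    dropped_items: list[tuple[str, str]] = field(default_factory=list)
    loglik_path: list[float] = field(default_factory=list)
    ability_estimates: np.ndarray | None = None
    unit_ids: np.ndarray | None = None

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    def to_dict(self) -> dict:
        return {
            "item_ids": list(self.item_ids),
            "difficulties": [float(b) for b in self.difficulties],
            "quadrature": {
                "n_nodes": int(len(self.quadrature_nodes)),
                "nodes": [float(x) for x in self.quadrature_nodes],
                "weights": [float(w) for w in self.quadrature_weights],
            },
            "log_likelihood": float(self.log_likelihood),
            "convergence": {
                "n_iter": int(self.n_iter),
                "final_max_delta": float(self.final_max_delta),
                "converged": bool(self.converged),
            },
            "dropped_items": [list(t) for t in self.dropped_items],
        }


def _coerce(matrix) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Accept an IndicatorMatrix, DataFrame or ndarray; NaN marks missing."""
    if isinstance(matrix, IndicatorMatrix):
        return matrix.values, list(matrix.columns), matrix.unit_ids
    if isinstance(matrix, pd.DataFrame):
        return matrix.to_numpy(dtype=float), [str(c) for c in matrix.columns], \
            matrix.index.to_numpy()
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2:
        raise ShapeError("response matrix must be 2-D")
    return arr, [f"item_{i+1}" for i in range(arr.shape[1])], np.arange(arr.shape[0])


def _loglik_terms(values: np.ndarray, b: np.ndarray, nodes: np.ndarray):
    """Per-person, per-node conditional log-likelihoods (J x K)."""
    obs = ~np.isnan(values)
    y = np.where(obs, values, 0.0)
    logits = nodes[:, None] - b[None, :]           # K x I
    logp = -np.logaddexp(0.0, -logits)
    log1mp = -np.logaddexp(0.0, logits)
    return (y * obs) @ logp.T + ((1.0 - y) * obs) @ log1mp.T


def marginal_loglik(fit: RaschFit, matrix) -> float:
    """Gauss-Hermite approximation of the marginal log-likelihood.

    Missing cells contribute nothing; a unit with no observed responses
    contributes an empty product (log 1 = 0).
    """
    values, item_ids, _ = _coerce(matrix)
    if values.shape[1] != fit.n_items:
        raise ShapeError(
            f"matrix has {values.shape[1]} items but fit has {fit.n_items}")
    ll = _loglik_terms(values, fit.difficulties, fit.quadrature_nodes)
    return float(logsumexp(ll + np.log(fit.quadrature_weights)[None, :], axis=1).sum())


def fit_rasch_mml(
    matrix,
    n_quadrature: int = DEFAULT_QUADRATURE_NODES,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    score_abilities: bool = True,
) -> RaschFit:
    """Estimate item difficulties by marginal maximum likelihood (EM).

    Zero-variance items (endorsed by all or by none of the respondents
    observed on them) have difficulties at +-infinity and are dropped with
    a logged reason before fitting.  Non-convergence within ``max_iter``
    iterations is flagged on the fit, never silently ignored.
    """
    values, item_ids, unit_ids = _coerce(matrix)
    n_units, n_items = values.shape
    if n_units < 2:
        raise UnidentifiableModelError("need at least 2 units to fit")

    dropped: list[tuple[str, str]] = []
    keep: list[int] = []
    for i in range(n_items):
        col = values[:, i]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            dropped.append((item_ids[i], "all responses missing"))
        elif obs.min() == obs.max():
            dropped.append((item_ids[i], "zero variance"))
        else:
            keep.append(i)
    if len(keep) < 2:
        raise UnidentifiableModelError(
            "fewer than 2 items with response variance; model unidentifiable "
            f"(dropped: {dropped})"
        )
    if dropped:
        warnings.warn(f"dropped items before Rasch fit: {dropped}", stacklevel=2)
    values = values[:, keep]
    kept_ids = [item_ids[i] for i in keep]

    nodes, wts = gauss_hermite_prior(n_quadrature)
    logw = np.log(wts)
    obs = ~np.isnan(values)
    y = np.where(obs, values, 0.0)

    # starting values: logit of the observed per-item failure rate
    rates = np.nansum(values, axis=0) / obs.sum(axis=0)
    b = -np.log(rates / (1.0 - rates))

    loglik_path: list[float] = []
    converged = False
    max_delta = np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        ll_jk = _loglik_terms(values, b, nodes)
        joint = ll_jk + logw[None, :]
        marg = logsumexp(joint, axis=1)
        loglik_path.append(float(marg.sum()))
        post = np.exp(joint - marg[:, None])       # J x K posterior weights
        # expected per-node counts: trials and successes, K x I
        n_ki = post.T @ obs
        r_ki = post.T @ (y * obs)
        new_b = np.empty_like(b)
        for i in range(values.shape[1]):
            target = r_ki[:, i].sum()
            n_col = n_ki[:, i]

            def score(bi, n_col=n_col, target=target):
                return float(expit(nodes - bi) @ n_col - target)

            new_b[i] = brentq(score, -35.0, 35.0, xtol=1e-12)
        max_delta = float(np.max(np.abs(new_b - b)))
        b = new_b
        if max_delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"Rasch EM did not converge in {max_iter} iterations "
            f"(max |delta b| = {max_delta:.2e})", stacklevel=2)

    fit = RaschFit(
        item_ids=kept_ids,
        difficulties=b,
        quadrature_nodes=nodes,
        quadrature_weights=wts,
        log_likelihood=float("nan"),
        n_iter=n_iter,
        final_max_delta=max_delta,
        converged=converged,
        dropped_items=dropped,
        loglik_path=loglik_path,
        unit_ids=unit_ids,
    )
    fit.log_likelihood = marginal_loglik(fit, values)
    if score_abilities:
        fit.ability_estimates = eap_abilities(fit, values)
    return fit


def eap_abilities(fit: RaschFit, matrix) -> np.ndarray:
    """EAP (posterior-mean) ability per unit under the N(0,1) prior.

    Units with no observed responses get NaN: their posterior is the prior
    and no data-driven score is defined for them.
    """
    values, _, _ = _coerce(matrix)
    if values.shape[1] != fit.n_items:
        raise ShapeError(
            f"matrix has {values.shape[1]} items but fit has {fit.n_items}")
    ll = _loglik_terms(values, fit.difficulties, fit.quadrature_nodes)
    joint = ll + np.log(fit.quadrature_weights)[None, :]
    post = np.exp(joint - logsumexp(joint, axis=1)[:, None])
    theta = post @ fit.quadrature_nodes
    none_observed = np.isnan(values).all(axis=1)
    theta[none_observed] = np.nan
    return theta


def eap_theta(fit: RaschFit, responses) -> float:
    """EAP ability for a single unit's response vector (NaN = missing)."""
    responses = np.asarray(responses, dtype=float).reshape(1, -1)
    if np.isnan(responses).all():
        raise PhcqualError("all responses missing; EAP undefined for this unit")
    return float(eap_abilities(fit, responses)[0])


def map_score(fit: RaschFit, theta):
    """Map ability onto [0,1] via the test characteristic curve.

    The score is the expected proportion of the instrument's retained items
    endorsed at ability ``theta``: strictly increasing, with limits 0 and 1
    as theta -> -inf / +inf.  NaN abilities propagate to NaN scores.
    """
    if fit.n_items < 1:
        raise UnidentifiableModelError("fit retains no items")
    theta = np.asarray(theta, dtype=float)
    out = expit(theta[..., None] - fit.difficulties).mean(axis=-1)
    return float(out) if out.ndim == 0 else out
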
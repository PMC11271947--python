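"""Arithmetic-mean quality scores on the [0,1] scale.

A sub-domain score for a unit is the mean of that unit's non-missing
indicators in the sub-domain; a domain score is the equal-weight mean of
its constituent sub-domain scores.  Scores strictly above 0.7 are flagged
favourable.  The clinical-care domain deliberately receives no single
domain score: its sub-domains come from disparate data sources and are
reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import DOMAINS, SUBDOMAIN_DOMAIN
from .errors import PhcqualError
from .matrix import IndicatorMatrix

FAVOURABLE_THRESHOLD = 0.7

#: domains that are summarised into a single per-unit score
SUMMATIVE_DOMAINS = {
    "PHC system": ("accessibility", "comprehensiveness", "continuity", "coordination"),
    "user experience": ("shared decision-making", "family-centeredness",
                        "information sharing", "respect for patient preferences"),
}


def subdomain_score(matrix: IndicatorMatrix, sub_domain: str) -> np.ndarray:
    """Per-unit mean of the sub-domain's non-missing indicators.

    Units with every cell missing get NaN (undefined, never silently 0).
    """
    cols = matrix.columns_for(sub_domain)
    if not cols:
        raise KeyError(f"sub-domain {sub_domain!r} has no indicators in this matrix")
    sub = matrix.restrict(cols)
    observed = (~np.isnan(sub.values)).sum(axis=1)
    totals = np.nansum(sub.values, axis=1)
    return np.where(observed > 0, totals / np.maximum(observed, 1), np.nan)


def domain_score(subdomain_scores: pd.DataFrame, domain: str) -> np.ndarray:
    """Equal-weight mean of a domain's sub-domain scores, per unit.

    Undefined (NaN) whenever any constituent sub-domain score is undefined
    for the unit.
    """
    if domain not in SUMMATIVE_DOMAINS:
        raise KeyError(
            f"domain {domain!r} has no summative score "
            f"(summative domains: {sorted(SUMMATIVE_DOMAINS)})"
        )
    members = SUMMATIVE_DOMAINS[domain]
    absent = [m for m in members if m not in subdomain_scores.columns]
    if absent:
        raise KeyError(f"sub-domain scores missing for {absent}")
    return subdomain_scores[list(members)].mean(axis=1, skipna=False).to_numpy()


def domain_score_from_aggregates(values) -> float:
    """Equal-weight mean of sub-domain aggregate scores (scalar form)."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise KeyError("empty sub-domain score set")
    return float(values.mean())


def favourable(score: float) -> bool:
    """True iff the score is strictly above the 0.7 favourability threshold."""
    if not np.isfinite(score) or not (0.0 <= score <= 1.0):
        raise PhcqualError(f"score {score!r} outside [0, 1]")
    return score > FAVOURABLE_THRESHOLD


@dataclass
class QualityScoreTable:
    """Per-unit and aggregate (sub-)domain scores with favourability flags."""

    unit_ids: np.ndarray
    subdomain_scores: pd.DataFrame  # units x sub-domains, NaN = undefined
    domain_scores: pd.DataFrame     # units x summative domains
    aggregate_means: dict[str, float]
    favourable_flags: dict[str, bool]

    def to_frame(self) -> pd.DataFrame:
        out = pd.concat([self.subdomain_scores, self.domain_scores], axis=1)
        out.index = pd.Index(self.unit_ids, name="unit_id")
        return out


def score_table(matrix: IndicatorMatrix,
                sub_domains: list[str] | None = None) -> QualityScoreTable:
    """Mean-based scores for every requested sub-domain plus domain rollups.

    Domain scores are produced only for summative domains all of whose
    sub-domains are present in the matrix.
    """
    if sub_domains is None:
        sub_domains = [s for s in SUBDOMAIN_DOMAIN if matrix.columns_for(s)]
    subs = pd.DataFrame(
        {s: subdomain_score(matrix, s) for s in sub_domains},
        index=pd.Index(matrix.unit_ids, name="unit_id"),
    )
    doms = {}
    for domain, members in SUMMATIVE_DOMAINS.items():
        if all(m in subs.columns for m in members):
            doms[domain] = domain_score(subs, domain)
    domains = pd.DataFrame(doms, index=subs.index)
    aggregates: dict[str, float] = {}
    for col in subs.columns:
        aggregates[col] = float(np.nanmean(subs[col].to_numpy()))
    for domain in domains.columns:
        aggregates[domain] = domain_score_from_aggregates(
            [aggregates[m] for m in SUMMATIVE_DOMAINS[domain]])
    flags = {name: favourable(v) for name, v in aggregates.items()}
    return QualityScoreTable(
        unit_ids=matrix.unit_ids,
        subdomain_scores=subs,
        domain_scores=domains,
        aggregate_means=aggregates,
        favourable_flags=flags,
    )
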
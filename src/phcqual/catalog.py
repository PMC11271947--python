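"""Indicator catalogue: the domain -> sub-domain -> indicator tree, and the
binarization of raw records into an :class:`~phcqual.matrix.IndicatorMatrix`.

The quality framework has exactly three domains and thirteen sub-domains.
The bundled default catalogue is configuration, not code: it is a synthetic
stand-in for the study's (unavailable) questionnaires and chart checklists,
with 4-8 indicators per sub-domain named after each sub-domain's
definitional clauses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError
from .matrix import IndicatorMatrix

#: domain of each of the 13 sub-domains
SUBDOMAIN_DOMAIN: dict[str, str] = {
    "accessibility": "PHC system",
    "comprehensiveness": "PHC system",
    "continuity": "PHC system",
    "coordination": "PHC system",
    "assessment": "clinical care",
    "diagnosis": "clinical care",
    "treatment": "clinical care",
    "disease management": "clinical care",
    "provider competence": "clinical care",
    "shared decision-making": "user experience",
    "family-centeredness": "user experience",
    "information sharing": "user experience",
    "respect for patient preferences": "user experience",
}

DOMAINS = ("PHC system", "clinical care", "user experience")

#: sub-domains scored by the arithmetic mean of their indicators
MEAN_SCORED = (
    "accessibility", "comprehensiveness", "continuity", "coordination",
    "disease management",
    "shared decision-making", "family-centeredness", "information sharing",
    "respect for patient preferences",
)

#: sub-domains scored through the Rasch latent-trait model
RASCH_SCORED = ("assessment", "diagnosis", "treatment", "provider competence")

SOURCES = ("patient survey", "provider survey", "chart abstraction", "registry")

#: unit level each source's records live at
SOURCE_UNIT_LEVEL = {
    "patient survey": "patient",
    "provider survey": "provider",
    "chart abstraction": "chart",
    "registry": "patient",
}


@dataclass(frozen=True)
class BinarizationRule:
    """How a raw field becomes a 0/1 indicator.

    kind
        ``identity`` (raw value already 0/1), ``categories`` (1 iff the raw
        value is in ``categories``; values in ``missing_categories`` become
        missing rather than 0), or ``threshold`` (numeric comparison).
    """

    kind: str
    field: str | None = None
    categories: frozenset = frozenset()
    missing_categories: frozenset = frozenset()
    op: str = ">="
    value: float = 0.0

    def apply(self, raw: pd.Series) -> np.ndarray:
        """Binarize a raw column; returns floats with NaN for missing."""
        out = np.full(len(raw), np.nan)
        present = raw.notna().to_numpy()
        if self.kind == "identity":
            vals = pd.to_numeric(raw, errors="coerce").to_numpy(dtype=float)
            bad = present & ~np.isin(vals, (0.0, 1.0)) & ~np.isnan(vals)
            if bad.any():
                raise SchemaError(
                    f"identity rule on non-binary raw values: {raw[bad].unique()[:5]}"
                )
            out[present] = vals[present]
        elif self.kind == "categories":
            as_str = raw.astype("string")
            is_missing = as_str.isin(list(self.missing_categories)).to_numpy()
            out[present] = as_str[present].isin(list(self.categories)).to_numpy(dtype=float)
            out[is_missing] = np.nan
        elif self.kind == "threshold":
            vals = pd.to_numeric(raw, errors="coerce").to_numpy(dtype=float)
            present = present & ~np.isnan(vals)
            cmp = {
                ">=": np.greater_equal, ">": np.greater,
                "<=": np.less_equal, "<": np.less,
            }[self.op]
            out[present] = cmp(vals[present], self.value).astype(float)
        else:  # pragma: no cover - rejected at load time
            raise SchemaError(f"unknown rule kind {self.kind!r}")
        return out


@dataclass(frozen=True)
class CatalogEntry:
    indicator_id: str
    sub_domain: str
    source: str
    rule: BinarizationRule

    @property
    def domain(self) -> str:
        return SUBDOMAIN_DOMAIN[self.sub_domain]

    @property
    def raw_field(self) -> str:
        """Raw-record column this entry reads (defaults to the indicator id)."""
        return self.rule.field or self.indicator_id


@dataclass
class IndicatorCatalog:
    """Validated indicator catalogue."""

    entries: list[CatalogEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            if e.sub_domain not in SUBDOMAIN_DOMAIN:
                raise SchemaError(
                    f"indicator {e.indicator_id!r}: unknown sub-domain {e.sub_domain!r}"
                )
            if e.source not in SOURCES:
                raise SchemaError(
                    f"indicator {e.indicator_id!r}: unknown source {e.source!r}"
                )
            if e.indicator_id in seen:
                raise SchemaError(f"duplicate indicator id {e.indicator_id!r}")
            seen.add(e.indicator_id)

    @property
    def indicator_ids(self) -> list[str]:
        return [e.indicator_id for e in self.entries]

    @property
    def sub_domains(self) -> list[str]:
        """Sub-domains present, in canonical framework order."""
        present = {e.sub_domain for e in self.entries}
        return [s for s in SUBDOMAIN_DOMAIN if s in present]

    def entries_for(self, sub_domain: str | None = None,
                    source: str | None = None) -> list[CatalogEntry]:
        out = self.entries
        if sub_domain is not None:
            out = [e for e in out if e.sub_domain == sub_domain]
        if source is not None:
            out = [e for e in out if e.source == source]
        return out

    def mapping(self) -> dict[str, tuple[str, str]]:
        return {e.indicator_id: (e.sub_domain, e.domain) for e in self.entries}


def _parse_rule(doc: dict) -> BinarizationRule:
    kind = doc.get("kind")
    if kind not in ("identity", "categories", "threshold"):
        raise SchemaError(f"unknown binarization rule kind {kind!r}")
    return BinarizationRule(
        kind=kind,
        field=doc.get("field"),
        categories=frozenset(doc.get("categories", [])),
        missing_categories=frozenset(doc.get("missing_categories", [])),
        op=doc.get("op", ">="),
        value=float(doc.get("value", 0.0)),
    )


def load_catalog(document: str | Path | dict) -> IndicatorCatalog:
    """Load and validate a catalogue from a YAML/JSON file path or a dict.

    Raises :class:`~phcqual.errors.SchemaError` naming the offending entry
    on unknown sub-domains, unknown sources, duplicate ids or malformed
    rules.
    """
    if isinstance(document, (str, Path)):
        with open(document, "r", encoding="utf-8") as fh:
            document = yaml.safe_load(fh)
    if not isinstance(document, dict) or "indicators" not in document:
        raise SchemaError("catalogue document must contain an 'indicators' list")
    entries = []
    for item in document["indicators"]:
        try:
            entries.append(CatalogEntry(
                indicator_id=str(item["id"]),
                sub_domain=str(item["sub_domain"]),
                source=str(item["source"]),
                rule=_parse_rule(item.get("rule", {"kind": "identity"})),
            ))
        except KeyError as exc:
            raise SchemaError(f"catalogue entry {item!r} missing key {exc}") from None
    return IndicatorCatalog(entries)


def default_catalog() -> IndicatorCatalog:
    """The bundled default catalogue (13 sub-domains, 59 indicators)."""
    ref = resources.files("phcqual.data").joinpath("default_catalog.yaml")
    return load_catalog(yaml.safe_load(ref.read_text(encoding="utf-8")))


def binarize(
    records: pd.DataFrame,
    catalog: IndicatorCatalog,
    unit_level: str,
    id_column: str | None = None,
    sources: tuple[str, ...] | None = None,
) -> IndicatorMatrix:
    """Apply the catalogue's binarization rules to raw records.

    Only catalogue entries whose source maps to ``unit_level`` (or whose
    source is listed in ``sources``) are used.  A raw field absent from
    ``records`` raises; a missing raw value yields a masked cell, never a
    silent 0.  Every selected indicator appears as a column even if
    all-missing.
    """
    if id_column is None:
        id_column = f"{unit_level}_id"
    if id_column not in records.columns:
        raise SchemaError(f"records lack the id column {id_column!r}")
    if sources is None:
        selected = [e for e in catalog.entries
                    if SOURCE_UNIT_LEVEL[e.source] == unit_level]
    else:
        selected = [e for e in catalog.entries if e.source in sources]
    if not selected:
        raise SchemaError(f"catalogue has no indicators at unit level {unit_level!r}")
    cols = {}
    for e in selected:
        if e.raw_field not in records.columns:
            raise SchemaError(
                f"indicator {e.indicator_id!r} reads raw field {e.raw_field!r} "
                "which is absent from the records"
            )
        cols[e.indicator_id] = e.rule.apply(records[e.raw_field])
    frame = pd.DataFrame(cols, index=pd.Index(records[id_column], name="unit_id"))
    return IndicatorMatrix.from_frame(
        frame, mapping={e.indicator_id: (e.sub_domain, e.domain) for e in selected},
        unit_level=unit_level,
    )
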
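"""The units x binary-indicators container shared by every analysis stage."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError, ShapeError


@dataclass
class IndicatorMatrix:
    """Units x binary indicators with an explicit missingness mask.

    Parameters
    ----------
    unit_ids
        One identifier per row (patient, provider or chart id).
    values
        Float array of shape ``(n_units, n_indicators)`` holding 0/1 for
        observed cells; entries under the mask are ignored (stored as NaN).
    mask
        Boolean array, same shape; ``True`` flags a missing cell.
    columns
        Indicator ids, one per column.
    mapping
        ``indicator id -> (sub_domain, domain)``, covering every column.
    unit_level
        One of ``{"patient", "provider", "chart"}``.
    original_values
        Optional pre-masking values retained by the missingness injector so
        imputation recovery can be evaluated against the truth.
    """

    unit_ids: np.ndarray
    values: np.ndarray
    mask: np.ndarray
    columns: list[str]
    mapping: dict[str, tuple[str, str]]
    unit_level: str
    original_values: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.unit_ids = np.asarray(self.unit_ids)
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ShapeError("values and mask shapes differ")
        if self.values.shape != (len(self.unit_ids), len(self.columns)):
            raise ShapeError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.unit_ids)} units x {len(self.columns)} indicators"
            )
        missing_cols = [c for c in self.columns if c not in self.mapping]
        if missing_cols:
            raise SchemaError(f"mapping does not cover columns {missing_cols}")
        observed = self.values[~self.mask]
        if observed.size and not np.isin(observed, (0.0, 1.0)).all():
            raise SchemaError("observed indicator values must be 0 or 1")
        self.values = self.values.copy()
        self.values[self.mask] = np.nan

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def n_indicators(self) -> int:
        return len(self.columns)

    def sub_domain_of(self, indicator_id: str) -> str:
        return self.mapping[indicator_id][0]

    def columns_for(self, sub_domain: str) -> list[str]:
        return [c for c in self.columns if self.mapping[c][0] == sub_domain]

    def restrict(self, columns: list[str]) -> "IndicatorMatrix":
        """New matrix holding only the given columns (order preserved)."""
        unknown = [c for c in columns if c not in self.columns]
        if unknown:
            raise KeyError(f"unknown indicator columns {unknown}")
        idx = [self.columns.index(c) for c in columns]
        orig = None if self.original_values is None else self.original_values[:, idx]
        return IndicatorMatrix(
            unit_ids=self.unit_ids,
            values=self.values[:, idx],
            mask=self.mask[:, idx],
            columns=list(columns),
            mapping={c: self.mapping[c] for c in columns},
            unit_level=self.unit_level,
            original_values=orig,
        )

    def instrument(self, sub_domain: str) -> "IndicatorMatrix":
        """Restrict to the columns of one sub-domain (one instrument)."""
        cols = self.columns_for(sub_domain)
        if not cols:
            raise KeyError(f"no indicators mapped to sub-domain {sub_domain!r}")
        return self.restrict(cols)

    def to_frame(self) -> pd.DataFrame:
        """DataFrame with the unit id as index; missing cells are NaN."""
        return pd.DataFrame(self.values, index=pd.Index(self.unit_ids, name="unit_id"),
                            columns=self.columns)

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        mapping: dict[str, tuple[str, str]],
        unit_level: str,
    ) -> "IndicatorMatrix":
        """Build from a DataFrame whose NaNs denote missing cells."""
        values = frame.to_numpy(dtype=float)
        mask = np.isnan(values)
        return cls(
            unit_ids=frame.index.to_numpy(),
            values=values,
            mask=mask,
            columns=list(frame.columns),
            mapping=mapping,
            unit_level=unit_level,
        )

    def save(self, path, mapping_path=None) -> None:
        """Write as a delimited table plus a JSON sidecar mapping file."""
        import json
        from pathlib import Path

        path = Path(path)
        if mapping_path is None:
            mapping_path = path.with_suffix(".mapping.json")
        self.to_frame().to_csv(path, na_rep="")
        doc = {"unit_level": self.unit_level,
               "mapping": {c: list(self.mapping[c]) for c in self.columns}}
        Path(mapping_path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n",
                                      encoding="utf-8")

    @classmethod
    def load(cls, path, mapping_path=None) -> "IndicatorMatrix":
        """Read a matrix written by :meth:`save` (lossless round trip)."""
        import json
        from pathlib import Path

        path = Path(path)
        if mapping_path is None:
            mapping_path = path.with_suffix(".mapping.json")
        doc = json.loads(Path(mapping_path).read_text(encoding="utf-8"))
        frame = pd.read_csv(path, index_col=0)
        return cls.from_frame(frame,
                              mapping={c: tuple(v) for c, v in doc["mapping"].items()},
                              unit_level=doc["unit_level"])

    def with_values(self, values: np.ndarray) -> "IndicatorMatrix":
        """Copy with new (complete) values; observed cells must be unchanged."""
        values = np.asarray(values, dtype=float)
        if values.shape != self.values.shape:
            raise ShapeError("replacement values have the wrong shape")
        return IndicatorMatrix(
            unit_ids=self.unit_ids,
            values=values,
            mask=np.zeros_like(self.mask),
            columns=list(self.columns),
            mapping=dict(self.mapping),
            unit_level=self.unit_level,
        )
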
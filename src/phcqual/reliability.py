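"""Internal-consistency reliability (Cronbach's alpha) of summative scales."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ReliabilityError
from .matrix import IndicatorMatrix


@dataclass(frozen=True)
class ReliabilityResult:
    domain: str
    alpha: float
    k_items: int
    n_units: int  # complete cases used


def cronbach_alpha(matrix, domain: str = "") -> ReliabilityResult:
    """Cronbach's alpha of the given item set.

    alpha = k/(k-1) * (1 - sum var(item_i) / var(total)), with sample
    variances (denominator n-1) computed on listwise-complete units.
    Accepts an :class:`IndicatorMatrix` (restricted to one scale), a
    DataFrame or an array; NaN marks missing.
    """
    if isinstance(matrix, IndicatorMatrix):
        values = matrix.values
    elif isinstance(matrix, pd.DataFrame):
        values = matrix.to_numpy(dtype=float)
    else:
        values = np.asarray(matrix, dtype=float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise ReliabilityError("Cronbach's alpha requires at least 2 items")
    complete = values[~np.isnan(values).any(axis=1)]
    n, k = complete.shape
    if n < 2:
        raise ReliabilityError(
            f"only {n} listwise-complete units; alpha undefined")
    item_var = complete.var(axis=0, ddof=1)
    total_var = complete.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ReliabilityError("zero total-score variance; alpha undefined")
    alpha = k / (k - 1) * (1.0 - item_var.sum() / total_var)
    return ReliabilityResult(domain=domain, alpha=float(alpha),
                             k_items=int(k), n_units=int(n))
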
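"""Multiple imputation of item nonresponse and Rubin pooling.

Twenty percent of survey cells are masked completely at random, refilled by
chained logistic imputations (m completed datasets), and the per-indicator
means are pooled across imputations.
"""

import numpy as np

from phcqual import (IndicatorMatrix, SyntheticConfig, inject_missingness,
                     mice_impute, pool_estimates)

rng = np.random.default_rng(3)
p_true = np.array([0.8, 0.6, 0.5, 0.7])
values = (rng.random((400, 4)) < p_true).astype(float)
cols = [f"item_{j}" for j in range(4)]
matrix = IndicatorMatrix(
    unit_ids=np.arange(400), values=values,
    mask=np.zeros_like(values, dtype=bool), columns=cols,
    mapping={c: ("continuity", "PHC system") for c in cols},
    unit_level="patient")

config = SyntheticConfig(n_patients=400, missing_rate=0.2, seed=3)
masked = inject_missingness(matrix, config)
print(f"masked fraction: {masked.mask.mean():.3f}")

imputed = mice_impute(masked, m=10, cycles=10, seed=3)
truth = masked.original_values.mean(axis=0)
pooled = imputed.pooled_column_means()
print("item     truth   pooled mean")
for c, t, q in zip(cols, truth, pooled):
    print(f"{c}   {t:.3f}   {q:.3f}")

example = pool_estimates([0.5, 0.7], [0.01, 0.01])
print(f"\nRubin pooling of (0.5, 0.7) with variances (0.01, 0.01): "
      f"Q-bar={example.estimate:.2f}, T={example.total_var:.2f}")
print("Pooled means sit close to the pre-masking truth: imputation adds no")
print("systematic bias, and total variance reflects between-imputation spread.")
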
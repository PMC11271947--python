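"""Synthetic generator for the four linked study tables.

Emulates the statistical structure the analysis assumes: covariates drawn
from the study's marginal distributions, binary quality indicators drawn
Bernoulli per sub-domain endorsement probability, vignette/checklist items
drawn from the Rasch model with person abilities ``theta ~ N(0,1)`` shifted
by covariate effects, a three-level county/town/village cluster structure,
a Poisson-process follow-up registry, and MCAR/MAR item nonresponse.

Seed-splitting scheme: the single integer seed feeds a
``numpy.random.SeedSequence`` whose children, in the fixed order
``patients, providers, charts, registry, missingness``, seed one generator
per table, so every table is reproducible independently of the others.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .catalog import IndicatorCatalog, MEAN_SCORED, default_catalog
from .config import MAR, MCAR, SyntheticConfig
from .errors import ConfigError, ShapeError
from .matrix import IndicatorMatrix
from . import studydata

_STREAMS = ("patients", "providers", "charts", "registry", "missingness")


def rng_streams(seed: int) -> dict[str, np.random.Generator]:
    """One independent generator per table, all derived from one seed."""
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}


def _cluster_labels(config: SyntheticConfig):
    c = config.cluster_sizes
    counties = [f"county_{i+1}" for i in range(c.get("counties", 3))]
    towns, villages = [], []
    for county in counties:
        for j in range(c.get("towns_per_county", 3)):
            town = f"{county}_town_{j+1}"
            towns.append((county, town))
            for k in range(c.get("villages_per_town", 5)):
                villages.append((county, town, f"{town}_village_{k+1}"))
    return counties, towns, villages


def _draw_categorical(rng: np.random.Generator, dist: dict[str, float], n: int) -> np.ndarray:
    levels = list(dist)
    p = np.asarray([dist[l] for l in levels], dtype=float)
    return rng.choice(levels, size=n, p=p / p.sum())


def _indicator_prob(config: SyntheticConfig, indicator_id: str, sub_domain: str) -> float:
    probs = config.indicator_probs
    if indicator_id in probs:
        return float(probs[indicator_id])
    if sub_domain in probs:
        return float(probs[sub_domain])
    raise ConfigError(
        f"no endorsement probability for indicator {indicator_id!r} "
        f"(sub-domain {sub_domain!r})"
    )


def generate_rasch_responses(
    difficulties: np.ndarray,
    abilities: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``Y_ij ~ Bernoulli(sigma(theta_j - b_i))``, persons x items."""
    b = np.asarray(difficulties, dtype=float)
    theta = np.asarray(abilities, dtype=float)
    if b.ndim != 1 or theta.ndim != 1:
        raise ShapeError("difficulties and abilities must be 1-D vectors")
    if not np.isfinite(b).all():
        raise ConfigError("item difficulties must be finite")
    if not np.isfinite(theta).all():
        raise ConfigError("abilities must be finite")
    logits = theta[:, None] - b[None, :]
    p = 1.0 / (1.0 + np.exp(-logits))
    return (rng.random(p.shape) < p).astype(int)


def _ability_shift(effect_map: dict, frame: pd.DataFrame) -> np.ndarray:
    shift = np.zeros(len(frame))
    for covariate, effects in effect_map.items():
        if covariate not in frame.columns:
            continue
        col = frame[covariate].astype(str)
        for level, delta in effects.items():
            shift += np.where(col == level, float(delta), 0.0)
    return shift


def generate_patients(
    config: SyntheticConfig,
    catalog: IndicatorCatalog | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Patient survey table: covariates, cluster labels, binary survey items."""
    catalog = catalog or default_catalog()
    rng = rng or rng_streams(config.seed)["patients"]
    n = config.n_patients
    _, _, villages = _cluster_labels(config)
    vidx = rng.integers(0, len(villages), size=n)
    table = {
        "patient_id": [f"P{i+1:05d}" for i in range(n)],
        "county": [villages[i][0] for i in vidx],
        "town": [villages[i][1] for i in vidx],
        "village": [villages[i][2] for i in vidx],
    }
    for cov, dist in config.covariate_marginals.items():
        if cov == "county":
            continue  # county implied by the sampled village
        table[cov] = _draw_categorical(rng, dist, n)
    frame = pd.DataFrame(table)
    for entry in catalog.entries_for(source="patient survey"):
        if entry.sub_domain not in MEAN_SCORED:
            continue
        p = _indicator_prob(config, entry.indicator_id, entry.sub_domain)
        frame[entry.raw_field] = (rng.random(n) < p).astype(int)
    return frame


def generate_providers(
    config: SyntheticConfig,
    catalog: IndicatorCatalog | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Provider survey table: covariates plus Rasch-generated vignette items.

    Provider ability is ``theta ~ N(0,1)`` plus the configured covariate
    shifts (workplace, permanent post by default); education is drawn
    conditionally on workplace, mirroring the study's strong confounding
    between the two.
    """
    catalog = catalog or default_catalog()
    rng = rng or rng_streams(config.seed)["providers"]
    n = config.n_providers
    counties, towns, _ = _cluster_labels(config)
    tidx = rng.integers(0, len(towns), size=n)
    frame = pd.DataFrame({
        "provider_id": [f"D{i+1:04d}" for i in range(n)],
        "county": [towns[i][0] for i in tidx],
        "town": [towns[i][1] for i in tidx],
    })
    for cov, dist in config.provider_marginals.items():
        frame[cov] = _draw_categorical(rng, dist, n)
    # education conditional on workplace
    low_p = frame["facility_level"].map(studydata.PROVIDER_EDU_LOW_BY_FACILITY).to_numpy()
    frame["education"] = np.where(rng.random(n) < low_p,
                                  "high_school_or_below", "college_or_above")
    entries = catalog.entries_for(sub_domain="provider competence")
    b = np.asarray(config.item_difficulties["provider competence"], dtype=float)
    if len(b) != len(entries):
        raise ConfigError(
            f"provider-competence instrument has {len(entries)} items but "
            f"{len(b)} difficulties are configured"
        )
    theta = rng.standard_normal(n) + _ability_shift(config.covariate_effects, frame)
    responses = generate_rasch_responses(b, theta, rng)
    for j, entry in enumerate(entries):
        frame[entry.raw_field] = responses[:, j]
    return frame


def generate_charts(
    config: SyntheticConfig,
    catalog: IndicatorCatalog | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Chart-abstraction table: checklist items drawn from the Rasch model.

    Charts come only from township health centres and county hospitals
    (village clinics provide no inpatient services).
    """
    catalog = catalog or default_catalog()
    rng = rng or rng_streams(config.seed)["charts"]
    n = config.n_charts
    counties, towns, _ = _cluster_labels(config)
    tidx = rng.integers(0, len(towns), size=n)
    frame = pd.DataFrame({
        "chart_id": [f"C{i+1:05d}" for i in range(n)],
        "county": [towns[i][0] for i in tidx],
        "town": [towns[i][1] for i in tidx],
    })
    for cov, dist in config.chart_marginals.items():
        frame[cov] = _draw_categorical(rng, dist, n)
    if (frame["facility_level"] == "village clinic").any():
        raise ConfigError("chart_marginals must not place charts at village clinics")
    theta = rng.standard_normal(n) + _ability_shift(config.chart_covariate_effects, frame)
    for sub_domain in ("assessment", "diagnosis", "treatment"):
        entries = catalog.entries_for(sub_domain=sub_domain)
        b = np.asarray(config.item_difficulties[sub_domain], dtype=float)
        if len(b) != len(entries):
            raise ConfigError(
                f"{sub_domain} instrument has {len(entries)} items but "
                f"{len(b)} difficulties are configured"
            )
        responses = generate_rasch_responses(b, theta, rng)
        for j, entry in enumerate(entries):
            frame[entry.raw_field] = responses[:, j]
    return frame


def generate_registry(
    config: SyntheticConfig,
    patients: pd.DataFrame,
    rng: np.random.Generator | None = None,
    year: int = 2022,
) -> pd.DataFrame:
    """Follow-up registry: one row per visit with date and measurement.

    Visit counts are Poisson(``registry_visit_rate``) per patient-year;
    dates are strictly increasing within a patient.  Blood pressure is
    recorded for hypertensive (and comorbid) patients, glycated
    haemoglobin for the rest.
    """
    rng = rng or rng_streams(config.seed)["registry"]
    days = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    rows = []
    counts = rng.poisson(config.registry_visit_rate, size=len(patients))
    for (pid, disease), k in zip(
            patients[["patient_id", "disease_group"]].itertuples(index=False), counts):
        if k == 0:
            continue
        k = min(int(k), len(days))
        visit_days = np.sort(rng.choice(len(days), size=k, replace=False))
        if disease == "diabetes":
            kind, values = "hba1c", rng.normal(7.5, 1.2, size=k).round(1)
        else:
            kind, values = "systolic_bp", rng.normal(142.0, 15.0, size=k).round(0)
        for d, v in zip(visit_days, values):
            rows.append((pid, days[d].date().isoformat(), kind, float(v)))
    return pd.DataFrame(rows, columns=["patient_id", "visit_date",
                                       "measurement_type", "value"])


def registry_followups_per_year(registry: pd.DataFrame,
                                patients: pd.DataFrame) -> pd.DataFrame:
    """Visits per patient over the registry's observation year.

    Patients absent from the registry count zero visits (they were
    registered but never followed up), so the derived adequacy indicator is
    defined for every patient.
    """
    counts = registry.groupby("patient_id").size() if len(registry) else pd.Series(dtype=int)
    out = patients[["patient_id"]].copy()
    out["followups_per_year"] = out["patient_id"].map(counts).fillna(0).astype(int)
    return out


def generate_tables(
    config: SyntheticConfig,
    catalog: IndicatorCatalog | None = None,
) -> dict[str, pd.DataFrame]:
    """All four linked tables from one seed (the headline entry point)."""
    catalog = catalog or default_catalog()
    streams = rng_streams(config.seed)
    patients = generate_patients(config, catalog, streams["patients"])
    providers = generate_providers(config, catalog, streams["providers"])
    charts = generate_charts(config, catalog, streams["charts"])
    registry = generate_registry(config, patients, streams["registry"])
    return {"patients": patients, "providers": providers,
            "charts": charts, "registry": registry}


def inject_missingness(
    matrix: IndicatorMatrix,
    config: SyntheticConfig,
    covariate_values: pd.Series | np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> IndicatorMatrix:
    """Mask observed cells per the configured nonresponse mechanism.

    MCAR masks every observed cell independently at ``missing_rate``.  MAR
    masks at a rate depending only on the supplied fully observed covariate
    (per-level rates from ``config.mar_rates``, or ``missing_rate`` scaled
    0.5x/1.5x across levels when unspecified).  The pre-masking values are
    retained on the result (``original_values``) for recovery testing.
    """
    if config.missing_rate >= 1.0:
        raise ConfigError("missing_rate must be < 1")
    rng = rng or rng_streams(config.seed)["missingness"]
    if config.missing_mechanism == MCAR:
        cell_rate = np.full(matrix.values.shape, config.missing_rate)
    elif config.missing_mechanism == MAR:
        if covariate_values is None:
            raise ConfigError("MAR missingness requires the conditioning covariate values")
        cov = pd.Series(np.asarray(covariate_values)).astype(str)
        if len(cov) != matrix.n_units:
            raise ShapeError("covariate values do not match the number of units")
        if cov.isin(["nan", "None", ""]).any():
            raise ConfigError("MAR conditioning covariate must be fully observed")
        rates = config.mar_rates
        if rates is None:
            levels = sorted(cov.unique())
            scale = np.linspace(0.5, 1.5, len(levels))
            rates = {l: min(config.missing_rate * s, 0.99) for l, s in zip(levels, scale)}
        unknown = set(cov.unique()) - set(rates)
        if unknown:
            raise ConfigError(f"no MAR rate configured for levels {sorted(unknown)}")
        unit_rate = cov.map(rates).to_numpy(dtype=float)
        cell_rate = np.broadcast_to(unit_rate[:, None], matrix.values.shape)
    else:  # pragma: no cover - rejected by config validation
        raise ConfigError(f"unknown mechanism {config.missing_mechanism!r}")
    new_mask = matrix.mask | ((rng.random(matrix.values.shape) < cell_rate) & ~matrix.mask)
    return IndicatorMatrix(
        unit_ids=matrix.unit_ids,
        values=np.where(new_mask, np.nan, matrix.values),
        mask=new_mask,
        columns=list(matrix.columns),
        mapping=dict(matrix.mapping),
        unit_level=matrix.unit_level,
        original_values=matrix.values.copy(),
    )
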
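"""One-call orchestration: generate/load -> binarize -> impute -> score
(means + Rasch) -> reliability -> subgroups -> regression -> report bundle.

Every table is written as UTF-8 comma-delimited text with a header row and
empty fields for missing cells; the manifest records the configuration,
its hash and the seed, so identical config+seed reproduces the bundle
byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .catalog import (IndicatorCatalog, MEAN_SCORED, RASCH_SCORED,
                      default_catalog, load_catalog, binarize)
from .config import SyntheticConfig
from .errors import ConfigError, PipelineError, ReliabilityError
from .impute import mice_impute, pool_estimates
from .inference import MODEL_TERMS, fit_provider_regression, subgroup_means
from .matrix import IndicatorMatrix
from .rasch import eap_abilities, fit_rasch_mml, map_score
from .reliability import cronbach_alpha
from .scoring import (SUMMATIVE_DOMAINS, domain_score,
                      domain_score_from_aggregates, favourable, score_table)
from .synthetic import generate_tables, inject_missingness, registry_followups_per_year

DEFAULT_SUBGROUP_COVARIATES = (
    "gender", "age_band", "marriage", "education", "income_quintile",
    "insurance", "disease_group",
)


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    Exactly one of ``input_paths`` (the four table files) and ``synthetic``
    must be supplied; a seed is required whenever a stochastic stage
    (generation, missingness, imputation) is active.
    """

    synthetic: SyntheticConfig | None = None
    input_paths: dict[str, str] | None = None
    catalog_path: str | None = None
    impute: bool = True
    m: int = 10
    cycles: int = 10
    quadrature_nodes: int = 21
    subgroup_covariates: tuple[str, ...] = DEFAULT_SUBGROUP_COVARIATES
    adjust_response_rates: bool = False
    seed: int | None = None
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.input_paths is None):
            raise ConfigError(
                "exactly one of input_paths and synthetic must be supplied")
        if self.input_paths is not None:
            required = {"patients", "providers", "charts", "registry"}
            missing = required - set(self.input_paths)
            if missing:
                raise ConfigError(f"input_paths missing tables {sorted(missing)}")
        if (self.synthetic is not None or self.impute) and self.seed is None:
            raise ConfigError("a seed is required when a stochastic stage is active")
        if self.m < 1 or self.cycles < 1 or self.quadrature_nodes < 2:
            raise ConfigError("m, cycles and quadrature_nodes must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        import yaml
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        doc.update(overrides)
        if "synthetic" in doc and isinstance(doc["synthetic"], dict):
            doc["synthetic"] = SyntheticConfig.from_dict(doc["synthetic"])
        if "subgroup_covariates" in doc:
            doc["subgroup_covariates"] = tuple(doc["subgroup_covariates"])
        known = set(cls.__dataclass_fields__)
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown PipelineConfig keys {sorted(unknown)}")
        return cls(**doc)

    def to_dict(self) -> dict:
        return {
            "synthetic": None if self.synthetic is None else self.synthetic.to_dict(),
            "input_paths": self.input_paths,
            "catalog_path": self.catalog_path,
            "impute": self.impute,
            "m": self.m,
            "cycles": self.cycles,
            "quadrature_nodes": self.quadrature_nodes,
            "subgroup_covariates": list(self.subgroup_covariates),
            "adjust_response_rates": self.adjust_response_rates,
            "seed": self.seed,
        }


@dataclass
class PipelineResult:
    """In-memory bundle of everything the pipeline computed."""

    tables: dict[str, pd.DataFrame]
    patient_matrix: IndicatorMatrix
    provider_matrix: IndicatorMatrix
    chart_matrix: IndicatorMatrix
    patient_scores: object
    subdomain_aggregates: dict[str, float]
    domain_aggregates: dict[str, float]
    favourable_flags: dict[str, bool]
    rasch_fits: dict[str, object]
    rasch_scores: dict[str, np.ndarray]
    reliability: dict[str, dict]
    subgroups: pd.DataFrame
    regressions: dict[str, object]
    imputation_diagnostics: dict
    manifest: dict
    written: list[str] = field(default_factory=list)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def _load_tables(paths: dict[str, str]) -> dict[str, pd.DataFrame]:
    return {name: pd.read_csv(p) for name, p in paths.items()}


def run_pipeline(config: PipelineConfig,
                 catalog: IndicatorCatalog | None = None) -> PipelineResult:
    """Execute the full analysis and (optionally) write the report bundle."""
    if catalog is None:
        catalog = (load_catalog(config.catalog_path)
                   if config.catalog_path else default_catalog())

    # -- acquire tables ------------------------------------------------------
    if config.synthetic is not None:
        tables = _stage("generate")(generate_tables)(config.synthetic, catalog)
    else:
        tables = _stage("load")(_load_tables)(config.input_paths)
    patients, providers = tables["patients"], tables["providers"]
    charts, registry = tables["charts"], tables["registry"]

    # -- binarize ------------------------------------------------------------
    @_stage("binarize")
    def _binarize():
        pat_raw = patients.merge(
            registry_followups_per_year(registry, patients), on="patient_id")
        pat = binarize(pat_raw, catalog, "patient")
        prov = binarize(providers, catalog, "provider")
        cha = binarize(charts, catalog, "chart")
        return pat, prov, cha
    patient_matrix, provider_matrix, chart_matrix = _binarize()

    # -- missingness (synthetic mode only adds nonresponse) -------------------
    if config.synthetic is not None and config.synthetic.missing_rate > 0:
        cov = None
        if config.synthetic.missing_mechanism == "MAR":
            cov = patients[config.synthetic.mar_covariate]
        patient_matrix = _stage("missingness")(inject_missingness)(
            patient_matrix, config.synthetic, covariate_values=cov)

    # -- reliability (pre-imputation, listwise) -------------------------------
    reliability: dict[str, dict] = {}
    scales = {
        "PHC system": patient_matrix.restrict(
            [c for c in patient_matrix.columns
             if patient_matrix.mapping[c][1] == "PHC system"]),
        "user experience": patient_matrix.restrict(
            [c for c in patient_matrix.columns
             if patient_matrix.mapping[c][1] == "user experience"]),
        "provider competence": provider_matrix.instrument("provider competence"),
    }
    for name, scale in scales.items():
        try:
            r = cronbach_alpha(scale, domain=name)
            reliability[name] = {"alpha": r.alpha, "k_items": r.k_items,
                                 "n_complete": r.n_units}
        except ReliabilityError as exc:
            reliability[name] = {"error": str(exc)}

    # -- imputation -----------------------------------------------------------
    imputation_diagnostics: dict = {"enabled": bool(config.impute)}
    mean_subdomains = [s for s in MEAN_SCORED if patient_matrix.columns_for(s)]
    if config.impute:
        covs = patients[[c for c in config.subgroup_covariates
                         if c in patients.columns]]
        imp = _stage("impute")(mice_impute)(
            patient_matrix, covariates=covs, m=config.m,
            cycles=config.cycles, seed=config.seed)
        per_imp_tables = [score_table(c, mean_subdomains) for c in imp.completed]
        # per-unit scores: across-imputation average; aggregates: Rubin Q-bar
        subs = sum(t.subdomain_scores for t in per_imp_tables) / imp.m
        n = patient_matrix.n_units
        pooled = {}
        for s in mean_subdomains:
            ests = [float(np.nanmean(t.subdomain_scores[s])) for t in per_imp_tables]
            variances = [float(np.nanvar(t.subdomain_scores[s], ddof=1) / n)
                         for t in per_imp_tables]
            pooled[s] = pool_estimates(ests, variances)
        imputation_diagnostics.update({
            "m": imp.m, "cycles": config.cycles,
            "column_missing_rates": {
                c: float(patient_matrix.mask[:, j].mean())
                for j, c in enumerate(patient_matrix.columns)
                if patient_matrix.mask[:, j].any()},
            "model_families": imp.models,
        })
        subdomain_aggregates = {s: p.estimate for s, p in pooled.items()}
    else:
        t = score_table(patient_matrix, mean_subdomains)
        subs = t.subdomain_scores
        subdomain_aggregates = {s: t.aggregate_means[s] for s in mean_subdomains}

    patient_scores = score_table(patient_matrix, mean_subdomains)
    patient_scores.subdomain_scores = subs  # headline (post-imputation) scores
    patient_scores.domain_scores = pd.DataFrame(
        {d: domain_score(subs, d) for d, members in SUMMATIVE_DOMAINS.items()
         if all(m in subs.columns for m in members)},
        index=subs.index)

    # -- Rasch scoring --------------------------------------------------------
    rasch_fits: dict[str, object] = {}
    rasch_scores: dict[str, np.ndarray] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for sub in ("assessment", "diagnosis", "treatment"):
            inst = chart_matrix.instrument(sub)
            fit = _stage(f"rasch:{sub}")(fit_rasch_mml)(
                inst, n_quadrature=config.quadrature_nodes)
            rasch_fits[sub] = fit
            rasch_scores[sub] = map_score(fit, fit.ability_estimates)
            subdomain_aggregates[sub] = float(np.nanmean(rasch_scores[sub]))
        inst = provider_matrix.instrument("provider competence")
        fit = _stage("rasch:provider competence")(fit_rasch_mml)(
            inst, n_quadrature=config.quadrature_nodes)
        rasch_fits["provider competence"] = fit
        rasch_scores["provider competence"] = map_score(fit, fit.ability_estimates)
        subdomain_aggregates["provider competence"] = float(
            np.nanmean(rasch_scores["provider competence"]))

    # -- domain rollups -------------------------------------------------------
    domain_aggregates = {
        d: domain_score_from_aggregates([subdomain_aggregates[m] for m in members])
        for d, members in SUMMATIVE_DOMAINS.items()
    }
    favourable_flags = {k: favourable(v) for k, v in
                        {**subdomain_aggregates, **domain_aggregates}.items()}

    # -- subgroup summaries ---------------------------------------------------
    rows = []
    dims = [c for c in config.subgroup_covariates if c in patients.columns]
    score_cols = dict(subs.items())
    for domain, members in SUMMATIVE_DOMAINS.items():
        if all(m in subs.columns for m in members):
            score_cols[domain] = subs[list(members)].mean(axis=1, skipna=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for score_name, values in score_cols.items():
            for dim in dims:
                for s in subgroup_means(np.asarray(values, dtype=float),
                                        patients[dim], patients["town"],
                                        dimension=dim):
                    rows.append({
                        "score": score_name, "dimension": s.dimension,
                        "level": s.level, "n": s.n, "mean": s.mean, "se": s.se,
                        "ci_low": s.ci_low, "ci_high": s.ci_high,
                        "n_clusters": s.n_clusters, "p_vs_ref": s.p_vs_ref,
                    })
    subgroups = pd.DataFrame(rows)

    # -- provider regression --------------------------------------------------
    competence = rasch_scores["provider competence"]
    weights = None
    if config.adjust_response_rates:
        from .studydata import PROVIDERS_RECRUITED, PROVIDERS_RESPONDED
        weights = {lvl: PROVIDERS_RESPONDED[lvl] / PROVIDERS_RECRUITED.get(lvl, PROVIDERS_RESPONDED[lvl])
                   for lvl in PROVIDERS_RESPONDED}
    regressions = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for model_id in MODEL_TERMS:
            regressions[model_id] = _stage(f"regress:{model_id}")(
                fit_provider_regression)(
                providers, competence, model_id=model_id,
                response_rate_weights=weights)

    # -- manifest -------------------------------------------------------------
    config_doc = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "phcqual_version": __version__,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(config_doc.encode()).hexdigest(),
        "seed": config.seed,
        "n_units": {"patients": len(patients), "providers": len(providers),
                    "charts": len(charts), "registry_visits": len(registry)},
    }

    result = PipelineResult(
        tables=tables,
        patient_matrix=patient_matrix,
        provider_matrix=provider_matrix,
        chart_matrix=chart_matrix,
        patient_scores=patient_scores,
        subdomain_aggregates=subdomain_aggregates,
        domain_aggregates=domain_aggregates,
        favourable_flags=favourable_flags,
        rasch_fits=rasch_fits,
        rasch_scores=rasch_scores,
        reliability=reliability,
        subgroups=subgroups,
        regressions=regressions,
        imputation_diagnostics=imputation_diagnostics,
        manifest=manifest,
    )
    if config.out_dir is not None:
        write_bundle(result, config.out_dir)
    return result


def write_bundle(result: PipelineResult, out_dir: str | Path) -> list[str]:
    """Write the report bundle (CSV tables + JSON report + manifest)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def _csv(name: str, frame: pd.DataFrame, index: bool = False) -> None:
        path = out / name
        frame.to_csv(path, index=index, na_rep="")
        written.append(str(path))

    for name, table in result.tables.items():
        _csv(f"{name}.csv", table)
    _csv("patient_scores.csv", result.patient_scores.to_frame(), index=True)
    _csv("subgroups.csv", result.subgroups)
    _csv("regression.csv",
         pd.concat([r.to_frame() for r in result.regressions.values()]),
         index=True)

    report = {
        "subdomain_scores": {k: round(v, 6) for k, v in
                             sorted(result.subdomain_aggregates.items())},
        "domain_scores": {k: round(v, 6) for k, v in
                          sorted(result.domain_aggregates.items())},
        "favourable": dict(sorted(result.favourable_flags.items())),
        "reliability": result.reliability,
        "imputation": result.imputation_diagnostics,
        "rasch_fits": {k: f.to_dict() for k, f in result.rasch_fits.items()},
    }
    for name, doc in (("report.json", report), ("manifest.json", result.manifest)):
        path = out / name
        path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n",
                        encoding="utf-8")
        written.append(str(path))
    result.written = written
    return written
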
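"""Sample composition of the motivating rural-China PHC field study.

These are the published sample counts and marginal distributions from a
cross-sectional quality-of-care study of hypertension and type-2 diabetes
care in three low-resource counties (village clinic / township health
centre / county hospital system).  They serve two purposes:

* calibration of the synthetic-data generator defaults, so that simulated
  tables have the covariate structure the analysis assumes;
* simple sample-accounting arithmetic (retention, shares, response rates)
  used in reports.
"""

from __future__ import annotations

# -- patient questionnaire survey -------------------------------------------
PATIENT_QUESTIONNAIRES_FIELDED = 1357
PATIENT_QUESTIONNAIRES_EXCLUDED = 2  # excluded for missing quality items
N_PATIENTS = PATIENT_QUESTIONNAIRES_FIELDED - PATIENT_QUESTIONNAIRES_EXCLUDED

FEMALE_PATIENTS = 845
COMORBIDITY_PATIENTS = 276  # dual diagnosis of hypertension and diabetes

PATIENT_AGE_MEAN = 65.8
PATIENT_AGE_SD = 9.4

# -- provider questionnaire survey ------------------------------------------
N_PROVIDERS = 333
# recruited / responded per facility level; township recruitment was reported
# inconsistently at the source and is therefore not listed here
PROVIDERS_RECRUITED = {"county hospital": 50, "village clinic": 199}
PROVIDERS_RESPONDED = {
    "county hospital": 47,
    "township health centre": 107,
    "village clinic": 179,
}

PROVIDER_AGE_MEAN = 41.3
PROVIDER_AGE_SD = 10.5

# -- chart abstraction -------------------------------------------------------
N_CHARTS = 2203

# -- marginal distributions used to calibrate the synthetic generator -------
PATIENT_MARGINALS = {
    "county": {"county_hubei": 420 / 1355, "county_henan": 466 / 1355, "county_shanxi": 469 / 1355},
    "gender": {"female": 845 / 1355, "male": 510 / 1355},
    # age bands <50 / 50-60 / 60-70 / >=70 implied by age ~ N(65.8, 9.4)
    "age_band": {"<50": 0.046, "50-60": 0.222, "60-70": 0.404, ">=70": 0.328},
    "disease_group": {"hypertension": 901 / 1355, "diabetes": 178 / 1355, "comorbidity": 276 / 1355},
    # the source reports no marriage/education/income/insurance breakdown;
    # values below are field-realistic choices for elderly rural China
    "marriage": {"married": 0.85, "unmarried": 0.15},
    "education": {"primary_or_less": 0.55, "middle_school": 0.30, "high_school_or_more": 0.15},
    "income_quintile": {"q1": 0.2, "q2": 0.2, "q3": 0.2, "q4": 0.2, "q5": 0.2},
    "insurance": {"UEBMI": 0.05, "URBMI": 0.03, "NCMS": 0.32, "URRBMI": 0.60},
}

PROVIDER_MARGINALS = {
    "facility_level": {
        "village clinic": 179 / 333,
        "township health centre": 107 / 333,
        "county hospital": 47 / 333,
    },
    "gender": {"female": 162 / 333, "male": 171 / 333},
    "permanent_post": {"yes": 0.5, "no": 0.5},
    "passed_licensing_exam": {"yes": 0.5, "no": 0.5},
    "job_title": {"yes": 0.4, "no": 0.6},
    "administrative_role": {"yes": 0.2, "no": 0.8},
    "job_satisfaction": {"satisfied": 0.7, "not satisfied": 0.3},
}

# education is largely determined by workplace: share with high-school-or-below
PROVIDER_EDU_LOW_BY_FACILITY = {
    "village clinic": 0.75,
    "township health centre": 0.08,
    "county hospital": 0.0,
}

CHART_MARGINALS = {
    "facility_level": {"township health centre": 487 / 2203, "county hospital": 1716 / 2203},
    "disease_group": {"hypertension": 850 / 2203, "diabetes": 792 / 2203, "comorbidity": 561 / 2203},
}

# published per-sub-domain quality levels; used as default endorsement
# probabilities for the mean-scored sub-domains in the generator
SUBDOMAIN_LEVELS = {
    "accessibility": 0.781,
    "comprehensiveness": 0.887,
    "continuity": 0.489,
    "coordination": 0.714,
    "disease management": 0.777,
    "information sharing": 0.933,
    "shared decision-making": 0.657,
    "respect for patient preferences": 0.936,
    "family-centeredness": 0.382,
}


def retained(fielded: int, excluded: int) -> int:
    """Questionnaires retained after exclusion."""
    if excluded > fielded:
        raise ValueError("cannot exclude more questionnaires than fielded")
    return fielded - excluded


def share_pct(part: int, whole: int) -> float:
    """Percentage share of a subgroup, on the 0-100 scale."""
    if whole <= 0 or part < 0 or part > whole:
        raise ValueError(f"invalid share {part}/{whole}")
    return 100.0 * part / whole


def response_rate_pct(facility_level: str) -> float:
    """Provider response rate (%) for a facility level with known recruitment."""
    try:
        recruited = PROVIDERS_RECRUITED[facility_level]
    except KeyError:
        raise KeyError(f"recruitment count unavailable for {facility_level!r}") from None
    return share_pct(PROVIDERS_RESPONDED[facility_level], recruited)
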
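"""Synthetic Medicare Advantage claims cohorts for the LOS analysis.

Real hospital claims are proprietary, so every downstream stage of the
pipeline is exercised on cohorts drawn from a generator whose marginal
distributions emulate the study population: mostly female (61%), mean
age 77 (SD 11), about one third enrolled in an institutional special
needs plan, 58/30/12% low/moderate/high pharmacogenetic interaction
probability (PIP), roughly half with a moderate-or-worse drug–drug
interaction (DDI), and a zero-truncated negative binomial length of
stay averaging ≈12.6 days.

Medication lists are constructed, not merely labelled: each patient is
assigned a small drug bundle whose score under the bundled knowledge
base lands in the target PIP category and whose drug pairs realize the
target DDI severity, so re-scoring the generated claims through
:mod:`pgxlos.risk_scoring` reproduces the configured exposure mix. LOS
is drawn directly from the zero-truncated NB2 with log-mean
``intercept + x'beta``, which makes maximum-likelihood parameter
recovery a clean consistency check.

Contamination (in-hospital deaths, short enrollment, repeat admissions,
missing fields) is injected so the cohort-construction filters have
real work to do; :func:`apply_cohort_filters` applies the study's
inclusion rules and tallies exclusions.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .pgx_kb import KnowledgeBase, default_knowledge_base, severity_rank
from .risk_scoring import (
    MedicationRecord,
    compute_ddi,
    compute_pip,
    screen_medications,
)
from .ztnb_model import ztnb_rvs

__all__ = [
    "Admission",
    "PatientRecord",
    "TrueModel",
    "GeneratorConfig",
    "generate_raw_cohort",
    "filter_patients",
    "apply_cohort_filters",
    "build_design_matrix",
    "expected_retention",
    "BASELINE_COVARIATES",
    "ADJUSTED_CANDIDATES",
]

_EPOCH = dt.date(2020, 1, 1)  # study window: 1 Jan – 30 Jun 2020

HCC_CATEGORIES = ("0-1", "2-3", "4-5", "6+")
PIP_CATEGORIES = ("low", "moderate", "high")
DDI_GROUPS = ("none", "moderate", "major", "contraindicated")
CONDITIONS = ("copd", "diabetes", "hyperlipidemia", "hypertension")

#: covariate spec of the unadjusted ("baseline") regression
BASELINE_COVARIATES = ("age", "gender", "pip_category", "ddi")
#: candidate covariates offered to the LASSO screen for the adjusted model
ADJUSTED_CANDIDATES = (
    "age", "gender", "pip_category", "ddi", "hcc_count_category",
    "raf_score", "median_income", "i_snp", "c_snp", "d_snp",
    "copd", "diabetes", "hyperlipidemia", "hypertension",
)


@dataclass(frozen=True)
class Admission:
    start_date: dt.date
    end_date: dt.date
    covid_flag: bool
    died_flag: bool

    @property
    def los_days(self) -> int:
        return (self.end_date - self.start_date).days


@dataclass
class PatientRecord:
    """One synthetic member: demographics, plan and condition covariates,
    medication history, and admission episodes."""

    patient_id: str
    age: float
    gender: str
    race_ethnicity: str
    residence: str
    median_income: float
    c_snp: bool
    d_snp: bool
    i_snp: bool
    hcc_count_category: str
    raf_score: float
    copd: bool
    diabetes: bool
    hyperlipidemia: bool
    hypertension: bool
    medications: list[MedicationRecord]
    admissions: list[Admission]
    enrollment_months: int


@dataclass
class TrueModel:
    """Generating ZTNB: log-mean ``intercept + x'beta``, dispersion theta.

    Coefficient keys use design-matrix column names (``age`` per year
    centered at the configured mean age; ``income_10k`` per USD 10,000
    centered at the configured mean). ``hcc_effect_modifiers`` optionally
    overrides coefficients within an HCC stratum, giving stratum-specific
    exposure effects for subgroup simulations.
    """

    intercept: float = 2.2835  # baseline log-mean; calibrated so that the
    # filtered cohort's mean LOS is ~12.6 days under the default marginals
    theta: float = 1.5
    coefficients: dict[str, float] = field(default_factory=lambda: {
        "age": 0.005,
        "gender_male": math.log(1.08),
        "pip_moderate": math.log(1.09),
        "pip_high": math.log(1.16),
        "ddi_moderate_plus": math.log(1.04),
        "hcc_2_3": math.log(1.10),
        "hcc_4_5": math.log(1.20),
        "hcc_6plus": math.log(1.30),
        "copd": math.log(1.08),
        "diabetes": math.log(1.05),
        "hyperlipidemia": math.log(1.03),
        "hypertension": math.log(1.05),
        "i_snp": math.log(0.75),
        "c_snp": 0.0,
        "d_snp": 0.0,
        "income_10k": -0.002,
        "raf_score": 0.0,
    })
    hcc_effect_modifiers: dict[str, dict[str, float]] | None = None


@dataclass
class GeneratorConfig:
    """All knobs of the cohort generator, defaulting to the study's
    marginal distributions."""

    n_patients: int = 6025
    seed: int = 0

    # --- marginals -------------------------------------------------------
    female_share: float = 0.61
    age_mean: float = 77.0
    age_sd: float = 11.0
    age_range: tuple[float, float] = (40.0, 102.0)
    race_dist: dict[str, float] = field(default_factory=lambda: {
        "white": 0.62, "black": 0.30, "hispanic": 0.03,
        "other": 0.02, "asian_pacific": 0.02, "unknown": 0.01,
    })
    residence_dist: dict[str, float] = field(default_factory=lambda: {
        "urban": 0.47, "suburban": 0.37, "rural": 0.16,
    })
    income_mean: float = 63027.0
    income_sd: float = 17435.0
    snp_dist: dict[str, float] = field(default_factory=lambda: {
        "none": 0.56, "c_snp": 0.04, "d_snp": 0.06, "i_snp": 0.34,
    })
    hcc_dist: dict[str, float] = field(default_factory=lambda: {
        "0-1": 0.24, "2-3": 0.33, "4-5": 0.20, "6+": 0.23,
    })
    condition_prevalence: dict[str, float] = field(default_factory=lambda: {
        "copd": 0.24, "diabetes": 0.52,
        "hyperlipidemia": 0.58, "hypertension": 0.32,
    })
    pip_dist: dict[str, float] = field(default_factory=lambda: {
        "low": 0.58, "moderate": 0.30, "high": 0.12,
    })
    ddi_dist: dict[str, float] = field(default_factory=lambda: {
        "none": 0.52, "moderate": 0.16, "major": 0.25, "contraindicated": 0.07,
    })

    # --- outcome model ---------------------------------------------------
    true_model: TrueModel = field(default_factory=TrueModel)

    # --- contamination for the cohort filters ----------------------------
    death_rate: float = 0.16
    sub12_enrollment_rate: float = 0.12
    multiple_admission_rate: float = 0.10
    missing_income_rate: float = 0.01

    # --- optional design bias for sensitivity tests ----------------------
    #: >0 tilts high-PIP categories toward high HCC counts, confounding
    #: the PIP–LOS association through disease burden when HCC is omitted
    confounding_strength: float = 0.0

    def validate(self) -> list[str]:
        errs: list[str] = []
        if self.n_patients < 1:
            errs.append("n_patients: must be >= 1")
        for name, dist in (
            ("race_dist", self.race_dist),
            ("residence_dist", self.residence_dist),
            ("snp_dist", self.snp_dist),
            ("hcc_dist", self.hcc_dist),
            ("pip_dist", self.pip_dist),
            ("ddi_dist", self.ddi_dist),
        ):
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                errs.append(f"{name}: probabilities sum to {total!r}, not 1")
            if any(v < 0 for v in dist.values()):
                errs.append(f"{name}: negative probability")
        for name, share in (("female_share", self.female_share),):
            if not 0.0 <= share <= 1.0:
                errs.append(f"{name}: {share} outside [0, 1]")
        for name, rate in (
            ("death_rate", self.death_rate),
            ("sub12_enrollment_rate", self.sub12_enrollment_rate),
            ("multiple_admission_rate", self.multiple_admission_rate),
            ("missing_income_rate", self.missing_income_rate),
        ):
            if not 0.0 <= rate <= 1.0:
                errs.append(f"{name}: {rate} outside [0, 1]")
        if self.true_model.theta <= 0:
            errs.append("true_model.theta: must be > 0")
        if self.age_sd <= 0:
            errs.append("age_sd: must be > 0")
        return errs

    @classmethod
    def from_dict(cls, doc: Mapping) -> "GeneratorConfig":
        doc = dict(doc)
        tm = doc.pop("true_model", None)
        cfg = cls(**doc)
        if tm is not None:
            base = TrueModel()
            coeffs = dict(base.coefficients)
            coeffs.update(tm.get("coefficients", {}))
            cfg.true_model = TrueModel(
                intercept=tm.get("intercept", base.intercept),
                theta=tm.get("theta", base.theta),
                coefficients=coeffs,
                hcc_effect_modifiers=tm.get("hcc_effect_modifiers"),
            )
        return cfg


def expected_retention(config: GeneratorConfig) -> float:
    """Expected fraction of raw members surviving the cohort filters
    (contamination mechanisms are independent by construction)."""
    return (
        (1.0 - config.death_rate)
        * (1.0 - config.sub12_enrollment_rate)
        * (1.0 - config.missing_income_rate)
    )


# ---------------------------------------------------------------------------
# medication bundles

# Candidate drug bundles per PIP category; each is validated against the
# knowledge base at generation time so the scored category always equals
# the assigned one.
_PIP_POOL: dict[str, list[tuple[str, ...]]] = {
    "low": [(), ("tramadol",), ("azathioprine",), ("escitalopram",),
            ("tacrolimus",), ("abacavir",)],
    "moderate": [("metoprolol",), ("omeprazole",), ("pantoprazole",),
                 ("clopidogrel",), ("simvastatin",)],
    "high": [("warfarin",), ("metoprolol", "omeprazole"),
             ("metoprolol", "simvastatin"), ("metoprolol", "fluoxetine")],
}

# DDI realization bundles; "none" covers the minimal-or-minor analysis
# reference group (including patients with no interacting pair at all).
_DDI_POOL: dict[str, list[tuple[str, ...]]] = {
    "none": [(), ("acetaminophen", "ondansetron"), ("aspirin", "ibuprofen")],
    "moderate": [("lisinopril", "spironolactone")],
    "major": [("furosemide", "gentamicin")],
    "contraindicated": [("azithromycin", "hydroxychloroquine")],
}


def _valid_bundles(kb: KnowledgeBase) -> dict[tuple[str, str], list[tuple[str, ...]]]:
    """Cross the PIP and DDI pools, score each combined drug set against
    the knowledge base, and keep only combinations whose scored PIP
    category and DDI group match the assignment exactly."""
    out: dict[tuple[str, str], list[tuple[str, ...]]] = {}
    for pip_cat, pip_bundles in _PIP_POOL.items():
        for ddi_cat, ddi_bundles in _DDI_POOL.items():
            valid: list[tuple[str, ...]] = []
            for pb in pip_bundles:
                for db in ddi_bundles:
                    drugs = tuple(sorted(set(pb) | set(db)))
                    pip = compute_pip(kb, set(drugs))
                    ddi = compute_ddi(kb, set(drugs))
                    group = (
                        "none"
                        if ddi.max_severity is None
                        or severity_rank(ddi.max_severity) < severity_rank("moderate")
                        else ddi.max_severity
                    )
                    if pip.category == pip_cat and group == ddi_cat:
                        valid.append(drugs)
            if not valid:
                raise RuntimeError(
                    f"no medication bundle realizes PIP={pip_cat}, DDI={ddi_cat} "
                    "against this knowledge base"
                )
            out[(pip_cat, ddi_cat)] = valid
    return out


# ---------------------------------------------------------------------------
# generation

def _categorical(rng: np.random.Generator, dist: Mapping[str, float], n: int
                 ) -> np.ndarray:
    keys = list(dist.keys())
    probs = np.asarray([dist[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(keys), size=n, p=probs)
    return np.asarray(keys, dtype=object)[idx]


_RAF_BASE = {"0-1": 0.9, "2-3": 1.4, "4-5": 2.1, "6+": 3.0}


def generate_raw_cohort(
    config: GeneratorConfig, kb: KnowledgeBase | None = None
) -> list[PatientRecord]:
    """Draw a raw (pre-filter) synthetic claims cohort.

    Deterministic given ``config.seed``. Covariates follow the configured
    marginals; medication lists realize the configured PIP/DDI mix under
    ``kb``; LOS is zero-truncated NB2 with log-mean ``intercept + x'beta``;
    deaths, short enrollment, repeat admissions and missing income are
    injected at the configured rates.
    """
    errs = config.validate()
    if errs:
        raise ValueError("invalid generator config:\n  " + "\n  ".join(errs))
    kb = kb or default_knowledge_base()
    bundles = _valid_bundles(kb)
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    tm = config.true_model

    gender = np.where(rng.random(n) < config.female_share, "female", "male")
    age = np.clip(
        rng.normal(config.age_mean, config.age_sd, n), *config.age_range
    )
    race = _categorical(rng, config.race_dist, n)
    residence = _categorical(rng, config.residence_dist, n)
    income = np.clip(rng.normal(config.income_mean, config.income_sd, n),
                     5000.0, None)
    snp = _categorical(rng, config.snp_dist, n)
    hcc = _categorical(rng, config.hcc_dist, n)
    raf = np.array([_RAF_BASE[h] for h in hcc]) * rng.lognormal(0.0, 0.25, n)
    conditions = {
        c: rng.random(n) < p for c, p in config.condition_prevalence.items()
    }

    # exposure categories, optionally tilted by HCC (confounding knob)
    pip_keys = list(config.pip_dist.keys())
    base_pip = np.asarray([config.pip_dist[k] for k in pip_keys], dtype=float)
    hcc_index = np.array([HCC_CATEGORIES.index(h) for h in hcc])
    if config.confounding_strength != 0.0:
        pip_cat = np.empty(n, dtype=object)
        tilt = np.exp(
            config.confounding_strength
            * np.outer(hcc_index, np.arange(len(pip_keys)))
        )
        w = base_pip * tilt
        w /= w.sum(axis=1, keepdims=True)
        u = rng.random(n)
        cum = np.cumsum(w, axis=1)
        for i in range(n):
            pip_cat[i] = pip_keys[int(np.searchsorted(cum[i], u[i], side="right"))]
    else:
        pip_cat = _categorical(rng, config.pip_dist, n)
    ddi_cat = _categorical(rng, config.ddi_dist, n)

    # linear predictor on the generating design
    coef = tm.coefficients

    def _c(name: str, override: Mapping[str, float] | None) -> float:
        if override and name in override:
            return override[name]
        return coef.get(name, 0.0)

    eta = np.full(n, tm.intercept)
    for i in range(n):
        over = None
        if tm.hcc_effect_modifiers:
            over = tm.hcc_effect_modifiers.get(hcc[i])
        e = 0.0
        e += _c("age", over) * (age[i] - config.age_mean)
        if gender[i] == "male":
            e += _c("gender_male", over)
        if pip_cat[i] == "moderate":
            e += _c("pip_moderate", over)
        elif pip_cat[i] == "high":
            e += _c("pip_high", over)
        if ddi_cat[i] != "none":
            e += _c("ddi_moderate_plus", over)
        if hcc[i] == "2-3":
            e += _c("hcc_2_3", over)
        elif hcc[i] == "4-5":
            e += _c("hcc_4_5", over)
        elif hcc[i] == "6+":
            e += _c("hcc_6plus", over)
        for c in CONDITIONS:
            if conditions[c][i]:
                e += _c(c, over)
        if snp[i] != "none":
            e += _c(snp[i], over)
        e += _c("income_10k", over) * (income[i] - config.income_mean) / 1e4
        e += _c("raf_score", over) * raf[i]
        eta[i] += e

    mu = np.exp(np.clip(eta, -20, 20))
    los = ztnb_rvs(mu, tm.theta, rng)

    died = rng.random(n) < config.death_rate
    short_enroll = rng.random(n) < config.sub12_enrollment_rate
    readmit = rng.random(n) < config.multiple_admission_rate
    missing_income = rng.random(n) < config.missing_income_rate
    adm_offset = rng.integers(0, 152, n)  # index admissions Jan–May 2020
    med_lag = rng.integers(5, 120, n)
    distractor = rng.random(n) < 0.30  # out-of-window historical drug
    unscored = rng.random(n) < 0.40    # in-window drug absent from the KB
    enroll_ok = 12 + rng.integers(0, 49, n)
    enroll_short = rng.integers(1, 12, n)
    los2 = ztnb_rvs(mu, tm.theta, rng)  # LOS of any repeat admission

    patients: list[PatientRecord] = []
    for i in range(n):
        options = bundles[(str(pip_cat[i]), str(ddi_cat[i]))]
        drugs = options[int(rng.integers(0, len(options)))]
        start = _EPOCH + dt.timedelta(days=int(adm_offset[i]))
        end = start + dt.timedelta(days=int(los[i]))
        meds = [
            MedicationRecord(d, start - dt.timedelta(days=int(med_lag[i])), None)
            for d in drugs
        ]
        if distractor[i]:
            meds.append(MedicationRecord(
                "naproxen",
                start - dt.timedelta(days=200),
                start - dt.timedelta(days=60),
            ))
        if unscored[i]:
            meds.append(MedicationRecord(
                "metformin", start - dt.timedelta(days=90), None
            ))
        admissions = [Admission(start, end, True, bool(died[i]))]
        if readmit[i]:
            s2 = end + dt.timedelta(days=30)
            admissions.append(
                Admission(s2, s2 + dt.timedelta(days=int(los2[i])), True, False)
            )
        patients.append(PatientRecord(
            patient_id=f"P{i:06d}",
            age=float(age[i]),
            gender=str(gender[i]),
            race_ethnicity=str(race[i]),
            residence=str(residence[i]),
            median_income=float("nan") if missing_income[i] else float(income[i]),
            c_snp=snp[i] == "c_snp",
            d_snp=snp[i] == "d_snp",
            i_snp=snp[i] == "i_snp",
            hcc_count_category=str(hcc[i]),
            raf_score=float(raf[i]),
            copd=bool(conditions["copd"][i]),
            diabetes=bool(conditions["diabetes"][i]),
            hyperlipidemia=bool(conditions["hyperlipidemia"][i]),
            hypertension=bool(conditions["hypertension"][i]),
            medications=meds,
            admissions=admissions,
            enrollment_months=int(enroll_short[i] if short_enroll[i]
                                  else enroll_ok[i]),
        ))
    return patients


# ---------------------------------------------------------------------------
# cohort filters

_NON_RACE_FIELDS = (
    "age", "median_income", "raf_score", "enrollment_months",
)


def _index_admission(p: PatientRecord) -> Admission | None:
    covid = [a for a in p.admissions if a.covid_flag]
    if not covid:
        return None
    return min(covid, key=lambda a: a.start_date)


def filter_patients(
    raw: Iterable[PatientRecord],
) -> tuple[list[PatientRecord], dict[str, int]]:
    """Apply the inclusion rules and tally exclusions, in order:
    first-admission selection, in-hospital death, <12-month enrollment,
    missing non-race data. Idempotent on an already-filtered cohort."""
    tally = {
        "no_covid_admission": 0,
        "later_admissions_dropped": 0,
        "death": 0,
        "enrollment": 0,
        "missingness": 0,
    }
    kept: list[PatientRecord] = []
    for p in raw:
        index = _index_admission(p)
        if index is None:
            tally["no_covid_admission"] += 1
            continue
        if len([a for a in p.admissions if a.covid_flag]) > 1:
            tally["later_admissions_dropped"] += 1
        if index.died_flag:
            tally["death"] += 1
            continue
        if p.enrollment_months < 12:
            tally["enrollment"] += 1
            continue
        if any(
            v is None or (isinstance(v, float) and math.isnan(v))
            for v in (getattr(p, f) for f in _NON_RACE_FIELDS)
        ):
            tally["missingness"] += 1
            continue
        kept.append(replace(p, admissions=[index]))
    return kept, tally


def cohort_table(
    patients: Sequence[PatientRecord], kb: KnowledgeBase | None = None
) -> pd.DataFrame:
    """Score each retained patient's screened medications and assemble
    the rectangular analysis table (one row per patient)."""
    kb = kb or default_knowledge_base()
    pip_cache: dict[frozenset, tuple] = {}
    rows = []
    for p in patients:
        adm = p.admissions[0]
        drugs = frozenset(
            screen_medications(p.medications, adm.start_date, adm.end_date)
        )
        if drugs not in pip_cache:
            pip = compute_pip(kb, set(drugs))
            ddi = compute_ddi(kb, set(drugs))
            pip_cache[drugs] = (pip, ddi)
        pip, ddi = pip_cache[drugs]
        rows.append({
            "patient_id": p.patient_id,
            "age": p.age,
            "gender": p.gender,
            "race_ethnicity": p.race_ethnicity,
            "residence": p.residence,
            "median_income": p.median_income,
            "c_snp": p.c_snp,
            "d_snp": p.d_snp,
            "i_snp": p.i_snp,
            "hcc_count_category": p.hcc_count_category,
            "raf_score": p.raf_score,
            "copd": p.copd,
            "diabetes": p.diabetes,
            "hyperlipidemia": p.hyperlipidemia,
            "hypertension": p.hypertension,
            "pip": pip.probability,
            "pip_category": pip.category,
            "ddi_max_severity": ddi.max_severity or "none",
            "ddi_moderate_plus": ddi.flag_moderate_plus,
            "los_days": adm.los_days,
            "enrollment_months": p.enrollment_months,
        })
    return pd.DataFrame(rows)


def apply_cohort_filters(
    raw: Iterable[PatientRecord], kb: KnowledgeBase | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Filter a raw cohort and build the scored analysis table."""
    kept, tally = filter_patients(raw)
    return cohort_table(kept, kb), tally


# ---------------------------------------------------------------------------
# design matrix

_REFERENCE_LEVELS = {
    "gender": ("female", {"male": "gender_male"}),
    "pip_category": ("low", {"moderate": "pip_moderate", "high": "pip_high"}),
    "hcc_count_category": ("0-1", {"2-3": "hcc_2_3", "4-5": "hcc_4_5",
                                   "6+": "hcc_6plus"}),
    "race_ethnicity": ("white", {
        "black": "race_black", "hispanic": "race_hispanic",
        "other": "race_other", "asian_pacific": "race_asian_pacific",
        "unknown": "race_unknown",
    }),
    "residence": ("urban", {"suburban": "residence_suburban",
                            "rural": "residence_rural"}),
}
_BOOLEAN_COVARIATES = ("i_snp", "c_snp", "d_snp") + CONDITIONS


class DesignError(ValueError):
    pass


def build_design_matrix(
    cohort: pd.DataFrame, covariates: Sequence[str] = BASELINE_COVARIATES
) -> pd.DataFrame:
    """Expand a covariate spec into a numeric design table.

    Categoricals are reference-coded against declared baselines (female;
    low PIP; minimal/minor DDI; HCC 0-1; urban; white; non-enrolled SNP);
    ``age`` is centered at the cohort mean, ``median_income`` is centered
    and scaled to USD 10,000 units (column ``income_10k``). Degenerate
    (constant) columns and absent reference levels raise
    :class:`DesignError` naming the covariate; column order follows the
    requested covariate order.
    """
    cols: dict[str, np.ndarray] = {}
    for cov in covariates:
        if cov == "age":
            a = cohort["age"].to_numpy(dtype=float)
            cols["age"] = a - a.mean()
        elif cov == "median_income":
            inc = cohort["median_income"].to_numpy(dtype=float)
            cols["income_10k"] = (inc - inc.mean()) / 1e4
        elif cov == "raf_score":
            cols["raf_score"] = cohort["raf_score"].to_numpy(dtype=float)
        elif cov == "ddi":
            cols["ddi_moderate_plus"] = (
                cohort["ddi_moderate_plus"].to_numpy(dtype=bool).astype(float)
            )
        elif cov in _REFERENCE_LEVELS:
            ref, levels = _REFERENCE_LEVELS[cov]
            values = cohort[cov].astype(str)
            observed = set(values.unique())
            unknown = observed - set(levels) - {ref}
            if unknown:
                raise DesignError(
                    f"covariate {cov!r}: unexpected level(s) {sorted(unknown)}"
                )
            if ref not in observed:
                raise DesignError(
                    f"covariate {cov!r}: reference level {ref!r} absent from data"
                )
            added = 0
            for level, name in levels.items():
                if level in observed:
                    cols[name] = (values == level).to_numpy(dtype=float)
                    added += 1
            if added == 0:
                raise DesignError(
                    f"covariate {cov!r} is degenerate: only the reference "
                    f"level {ref!r} is present"
                )
        elif cov in _BOOLEAN_COVARIATES:
            cols[cov] = cohort[cov].to_numpy(dtype=bool).astype(float)
        else:
            raise DesignError(f"unknown covariate {cov!r}")
    design = pd.DataFrame(cols, index=cohort.index)
    constant = [c for c in design.columns if design[c].nunique() <= 1]
    if constant:
        raise DesignError(
            "degenerate (constant) design column(s): " + ", ".join(constant)
        )
    return design


#: which design columns belong to which covariate, for grouped selection
def design_column_groups(covariates: Sequence[str]) -> dict[str, str]:
    """Map design column name -> requesting covariate (for grouped
    LASSO selection of multi-level categoricals)."""
    groups: dict[str, str] = {}
    for cov in covariates:
        if cov == "age":
            groups["age"] = "age"
        elif cov == "median_income":
            groups["income_10k"] = "median_income"
        elif cov == "raf_score":
            groups["raf_score"] = "raf_score"
        elif cov == "ddi":
            groups["ddi_moderate_plus"] = "ddi"
        elif cov in _REFERENCE_LEVELS:
            for name in _REFERENCE_LEVELS[cov][1].values():
                groups[name] = cov
        elif cov in _BOOLEAN_COVARIATES:
            groups[cov] = cov
    return groups
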
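"""End-to-end analysis: score exposures, filter the cohort, fit the
baseline and LASSO-adjusted ZTNB models, repeat per HCC-count and
chronic-condition stratum, and emit descriptive, rate-ratio, and
LOS-distribution tables.

Strata follow the study design: the HCC-count strata partition the
cohort; the chronic-condition strata overlap (a patient with both
diabetes and hypertension contributes to both), and each condition
model forces the other three conditions as controls. Subgroup models
re-run covariate selection within the stratum by default.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_synth import (
    ADJUSTED_CANDIDATES,
    BASELINE_COVARIATES,
    CONDITIONS,
    HCC_CATEGORIES,
    PIP_CATEGORIES,
    GeneratorConfig,
    apply_cohort_filters,
    build_design_matrix,
    generate_raw_cohort,
)
from .covariate_selection import (
    FORCED_EXPOSURES,
    SelectionResult,
    screen_and_fit,
)
from .pgx_kb import KnowledgeBase, default_knowledge_base, load_knowledge_base
from .ztnb_model import ZtnbFit, fit_ztnb, rate_ratio_table

__all__ = [
    "AnalysisConfig",
    "StratifiedReport",
    "run_analysis",
    "descriptive_table",
    "los_by_risk_table",
]

logger = logging.getLogger(__name__)

_EXPOSURE_TERMS = ("pip_moderate", "pip_high", "ddi_moderate_plus")
_EXPOSURE_LABELS = {
    "pip_moderate": "Moderate PIP (26% to 50%)",
    "pip_high": "High PIP (>50%)",
    "ddi_moderate_plus": "Moderate, Major, or Contraindicated DDI",
}


@dataclass
class AnalysisConfig:
    """Configuration for :func:`run_analysis`."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    seed: int = 0
    select: str = "lasso"  # 'lasso' or 'none' (fit all candidates)
    folds: int = 10
    per_stratum_selection: bool = True
    kb_path: str | None = None  # None -> bundled fixture KB
    out_dir: str | None = None
    cohort_path: str | None = None  # pre-built cohort CSV instead of simulating


@dataclass
class StratifiedReport:
    """One stratum's fitted model and its rate-ratio rows."""

    label: str
    n: int
    fit: ZtnbFit
    selection: SelectionResult | None
    rows: pd.DataFrame  # one row per exposure term


def _mean_ci(values: np.ndarray) -> tuple[float, float, float, int]:
    """Mean with normal-approximation 95% CI; CI is NaN for n < 2."""
    n = len(values)
    if n == 0:
        return float("nan"), float("nan"), float("nan"), 0
    m = float(np.mean(values))
    if n < 2:
        return m, float("nan"), float("nan"), n
    half = 1.959963984540054 * float(np.std(values, ddof=1)) / np.sqrt(n)
    return m, m - half, m + half, n


def descriptive_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Cohort profile: counts and percentages for categoricals, mean and
    SD (n-1 denominator) for age, income, and LOS."""
    if cohort.empty:
        raise ValueError("cohort is empty")
    n = len(cohort)
    rows: list[dict] = []

    def count_row(variable: str, category: str, mask: pd.Series) -> None:
        c = int(mask.sum())
        rows.append({"variable": variable, "category": category,
                     "count": c, "percent": 100.0 * c / n,
                     "mean": np.nan, "sd": np.nan})

    def mean_row(variable: str, values: pd.Series) -> None:
        rows.append({"variable": variable, "category": "mean (SD)",
                     "count": np.nan, "percent": np.nan,
                     "mean": float(values.mean()),
                     "sd": float(values.std(ddof=1))})

    count_row("gender", "female", cohort["gender"] == "female")
    mean_row("age", cohort["age"])
    for level in ("white", "black", "hispanic", "other", "asian_pacific",
                  "unknown"):
        count_row("race_ethnicity", level, cohort["race_ethnicity"] == level)
    for level in ("urban", "suburban", "rural"):
        count_row("residence", level, cohort["residence"] == level)
    mean_row("median_income", cohort["median_income"])
    for snp in ("c_snp", "d_snp", "i_snp"):
        count_row(snp, "enrolled", cohort[snp])
    for level in HCC_CATEGORIES:
        count_row("hcc_count_category", level,
                  cohort["hcc_count_category"] == level)
    for cond in CONDITIONS:
        count_row("chronic_condition", cond, cohort[cond])
    mean_row("los_days", cohort["los_days"])
    for level in PIP_CATEGORIES:
        count_row("pip_category", level, cohort["pip_category"] == level)
    count_row("ddi", "minimal_or_minor", ~cohort["ddi_moderate_plus"])
    for level in ("moderate", "major", "contraindicated"):
        count_row("ddi", level, cohort["ddi_max_severity"] == level)
    return pd.DataFrame(rows)


def los_by_risk_table(
    cohort: pd.DataFrame, conditions: Sequence[str] = CONDITIONS
) -> pd.DataFrame:
    """Mean LOS (95% CI, normal approximation) per chronic-condition
    subpopulation, overall and split by PIP level and by the DDI
    dichotomy. Cells with no patients are reported as missing; a
    single-patient cell keeps its mean but has an undefined CI."""
    if cohort.empty:
        raise ValueError("cohort is empty")
    rows = []

    def add(condition: str, split: str, level: str, values: np.ndarray):
        m, lo, hi, k = _mean_ci(values)
        rows.append({
            "condition": condition, "split": split, "level": level,
            "n": k, "mean_los": m, "ci_low": lo, "ci_high": hi,
            "ci_defined": bool(np.isfinite(lo)),
        })

    for cond in conditions:
        sub = cohort[cohort[cond].astype(bool)]
        add(cond, "total", "all", sub["los_days"].to_numpy())
        for level in PIP_CATEGORIES:
            add(cond, "pip", level,
                sub.loc[sub["pip_category"] == level, "los_days"].to_numpy())
        add(cond, "ddi", "minimal_or_minor",
            sub.loc[~sub["ddi_moderate_plus"], "los_days"].to_numpy())
        add(cond, "ddi", "moderate_plus",
            sub.loc[sub["ddi_moderate_plus"].astype(bool),
                    "los_days"].to_numpy())
    return pd.DataFrame(rows)


def _exposure_rows(fit: ZtnbFit, label: str, n: int) -> pd.DataFrame:
    table = rate_ratio_table(fit, labels=_EXPOSURE_LABELS)
    table = table[table["term"].isin(_EXPOSURE_TERMS)].copy()
    table.insert(0, "population", label)
    table.insert(1, "n", n)
    return table.reset_index(drop=True)


def _fit_stratum(
    cohort: pd.DataFrame,
    label: str,
    candidates: Sequence[str],
    always_keep: Sequence[str],
    seed: int,
    select: str,
    folds: int,
) -> StratifiedReport:
    t0 = time.perf_counter()
    if select == "lasso":
        selection, fit = screen_and_fit(
            cohort, candidates, seed=seed, always_keep=always_keep,
            folds=folds,
        )
    else:
        design = build_design_matrix(cohort, candidates)
        fit = fit_ztnb(design, cohort["los_days"].to_numpy())
        selection = None
    logger.info(
        "stage=fit stratum=%s n=%d seed=%d converged=%s wall=%.2fs",
        label, len(cohort), seed, fit.converged, time.perf_counter() - t0,
    )
    return StratifiedReport(
        label=label, n=len(cohort), fit=fit, selection=selection,
        rows=_exposure_rows(fit, label, len(cohort)),
    )


def _fit_to_dict(report: StratifiedReport) -> dict:
    fit = report.fit
    out = {
        "label": report.label,
        "n": report.n,
        "beta": {k: float(v) for k, v in fit.beta.items()},
        "theta": fit.theta,
        "loglik": fit.loglik,
        "converged": fit.converged,
        "grad_norm": fit.grad_norm,
        "covariance": {
            "names": list(fit.covariance.columns),
            "matrix": fit.covariance.to_numpy().tolist(),
        },
    }
    if report.selection is not None:
        out["selection"] = {
            "selected_covariates": list(report.selection.selected_covariates),
            "always_keep": list(report.selection.always_keep),
            "chosen_lambda": report.selection.chosen_lambda,
            "seed": report.selection.seed,
            "folds": report.selection.folds,
            "diagnostics": report.selection.diagnostics,
        }
    return out


def run_analysis(config: AnalysisConfig) -> dict:
    """Run the full pipeline and return all reports.

    Returns a dict with keys ``cohort``, ``exclusions``, ``table1``,
    ``table2``, ``table3``, ``baseline`` and ``reports`` (stratum label
    -> :class:`StratifiedReport`, including ``total``). When
    ``config.out_dir`` is set, artifacts are persisted there; partial
    artifacts survive a stage failure for inspection.
    """
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "fits").mkdir(exist_ok=True)
    artifacts: dict = {}
    stage = "init"
    try:
        stage = "knowledge_base"
        kb = (load_knowledge_base(config.kb_path)
              if config.kb_path else default_knowledge_base())

        stage = "cohort"
        t0 = time.perf_counter()
        if config.cohort_path:
            cohort = pd.read_csv(config.cohort_path)
            tally = {}
        else:
            gen = GeneratorConfig(**{**config.generator.__dict__,
                                     "seed": config.seed})
            raw = generate_raw_cohort(gen, kb)
            cohort, tally = apply_cohort_filters(raw, kb)
        logger.info("stage=cohort n=%d seed=%d wall=%.2fs",
                    len(cohort), config.seed, time.perf_counter() - t0)
        artifacts["cohort"] = cohort
        artifacts["exclusions"] = tally
        if out_dir:
            cohort.to_csv(out_dir / "cohort.csv", index=False)
            (out_dir / "exclusions.json").write_text(
                json.dumps(tally, indent=2) + "\n")

        stage = "table1"
        artifacts["table1"] = descriptive_table(cohort)

        stage = "baseline_fit"
        design = build_design_matrix(cohort, BASELINE_COVARIATES)
        baseline = fit_ztnb(design, cohort["los_days"].to_numpy())
        artifacts["baseline"] = StratifiedReport(
            label="baseline", n=len(cohort), fit=baseline, selection=None,
            rows=_exposure_rows(baseline, "baseline", len(cohort)),
        )

        stage = "adjusted_fit"
        reports: dict[str, StratifiedReport] = {}
        reports["total"] = _fit_stratum(
            cohort, "total", ADJUSTED_CANDIDATES, FORCED_EXPOSURES,
            config.seed, config.select, config.folds,
        )

        stage = "hcc_strata"
        hcc_candidates = tuple(
            c for c in ADJUSTED_CANDIDATES if c != "hcc_count_category"
        )
        for level in HCC_CATEGORIES:
            sub = cohort[cohort["hcc_count_category"] == level]
            label = f"hcc_{level}"
            seed = (config.seed if config.per_stratum_selection
                    else config.seed)
            reports[label] = _fit_stratum(
                sub.reset_index(drop=True), label, hcc_candidates,
                FORCED_EXPOSURES, seed,
                config.select if config.per_stratum_selection else "none",
                config.folds,
            )

        stage = "condition_strata"
        for cond in CONDITIONS:
            sub = cohort[cohort[cond].astype(bool)].reset_index(drop=True)
            others = tuple(c for c in CONDITIONS if c != cond)
            candidates = tuple(c for c in ADJUSTED_CANDIDATES if c != cond)
            reports[cond] = _fit_stratum(
                sub, cond, candidates,
                FORCED_EXPOSURES + others, config.seed,
                config.select if config.per_stratum_selection else "none",
                config.folds,
            )
        artifacts["reports"] = reports

        stage = "table2"
        order = (["total"] + [f"hcc_{h}" for h in HCC_CATEGORIES]
                 + list(CONDITIONS))
        artifacts["table2"] = pd.concat(
            [reports[k].rows for k in order], ignore_index=True
        )

        stage = "table3"
        artifacts["table3"] = los_by_risk_table(cohort)

        stage = "persist"
        if out_dir:
            artifacts["table1"].to_csv(out_dir / "table1.csv", index=False)
            artifacts["table2"].to_csv(out_dir / "table2.csv", index=False)
            artifacts["table3"].to_csv(out_dir / "table3.csv", index=False)
            for key, report in [("baseline", artifacts["baseline"])] + list(
                reports.items()
            ):
                (out_dir / "fits" / f"{key}.json").write_text(
                    json.dumps(_fit_to_dict(report), indent=2) + "\n"
                )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return artifacts
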
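"""Exposure scoring: pharmacogenetic interaction probability (PIP) and
worst-case drug–drug interaction (DDI) severity.

PIP is the probability that testing a fixed pharmacogene panel would
reveal at least one clinically actionable gene–drug or gene–drug–drug
interaction for the patient's screened medication list. Per gene ``g``,
``p_g`` is the population frequency mass of phenotypes actionable for at
least one screened drug interacting with ``g``; assuming independence of
phenotypes across genes,

    PIP = 1 - prod_g (1 - p_g).

Gene–drug–drug interactions enter through phenoconversion: when a
screened inhibitor induces a phenotype at ``g`` that is actionable for a
screened substrate of ``g``, the interaction is certain and ``p_g = 1``.

DDI severity is graded on the ordinal scale minimal < minor < moderate <
major < contraindicated over all unordered pairs of screened drugs; only
the most severe matched pair is retained, and the analysis dichotomy
flags moderate-or-worse regimens.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .pgx_kb import KnowledgeBase, normalize_drug, severity_rank

__all__ = [
    "MedicationRecord",
    "PipResult",
    "DdiResult",
    "screen_medications",
    "gene_actionable_probability",
    "compute_pip",
    "categorize_pip",
    "compute_ddi",
    "score_patient",
    "score_cohort",
]

logger = logging.getLogger(__name__)

SCREEN_WINDOW_DAYS = 30  # days before admission in which active meds count


@dataclass(frozen=True)
class MedicationRecord:
    """One dispensed/active medication interval; ``end_date=None`` is open."""

    drug: str
    start_date: dt.date
    end_date: dt.date | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "drug", normalize_drug(self.drug))


@dataclass(frozen=True)
class GeneContribution:
    """Per-gene contribution to PIP: which screened drugs made which
    phenotype mass actionable; ``phenoconverted`` marks a deterministic
    gene–drug–drug triple (substrate, inhibitor)."""

    gene: str
    drugs: tuple[str, ...]
    p_g: float
    phenoconverted: bool = False
    inhibitor: str | None = None


@dataclass(frozen=True)
class PipResult:
    probability: float
    category: str
    contributing: tuple[GeneContribution, ...]
    unscored_drugs: tuple[str, ...] = ()


@dataclass(frozen=True)
class DdiResult:
    max_severity: str | None
    pairs: tuple[tuple[str, str, str], ...]
    flag_moderate_plus: bool


def screen_medications(
    meds: Iterable[MedicationRecord],
    admission_start: dt.date,
    admission_end: dt.date,
) -> set[str]:
    """Drugs active or prescribed within 30 days prior to and during an
    admission.

    A record is in-window when its active interval ``[start, end]``
    (open end = still active) intersects
    ``[admission_start - 30 days, admission_end]``. Malformed records
    (start after end) are logged and skipped; the rest are processed.
    """
    if admission_start > admission_end:
        raise ValueError("admission_start after admission_end")
    window_start = admission_start - dt.timedelta(days=SCREEN_WINDOW_DAYS)
    out: set[str] = set()
    for rec in meds:
        if rec.end_date is not None and rec.start_date > rec.end_date:
            logger.warning(
                "rejecting medication record %s: start %s after end %s",
                rec.drug, rec.start_date, rec.end_date,
            )
            continue
        ends_after = rec.end_date is None or rec.end_date >= window_start
        starts_before = rec.start_date <= admission_end
        if ends_after and starts_before:
            out.add(rec.drug)
    return out


def gene_actionable_probability(
    kb: KnowledgeBase, gene: str, drugs: set[str]
) -> float:
    """Probability ``p_g`` that gene ``g``'s phenotype is actionable for at
    least one in-list drug: the frequency mass of the union of
    actionable-phenotype sets over the gene's in-list drugs (1.0 if an
    in-list inhibitor phenoconverts the gene for an in-list substrate)."""
    contrib = _gene_contribution(kb, gene, drugs)
    return contrib.p_g if contrib is not None else 0.0


def _gene_contribution(
    kb: KnowledgeBase, gene: str, drugs: set[str]
) -> GeneContribution | None:
    profile = kb.profiles_by_gene.get(gene)
    if profile is None:
        raise KeyError(f"gene {gene!r} not in knowledge base")
    dgis = [
        d for d in kb.interactions_by_gene.get(gene, ()) if d.drug in drugs
    ]
    if not dgis:
        return None
    # phenoconversion: an in-list inhibitor of this gene whose induced
    # phenotype is actionable for an in-list substrate makes the
    # interaction deterministic.
    for rel in kb.inhibition_relations:
        if rel.gene != gene or rel.inhibitor_drug not in drugs:
            continue
        for d in dgis:
            if d.drug != rel.inhibitor_drug and rel.induced_phenotype in d.actionable_phenotypes:
                return GeneContribution(
                    gene=gene,
                    drugs=tuple(sorted({x.drug for x in dgis})),
                    p_g=1.0,
                    phenoconverted=True,
                    inhibitor=rel.inhibitor_drug,
                )
    actionable: set[str] = set()
    for d in dgis:
        actionable |= d.actionable_phenotypes
    return GeneContribution(
        gene=gene,
        drugs=tuple(sorted(d.drug for d in dgis)),
        p_g=profile.mass(actionable),
    )


def categorize_pip(probability: float) -> str:
    """Risk category: low (≤25%), moderate (>25% to ≤50%), high (>50%)."""
    if not (0.0 <= probability <= 1.0) or math.isnan(probability):
        raise ValueError(f"PIP {probability!r} outside [0, 1]")
    if probability <= 0.25:
        return "low"
    if probability <= 0.50:
        return "moderate"
    return "high"


def compute_pip(kb: KnowledgeBase, drugs: set[str]) -> PipResult:
    """PIP over the knowledge base's gene panel for a screened drug set."""
    drugs = {normalize_drug(d) for d in drugs}
    contributions: list[GeneContribution] = []
    log_surv = 0.0  # log prod_g (1 - p_g)
    certain = False
    for gene in kb.panel:
        contrib = _gene_contribution(kb, gene, drugs)
        if contrib is None or contrib.p_g == 0.0:
            continue
        contributions.append(contrib)
        if contrib.p_g >= 1.0:
            certain = True
        else:
            log_surv += math.log1p(-contrib.p_g)
    probability = 1.0 if certain else -math.expm1(log_surv)
    unscored = tuple(sorted(drugs - kb.known_drugs))
    if unscored:
        logger.debug("unscored drugs (absent from knowledge base): %s",
                     ", ".join(unscored))
    return PipResult(
        probability=probability,
        category=categorize_pip(probability),
        contributing=tuple(contributions),
        unscored_drugs=unscored,
    )


def compute_ddi(kb: KnowledgeBase, drugs: set[str]) -> DdiResult:
    """Worst-case DDI severity over all unordered in-list drug pairs."""
    drugs = sorted({normalize_drug(d) for d in drugs})
    matched: list[tuple[str, str, str]] = []
    for i, a in enumerate(drugs):
        for b in drugs[i + 1:]:
            sev = kb.pair_severity.get((a, b))
            if sev is not None:
                matched.append((a, b, sev))
    if matched:
        max_sev = max((sev for _, _, sev in matched), key=severity_rank)
        flag = severity_rank(max_sev) >= severity_rank("moderate")
    else:
        max_sev, flag = None, False
    return DdiResult(max_severity=max_sev, pairs=tuple(matched),
                     flag_moderate_plus=flag)


def score_patient(
    kb: KnowledgeBase,
    meds: Sequence[MedicationRecord],
    admission_start: dt.date,
    admission_end: dt.date,
) -> tuple[PipResult, DdiResult]:
    """Screen a medication history against an admission and score both
    exposures."""
    drugs = screen_medications(meds, admission_start, admission_end)
    return compute_pip(kb, drugs), compute_ddi(kb, drugs)


def score_cohort(
    kb: KnowledgeBase, med_table: pd.DataFrame
) -> pd.DataFrame:
    """Score per-patient medication lists given as a long table.

    ``med_table`` columns: patient_id, drug, start_date, end_date (ISO
    dates; end may be blank), admission_start, admission_end. Returns one
    row per patient: pip, pip_category, ddi_max_severity,
    ddi_moderate_plus, n_unscored_drugs.
    """
    rows = []
    for pid, grp in med_table.groupby("patient_id", sort=True):
        adm_start = pd.Timestamp(grp["admission_start"].iloc[0]).date()
        adm_end = pd.Timestamp(grp["admission_end"].iloc[0]).date()
        meds = [
            MedicationRecord(
                r.drug,
                pd.Timestamp(r.start_date).date(),
                None if pd.isna(r.end_date) else pd.Timestamp(r.end_date).date(),
            )
            for r in grp.itertuples()
        ]
        pip, ddi = score_patient(kb, meds, adm_start, adm_end)
        rows.append({
            "patient_id": pid,
            "pip": pip.probability,
            "pip_category": pip.category,
            "ddi_max_severity": ddi.max_severity or "none",
            "ddi_moderate_plus": ddi.flag_moderate_plus,
            "n_unscored_drugs": len(pip.unscored_drugs),
        })
    return pd.DataFrame(rows)
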
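"""Pharmacogene knowledge base: gene phenotype frequencies, drug–gene
interactions, drug-pair (DDI) severities, and inhibitor relations.

The knowledge base parameterizes the two exposure scores computed in
:mod:`pgxlos.risk_scoring`:

* the pharmacogenetic interaction probability (PIP), driven by per-gene
  phenotype prevalence and per-drug actionable-phenotype sets, and
* the worst-case drug–drug interaction (DDI) severity, driven by an
  ordinal severity table over unordered drug pairs.

A small curated fixture covering a 14-gene panel ships with the package
(:func:`default_knowledge_base`). Its phenotype frequencies are chosen to
be consistent with published U.S. population prevalences; the actionable
sets are illustrative, not a reproduction of any proprietary rule base.

On-disk formats: a directory bundle of four TSV tables plus a JSON
manifest (canonical), or a single JSON document (convenient for tests).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from functools import cached_property
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "SEVERITY_LEVELS",
    "severity_rank",
    "normalize_drug",
    "GenePhenotypeProfile",
    "DrugGeneInteraction",
    "DrugPairInteraction",
    "InhibitionRelation",
    "KnowledgeBase",
    "Violation",
    "KnowledgeBaseError",
    "validate_knowledge_base",
    "load_knowledge_base",
    "save_knowledge_base",
    "default_knowledge_base",
]

#: DDI severity scale, in increasing order of clinical concern.
SEVERITY_LEVELS: tuple[str, ...] = (
    "minimal",
    "minor",
    "moderate",
    "major",
    "contraindicated",
)
_SEVERITY_RANK: dict[str, int] = {s: i for i, s in enumerate(SEVERITY_LEVELS)}

#: Default 14-gene pharmacogene panel.
DEFAULT_PANEL: tuple[str, ...] = (
    "CYP2C19",
    "CYP2C9",
    "CYP2D6",
    "CYP3A4",
    "CYP3A5",
    "CYP2B6",
    "CYP4F2",
    "DPYD",
    "HLA-B*57:01",
    "IFNL3",
    "SLCO1B1",
    "TPMT",
    "UGT1A1",
    "VKORC1",
)

_WS = re.compile(r"\s+")


def severity_rank(severity: str) -> int:
    """Ordinal rank of a DDI severity level (minimal=0 … contraindicated=4)."""
    try:
        return _SEVERITY_RANK[severity]
    except KeyError:
        raise ValueError(
            f"unknown DDI severity {severity!r}; expected one of {SEVERITY_LEVELS}"
        ) from None


def normalize_drug(name: str) -> str:
    """Canonical drug-name form: case-folded, trimmed, single-spaced."""
    return _WS.sub(" ", name.strip()).casefold()


class KnowledgeBaseError(ValueError):
    """Raised when a knowledge base fails schema or integrity validation."""

    def __init__(self, violations: Sequence["Violation"]):
        self.violations = list(violations)
        lines = "\n".join(f"  [{v.code}] {v.message}" for v in self.violations)
        super().__init__(f"knowledge base validation failed:\n{lines}")


@dataclass(frozen=True)
class Violation:
    """One validation failure, machine-readable code plus human message."""

    code: str
    message: str
    table: str | None = None
    row: int | None = None


@dataclass(frozen=True)
class GenePhenotypeProfile:
    """Categorical phenotype distribution for one gene.

    ``phenotypes`` maps phenotype label -> population frequency; stored
    sorted by label so that serialization is canonical.
    """

    gene: str
    phenotypes: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "phenotypes", tuple(sorted(self.phenotypes, key=lambda t: t[0]))
        )

    @property
    def labels(self) -> frozenset[str]:
        return frozenset(label for label, _ in self.phenotypes)

    def frequency(self, label: str) -> float:
        for lab, freq in self.phenotypes:
            if lab == label:
                return freq
        raise KeyError(f"phenotype {label!r} not in profile for {self.gene}")

    def mass(self, labels: Iterable[str]) -> float:
        """Total frequency of a set of phenotype labels."""
        wanted = set(labels)
        return sum(freq for lab, freq in self.phenotypes if lab in wanted)


@dataclass(frozen=True)
class DrugGeneInteraction:
    """A drug whose dosing guidance depends on a gene's phenotype."""

    drug: str
    gene: str
    actionable_phenotypes: frozenset[str]
    source: str = "cpic"


@dataclass(frozen=True)
class DrugPairInteraction:
    """An unordered drug pair with an ordinal DDI severity."""

    drug_a: str
    drug_b: str
    severity: str

    def __post_init__(self) -> None:
        a, b = sorted((self.drug_a, self.drug_b))
        object.__setattr__(self, "drug_a", a)
        object.__setattr__(self, "drug_b", b)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.drug_a, self.drug_b)


@dataclass(frozen=True)
class InhibitionRelation:
    """A drug that phenoconverts patients at a gene.

    A co-medicated patient is treated as having ``induced_phenotype`` at
    ``gene`` while taking ``inhibitor_drug`` (e.g. a strong CYP2D6
    inhibitor induces a poor-metabolizer phenocopy).
    """

    inhibitor_drug: str
    gene: str
    induced_phenotype: str


@dataclass
class KnowledgeBase:
    """The four interaction tables plus the ordered gene panel."""

    gene_profiles: tuple[GenePhenotypeProfile, ...]
    drug_gene_interactions: tuple[DrugGeneInteraction, ...]
    drug_pair_interactions: tuple[DrugPairInteraction, ...]
    inhibition_relations: tuple[InhibitionRelation, ...]
    panel: tuple[str, ...] = DEFAULT_PANEL
    version: str = "0.1.0"

    @cached_property
    def profiles_by_gene(self) -> dict[str, GenePhenotypeProfile]:
        return {p.gene: p for p in self.gene_profiles}

    @cached_property
    def interactions_by_gene(self) -> dict[str, tuple[DrugGeneInteraction, ...]]:
        out: dict[str, list[DrugGeneInteraction]] = {}
        for dgi in self.drug_gene_interactions:
            out.setdefault(dgi.gene, []).append(dgi)
        return {g: tuple(v) for g, v in out.items()}

    @cached_property
    def pair_severity(self) -> dict[tuple[str, str], str]:
        return {p.pair: p.severity for p in self.drug_pair_interactions}

    @cached_property
    def known_drugs(self) -> frozenset[str]:
        drugs: set[str] = set()
        drugs.update(d.drug for d in self.drug_gene_interactions)
        for p in self.drug_pair_interactions:
            drugs.update(p.pair)
        drugs.update(i.inhibitor_drug for i in self.inhibition_relations)
        return frozenset(drugs)

    def content_key(self):
        """Hashable canonical content, for content-equality tests."""
        return (
            tuple(sorted(self.gene_profiles, key=lambda p: p.gene)),
            tuple(
                sorted(
                    self.drug_gene_interactions,
                    key=lambda d: (d.drug, d.gene),
                )
            ),
            tuple(sorted(self.drug_pair_interactions, key=lambda p: p.pair)),
            tuple(
                sorted(
                    self.inhibition_relations,
                    key=lambda i: (i.inhibitor_drug, i.gene),
                )
            ),
            self.panel,
        )


# ---------------------------------------------------------------------------
# validation

_FREQ_TOL = 1e-9


def validate_knowledge_base(kb: KnowledgeBase) -> list[Violation]:
    """Check every invariant and return the complete list of violations.

    An empty list means the knowledge base is internally consistent:
    frequencies are proper distributions, all cross-table references
    (gene, phenotype, drug pair) resolve, and no table holds duplicates.
    """
    out: list[Violation] = []

    seen_genes: set[str] = set()
    for i, prof in enumerate(kb.gene_profiles):
        if prof.gene in seen_genes:
            out.append(
                Violation("DUP_GENE", f"gene {prof.gene!r} appears more than once",
                          "gene_phenotypes", i)
            )
        seen_genes.add(prof.gene)
        labels = [lab for lab, _ in prof.phenotypes]
        if len(labels) != len(set(labels)):
            out.append(
                Violation("DUP_PHENOTYPE",
                          f"duplicate phenotype label in profile for {prof.gene}",
                          "gene_phenotypes", i)
            )
        for lab, freq in prof.phenotypes:
            if not (0.0 <= freq <= 1.0):
                out.append(
                    Violation("FREQ_RANGE",
                              f"{prof.gene}:{lab} frequency {freq} outside [0, 1]",
                              "gene_phenotypes", i)
                )
        total = sum(freq for _, freq in prof.phenotypes)
        if abs(total - 1.0) > _FREQ_TOL:
            out.append(
                Violation("FREQ_SUM",
                          f"frequencies for {prof.gene} sum to {total!r}, not 1",
                          "gene_phenotypes", i)
            )

    profiles = {p.gene: p for p in kb.gene_profiles}

    seen_edges: set[tuple[str, str]] = set()
    for i, dgi in enumerate(kb.drug_gene_interactions):
        key = (dgi.drug, dgi.gene)
        if key in seen_edges:
            out.append(
                Violation("DUP_EDGE",
                          f"duplicate drug–gene row for {dgi.drug!r} × {dgi.gene}",
                          "drug_gene", i)
            )
        seen_edges.add(key)
        if not dgi.actionable_phenotypes:
            out.append(
                Violation("EMPTY_ACTIONABLE",
                          f"{dgi.drug!r} × {dgi.gene}: empty actionable set",
                          "drug_gene", i)
            )
        prof = profiles.get(dgi.gene)
        if prof is None:
            out.append(
                Violation("UNKNOWN_GENE",
                          f"drug–gene row {dgi.drug!r} references unknown gene "
                          f"{dgi.gene!r}", "drug_gene", i)
            )
        else:
            for lab in sorted(dgi.actionable_phenotypes - prof.labels):
                out.append(
                    Violation("UNKNOWN_PHENOTYPE",
                              f"drug–gene row {dgi.drug!r} × {dgi.gene}: phenotype "
                              f"{lab!r} absent from the gene's profile",
                              "drug_gene", i)
                )

    seen_pairs: set[tuple[str, str]] = set()
    for i, dpi in enumerate(kb.drug_pair_interactions):
        if dpi.drug_a == dpi.drug_b:
            out.append(
                Violation("SELF_PAIR", f"drug pair {dpi.drug_a!r} with itself",
                          "drug_pairs", i)
            )
        if dpi.pair in seen_pairs:
            out.append(
                Violation("DUP_PAIR", f"duplicate drug pair {dpi.pair}",
                          "drug_pairs", i)
            )
        seen_pairs.add(dpi.pair)
        if dpi.severity not in _SEVERITY_RANK:
            out.append(
                Violation("BAD_SEVERITY",
                          f"pair {dpi.pair}: severity {dpi.severity!r} not on the "
                          f"scale {SEVERITY_LEVELS}", "drug_pairs", i)
            )

    seen_inhib: set[tuple[str, str]] = set()
    for i, rel in enumerate(kb.inhibition_relations):
        key = (rel.inhibitor_drug, rel.gene)
        if key in seen_inhib:
            out.append(
                Violation("DUP_INHIBITOR",
                          f"duplicate inhibitor row {key}", "inhibitors", i)
            )
        seen_inhib.add(key)
        prof = profiles.get(rel.gene)
        if prof is None:
            out.append(
                Violation("UNKNOWN_GENE",
                          f"inhibitor {rel.inhibitor_drug!r} references unknown "
                          f"gene {rel.gene!r}", "inhibitors", i)
            )
        elif rel.induced_phenotype not in prof.labels:
            out.append(
                Violation("UNKNOWN_PHENOTYPE",
                          f"inhibitor {rel.inhibitor_drug!r} × {rel.gene}: induced "
                          f"phenotype {rel.induced_phenotype!r} absent from the "
                          f"gene's profile", "inhibitors", i)
            )

    for gene in kb.panel:
        if gene not in profiles:
            out.append(
                Violation("PANEL_GENE_MISSING",
                          f"panel gene {gene!r} has no phenotype profile", "manifest")
            )

    return out


# ---------------------------------------------------------------------------
# i/o

_TABLES = {
    "gene_phenotypes": ("gene", "phenotype", "frequency"),
    "drug_gene": ("drug", "gene", "actionable_phenotypes", "source"),
    "drug_pairs": ("drug_a", "drug_b", "severity"),
    "inhibitors": ("inhibitor_drug", "gene", "induced_phenotype"),
}


def _read_tsv(path: Path, table: str) -> list[dict[str, str]]:
    expected = _TABLES[table]
    if not path.exists():
        raise FileNotFoundError(f"missing table file {path}")
    rows: list[dict[str, str]] = []
    header: list[str] | None = None
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cells = line.split("\t")
            if header is None:
                header = [c.strip() for c in cells]
                missing = [c for c in expected if c not in header]
                if missing:
                    raise KnowledgeBaseError([
                        Violation("SCHEMA",
                                  f"{path.name}: header missing column(s) "
                                  f"{missing}", table, lineno)
                    ])
                continue
            if len(cells) < len(header):
                raise KnowledgeBaseError([
                    Violation("SCHEMA",
                              f"{path.name} line {lineno}: expected "
                              f"{len(header)} columns, got {len(cells)}",
                              table, lineno)
                ])
            rows.append({h: c.strip() for h, c in zip(header, cells)})
    if header is None:
        raise KnowledgeBaseError(
            [Violation("SCHEMA", f"{path.name}: no header row", table)]
        )
    return rows


def _kb_from_rows(
    gp_rows: list[dict[str, str]],
    dg_rows: list[dict[str, str]],
    pair_rows: list[dict[str, str]],
    inh_rows: list[dict[str, str]],
    panel: Sequence[str],
    version: str,
) -> KnowledgeBase:
    by_gene: dict[str, list[tuple[str, float]]] = {}
    order: list[str] = []
    for i, row in enumerate(gp_rows):
        try:
            freq = float(row["frequency"])
        except ValueError:
            raise KnowledgeBaseError([
                Violation("SCHEMA",
                          f"gene_phenotypes row {i}: frequency "
                          f"{row['frequency']!r} is not a number",
                          "gene_phenotypes", i)
            ]) from None
        g = row["gene"]
        if g not in by_gene:
            by_gene[g] = []
            order.append(g)
        by_gene[g].append((row["phenotype"], freq))
    profiles = tuple(
        GenePhenotypeProfile(g, tuple(by_gene[g])) for g in order
    )
    dgis = tuple(
        DrugGeneInteraction(
            normalize_drug(r["drug"]),
            r["gene"],
            frozenset(p.strip() for p in r["actionable_phenotypes"].split(";") if p.strip()),
            r.get("source", "") or "unspecified",
        )
        for r in dg_rows
    )
    pairs = tuple(
        DrugPairInteraction(
            normalize_drug(r["drug_a"]), normalize_drug(r["drug_b"]), r["severity"]
        )
        for r in pair_rows
    )
    inhibitors = tuple(
        InhibitionRelation(
            normalize_drug(r["inhibitor_drug"]), r["gene"], r["induced_phenotype"]
        )
        for r in inh_rows
    )
    return KnowledgeBase(profiles, dgis, pairs, inhibitors, tuple(panel), version)


def load_knowledge_base(path: str | Path, format: str | None = None) -> KnowledgeBase:
    """Load and validate a knowledge base.

    ``format`` is ``"tsv-bundle"`` (a directory of four TSV tables plus
    ``manifest.json``) or ``"json"`` (a single document); when omitted it
    is inferred from the path. Raises :class:`KnowledgeBaseError` carrying
    the complete violation list if validation fails.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"knowledge base path {path} does not exist")
    if format is None:
        format = "tsv-bundle" if path.is_dir() else "json"
    if format == "tsv-bundle":
        manifest_path = path / "manifest.json"
        if not manifest_path.exists():
            raise FileNotFoundError(f"missing manifest {manifest_path}")
        manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
        kb = _kb_from_rows(
            _read_tsv(path / "gene_phenotypes.tsv", "gene_phenotypes"),
            _read_tsv(path / "drug_gene.tsv", "drug_gene"),
            _read_tsv(path / "drug_pairs.tsv", "drug_pairs"),
            _read_tsv(path / "inhibitors.tsv", "inhibitors"),
            manifest["panel"],
            manifest.get("version", "unversioned"),
        )
    elif format == "json":
        doc = json.loads(path.read_text(encoding="utf-8"))
        kb = _kb_from_rows(
            doc["gene_phenotypes"],
            doc["drug_gene"],
            doc["drug_pairs"],
            doc["inhibitors"],
            doc["panel"],
            doc.get("version", "unversioned"),
        )
    else:
        raise ValueError(f"unknown knowledge base format {format!r}")
    violations = validate_knowledge_base(kb)
    if violations:
        raise KnowledgeBaseError(violations)
    return kb


def _fmt_freq(freq: float) -> str:
    return format(freq, ".17g")


def save_knowledge_base(
    kb: KnowledgeBase, path: str | Path, format: str = "tsv-bundle"
) -> None:
    """Serialize in canonical order (genes and drugs sorted lexicographically),
    so save∘load is byte-stable."""
    path = Path(path)
    gp_rows = [
        {"gene": p.gene, "phenotype": lab, "frequency": _fmt_freq(freq)}
        for p in sorted(kb.gene_profiles, key=lambda p: p.gene)
        for lab, freq in p.phenotypes
    ]
    dg_rows = [
        {
            "drug": d.drug,
            "gene": d.gene,
            "actionable_phenotypes": ";".join(sorted(d.actionable_phenotypes)),
            "source": d.source,
        }
        for d in sorted(kb.drug_gene_interactions, key=lambda d: (d.drug, d.gene))
    ]
    pair_rows = [
        {"drug_a": p.drug_a, "drug_b": p.drug_b, "severity": p.severity}
        for p in sorted(kb.drug_pair_interactions, key=lambda p: p.pair)
    ]
    inh_rows = [
        {"inhibitor_drug": r.inhibitor_drug, "gene": r.gene,
         "induced_phenotype": r.induced_phenotype}
        for r in sorted(kb.inhibition_relations,
                        key=lambda r: (r.inhibitor_drug, r.gene))
    ]
    if format == "tsv-bundle":
        path.mkdir(parents=True, exist_ok=True)
        for table, rows in (
            ("gene_phenotypes", gp_rows),
            ("drug_gene", dg_rows),
            ("drug_pairs", pair_rows),
            ("inhibitors", inh_rows),
        ):
            cols = _TABLES[table]
            lines = ["\t".join(cols)]
            lines += ["\t".join(r[c] for c in cols) for r in rows]
            (path / f"{table}.tsv").write_text("\n".join(lines) + "\n",
                                               encoding="utf-8")
        manifest = {"version": kb.version, "panel": list(kb.panel)}
        (path / "manifest.json").write_text(
            json.dumps(manifest, indent=2) + "\n", encoding="utf-8"
        )
    elif format == "json":
        doc = {
            "version": kb.version,
            "panel": list(kb.panel),
            "gene_phenotypes": gp_rows,
            "drug_gene": dg_rows,
            "drug_pairs": pair_rows,
            "inhibitors": inh_rows,
        }
        path.write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown knowledge base format {format!r}")


def default_knowledge_base() -> KnowledgeBase:
    """The bundled 14-gene fixture knowledge base."""
    root = resources.files("pgxlos").joinpath("data/kb")
    with resources.as_file(root) as p:
        return load_knowledge_base(p, format="tsv-bundle")
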
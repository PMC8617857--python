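"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the library's closed-form code paths: the PIP
oracle enumerates the joint phenotype space outright, and the ZTNB grid
oracle maximizes the likelihood by lattice search.
"""

import itertools

import numpy as np

from pgxlos.pgx_kb import (
    DrugGeneInteraction,
    GenePhenotypeProfile,
    InhibitionRelation,
    KnowledgeBase,
)
from pgxlos.ztnb_model import ztnb_log_pmf


def pip_enumeration_oracle(kb: KnowledgeBase, drugs: set[str]) -> float:
    """P(at least one actionable interaction) by exhaustive enumeration of
    the joint phenotype assignment across the panel."""
    genes = list(kb.panel)
    profiles = {p.gene: p for p in kb.gene_profiles}
    # per gene: the set of phenotypes actionable for some in-list drug,
    # and whether a phenoconversion triple fires deterministically
    actionable: dict[str, set[str]] = {g: set() for g in genes}
    certain: set[str] = set()
    for g in genes:
        dgis = [d for d in kb.drug_gene_interactions
                if d.gene == g and d.drug in drugs]
        for d in dgis:
            actionable[g] |= d.actionable_phenotypes
        for rel in kb.inhibition_relations:
            if rel.gene != g or rel.inhibitor_drug not in drugs:
                continue
            for d in dgis:
                if (d.drug != rel.inhibitor_drug
                        and rel.induced_phenotype in d.actionable_phenotypes):
                    certain.add(g)
    if certain:
        return 1.0
    total = 0.0
    spaces = [profiles[g].phenotypes for g in genes]
    for combo in itertools.product(*spaces):
        mass = 1.0
        hit = False
        for g, (label, freq) in zip(genes, combo):
            mass *= freq
            if label in actionable[g]:
                hit = True
        if hit:
            total += mass
    return total


def random_tiny_kb(rng: np.random.Generator):
    """A random knowledge base with <=4 genes, <=4 phenotypes per gene,
    and a handful of drugs with random actionable sets."""
    n_genes = int(rng.integers(1, 5))
    genes = [f"G{i}" for i in range(n_genes)]
    profiles = []
    phenos: dict[str, list[str]] = {}
    for g in genes:
        k = int(rng.integers(2, 5))
        labels = [f"ph{j}" for j in range(k)]
        freqs = rng.dirichlet(np.ones(k))
        freqs = freqs / freqs.sum()
        profiles.append(GenePhenotypeProfile(
            g, tuple(zip(labels, map(float, freqs)))))
        phenos[g] = labels
    drugs = [f"d{i}" for i in range(int(rng.integers(1, 5)))]
    dgis = []
    for d in drugs:
        for g in genes:
            if rng.random() < 0.6:
                labels = phenos[g]
                size = int(rng.integers(1, len(labels) + 1))
                subset = rng.choice(labels, size=size, replace=False)
                dgis.append(DrugGeneInteraction(
                    d, g, frozenset(map(str, subset))))
    inhibitors = []
    if drugs and rng.random() < 0.4:
        g = genes[int(rng.integers(0, n_genes))]
        inhibitors.append(InhibitionRelation(
            drugs[int(rng.integers(0, len(drugs)))], g,
            phenos[g][int(rng.integers(0, len(phenos[g])))]))
    return KnowledgeBase(
        gene_profiles=tuple(profiles),
        drug_gene_interactions=tuple(dgis),
        drug_pair_interactions=(),
        inhibition_relations=tuple(inhibitors),
        panel=tuple(genes),
    ), set(drugs)


def ztnb_grid_mle_loglik(y: np.ndarray) -> float:
    """Intercept-only ZTNB maximum log-likelihood by two-stage lattice
    search over (log-mean, theta)."""
    def loglik(b0: float, theta: float) -> float:
        return float(np.sum(ztnb_log_pmf(y, np.exp(b0), theta)))

    b_grid = np.linspace(-1.0, 3.0, 81)
    t_grid = np.geomspace(0.1, 50.0, 81)
    best = max(((loglik(b, t), b, t) for b in b_grid for t in t_grid))
    _, b_best, t_best = best
    b_grid = np.linspace(b_best - 0.06, b_best + 0.06, 121)
    t_grid = np.geomspace(t_best * 0.85, t_best * 1.18, 121)
    best = max(((loglik(b, t), b, t) for b in b_grid for t in t_grid))
    b_best, t_best = best[1], best[2]
    b_grid = np.linspace(b_best - 0.002, b_best + 0.002, 81)
    t_grid = np.geomspace(t_best * 0.99, t_best * 1.01, 81)
    return max(loglik(b, t) for b in b_grid for t in t_grid)
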
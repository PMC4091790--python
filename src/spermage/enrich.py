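"""Disease-association enrichment of the age-affected gene set.

Compares the frequency of genes linked to each candidate disease within the
hit set (genes at regions of age-associated methylation change) against the
background of all genes carrying at least one disease association, by
Pearson chi-squared on the 2x2 table with Bonferroni correction over the
diseases tested. Diseases enter the test only when at least ``min_genes``
hit genes are associated with them. When any expected cell falls below 5
the test falls back to Fisher's exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationTable",
    "EnrichmentResult",
    "load_associations",
    "select_diseases",
    "enrichment_test",
    "run_enrichment",
]


@dataclass
class AssociationTable:
    """gene -> set of disease labels, plus the universe of associated genes."""

    associations: dict[str, set[str]]

    @property
    def universe(self) -> set[str]:
        return {g for g, ds in self.associations.items() if ds}

    def genes_with(self, disease: str) -> set[str]:
        return {g for g, ds in self.associations.items() if disease in ds}


def load_associations(pairs: pd.DataFrame) -> AssociationTable:
    """Build the table from a long-form (gene_id, disease) frame."""
    assoc: dict[str, set[str]] = {}
    for g, d in zip(pairs["gene_id"], pairs["disease"]):
        assoc.setdefault(str(g), set()).add(str(d))
    return AssociationTable(associations=assoc)


@dataclass
class EnrichmentResult:
    disease: str
    hits_with: int
    hits_total: int
    background_with: int
    background_total: int
    chi2: float
    p: float
    p_bonferroni: float
    test_used: str  # "chi2" or "fisher"


def select_diseases(
    hit_genes: set[str], table: AssociationTable, min_genes: int = 2
) -> list[str]:
    """Diseases associated with at least ``min_genes`` genes in the hit set."""
    counts: dict[str, int] = {}
    for g in hit_genes:
        for d in table.associations.get(g, ()):
            counts[d] = counts.get(d, 0) + 1
    return sorted(d for d, k in counts.items() if k >= min_genes)


def enrichment_test(
    disease: str,
    hit_genes: set[str],
    table: AssociationTable,
    n_tested: int = 1,
    background: set[str] | None = None,
) -> EnrichmentResult:
    """2x2 chi-squared of disease-association frequency, hits vs background.

    The default background is the universe of genes with >=1 association
    minus the hit set; in that case the hit margin is likewise restricted to
    hit genes inside the universe, so both margins are drawn from the same
    gene pool. Pass ``background`` to use e.g. a whole-genome set instead
    (hit genes then count whether or not they carry any association).
    Bonferroni multiplies p by ``n_tested`` (capped at 1).
    """
    with_disease = table.genes_with(disease)
    if not with_disease:
        raise ValueError(f"disease {disease!r} has no associations in the table")
    if background is None:
        background = table.universe - hit_genes
        hit_genes = hit_genes & table.universe
    hits_with = len(hit_genes & with_disease)
    bg_with = len(background & with_disease)
    hits_total = len(hit_genes)
    bg_total = len(background)
    tab = np.array(
        [
            [hits_with, hits_total - hits_with],
            [bg_with, bg_total - bg_with],
        ]
    )
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        logger.warning("enrichment_test: degenerate margin for %s; test skipped", disease)
        chi2, p, used = float("nan"), 1.0, "skipped"
    else:
        expected = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / tab.sum()
        chi2_v, chi2_p, _, _ = stats.chi2_contingency(tab, correction=False)
        chi2 = float(chi2_v)  # Pearson statistic always reported
        if expected.min() < 5:
            p = float(stats.fisher_exact(tab)[1])
            used = "fisher"
        else:
            p, used = float(chi2_p), "chi2"
    return EnrichmentResult(
        disease=disease,
        hits_with=hits_with,
        hits_total=hits_total,
        background_with=bg_with,
        background_total=bg_total,
        chi2=chi2,
        p=float(p),
        p_bonferroni=float(min(1.0, p * n_tested)),
        test_used=used,
    )


def run_enrichment(
    hit_genes: set[str],
    table: AssociationTable,
    min_genes: int = 2,
    background: set[str] | None = None,
) -> pd.DataFrame:
    """Select candidate diseases and test each, Bonferroni over those tested."""
    diseases = select_diseases(hit_genes, table, min_genes=min_genes)
    results = [
        enrichment_test(d, hit_genes, table, n_tested=len(diseases), background=background)
        for d in diseases
    ]
    return pd.DataFrame([r.__dict__ for r in results])
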
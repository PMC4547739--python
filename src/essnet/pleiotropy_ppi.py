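"""Disease pleiotropy and protein-interaction degree of disease genes.

A gene is pleiotropic when it is associated with two or more *canonical*
(subtype-merged) diseases, so numbered subtypes of one disorder never inflate
the count. Pleiotropy frequency is compared between essential and
nonessential disease genes with Fisher's exact test; the number of distinct
protein-interaction partners is compared with the Mann-Whitney U test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .disease_network import Diseasome
from .essentiality import DiseaseGeneLabelSet
from .stats import GroupComparisonResult, fisher_exact_2x2, mann_whitney

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PleiotropyRecord:
    gene_id: str
    n_diseases: int

    @property
    def pleiotropic(self) -> bool:
        return self.n_diseases >= 2


def compute_pleiotropy(
    diseasome: Diseasome, labels: DiseaseGeneLabelSet
) -> list[PleiotropyRecord]:
    """Canonical-disease count per mapped disease gene."""
    counts: dict[str, int] = {}
    for disease in diseasome.diseases.values():
        for gene in disease.genes:
            counts[gene] = counts.get(gene, 0) + 1
    return [
        PleiotropyRecord(g, n)
        for g, n in sorted(counts.items())
        if g in labels.mapped
    ]


def compare_pleiotropy(
    records: list[PleiotropyRecord],
    labels: DiseaseGeneLabelSet,
    alternative: str = "two_sided",
) -> GroupComparisonResult:
    """Fisher's exact test on pleiotropic vs non-pleiotropic by essentiality.

    Table rows are essential / nonessential genes, columns pleiotropic /
    not pleiotropic.
    """
    a = sum(1 for r in records if r.gene_id in labels.essential and r.pleiotropic)
    b = sum(1 for r in records if r.gene_id in labels.essential and not r.pleiotropic)
    c = sum(1 for r in records if r.gene_id in labels.nonessential and r.pleiotropic)
    d = sum(
        1 for r in records if r.gene_id in labels.nonessential and not r.pleiotropic
    )
    return fisher_exact_2x2(a, b, c, d, alternative=alternative)


def clean_ppi_edges(edges: pd.DataFrame) -> tuple[pd.DataFrame, int, int]:
    """Drop self-loops and duplicate unordered pairs; report removal counts."""
    a = edges["protein_a"].astype(str)
    b = edges["protein_b"].astype(str)
    df = pd.DataFrame(
        {
            "protein_a": a.where(a <= b, b),
            "protein_b": b.where(a <= b, a),
        }
    )
    loops = df["protein_a"] == df["protein_b"]
    n_loops = int(loops.sum())
    df = df[~loops]
    n_before = len(df)
    df = df.drop_duplicates()
    n_dups = n_before - len(df)
    if n_loops or n_dups:
        logger.info("PPI cleaning: removed %d self-loops, %d duplicates", n_loops, n_dups)
    return df.reset_index(drop=True), n_loops, n_dups


def ppi_degree(
    edges: pd.DataFrame, genes: set[str]
) -> tuple[dict[str, int], set[str]]:
    """Distinct-partner degree for ``genes`` present in the cleaned graph.

    Returns (degree map, absent genes). Genes absent from the graph reflect
    assay coverage rather than biology and are excluded, never given degree 0.
    """
    cleaned, _, _ = clean_ppi_edges(edges)
    degree = (
        pd.concat([cleaned["protein_a"], cleaned["protein_b"]])
        .value_counts()
        .to_dict()
    )
    genes = set(map(str, genes))
    present = {g: int(degree[g]) for g in genes if g in degree}
    absent = genes - set(present)
    if absent:
        logger.info("%d genes absent from the PPI graph", len(absent))
    return present, absent


def compare_degrees(
    degrees: dict[str, int],
    labels: DiseaseGeneLabelSet,
    alternative: str = "two_sided",
) -> GroupComparisonResult:
    """Mann-Whitney U on PPI degree: essential vs nonessential disease genes."""
    a = [d for g, d in degrees.items() if g in labels.essential]
    b = [d for g, d in degrees.items() if g in labels.nonessential]
    return mann_whitney(a, b, alternative=alternative)


def pleiotropy_to_frame(records: list[PleiotropyRecord]) -> pd.DataFrame:
    rows = [(r.gene_id, r.n_diseases, r.pleiotropic) for r in records]
    return pd.DataFrame(rows, columns=["gene_id", "n_diseases", "pleiotropic"])
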
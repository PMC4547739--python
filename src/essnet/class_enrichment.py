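"""Per-class over-representation of essential and nonessential disease genes.

Each disease class is tested twice with an upper-tail hypergeometric test —
once for essential genes, once for nonessential genes — against the
background of all mapped disease genes. A class is called
``essential_enriched`` (``nonessential_enriched``) when the corresponding raw
p falls below alpha; raw p-values are used by default (a Benjamini-Hochberg
option is available but off by default).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import pandas as pd
from scipy.stats import hypergeom

from .disease_network import Diseasome
from .errors import InputError
from .essentiality import DiseaseGeneLabelSet

logger = logging.getLogger(__name__)

CALLS = ("essential_enriched", "nonessential_enriched", "neither")


@dataclass
class EnrichmentResult:
    disease_class: str
    n_class_genes: int
    n_class_essential: int
    n_background: int
    n_background_essential: int
    p_essential: float
    p_nonessential: float
    call: str = "neither"

    def to_dict(self) -> dict:
        return asdict(self)


def class_gene_sets(
    diseasome: Diseasome, labels: DiseaseGeneLabelSet
) -> dict[str, tuple[set[str], set[str]]]:
    """Mapped (essential, nonessential) gene sets per disease class.

    A gene belongs to a class if it is associated with at least one disease
    of that class; set semantics, so a gene counts once per class however
    many diseases of the class carry it, and a gene in diseases of several
    classes counts in each. Unmapped genes are excluded.
    """
    out: dict[str, tuple[set[str], set[str]]] = {}
    for d in diseasome.diseases.values():
        ess, non = out.setdefault(d.disease_class, (set(), set()))
        ess |= d.genes & labels.essential
        non |= d.genes & labels.nonessential
        out[d.disease_class] = (ess, non)
    return out


def hypergeometric_enrichment(k: int, n: int, K: int, M: int) -> float:
    """Upper-tail hypergeometric p: P(X >= k), X ~ Hypergeom(M, K, n).

    M = background size, K = background successes, n = class size (draw),
    k = in-class successes.
    """
    if not (0 <= k <= n <= M and k <= K <= M):
        raise InputError(
            f"inconsistent hypergeometric counts k={k}, n={n}, K={K}, M={M}"
        )
    if n - k > M - K:
        raise InputError(
            f"impossible counts: {n - k} failures drawn but only {M - K} exist"
        )
    return float(hypergeom.sf(k - 1, M, K, n))


def enrich_classes(
    diseasome: Diseasome,
    labels: DiseaseGeneLabelSet,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> list[EnrichmentResult]:
    """Run both enrichment directions for every nonempty class and call it."""
    sets = class_gene_sets(diseasome, labels)
    background = set()
    for ess, non in sets.values():
        background |= ess | non
    M = len(background)
    K = len(background & labels.essential)
    results = []
    for dclass in sorted(sets):
        ess, non = sets[dclass]
        n = len(ess) + len(non)
        if n == 0:
            logger.warning("class %r has no mapped genes; excluded", dclass)
            continue
        p_ess = hypergeometric_enrichment(len(ess), n, K, M)
        p_non = hypergeometric_enrichment(len(non), n, M - K, M)
        results.append(
            EnrichmentResult(
                disease_class=dclass,
                n_class_genes=n,
                n_class_essential=len(ess),
                n_background=M,
                n_background_essential=K,
                p_essential=p_ess,
                p_nonessential=p_non,
            )
        )
    if bh_correct and results:
        from statsmodels.stats.multitest import multipletests

        for attr in ("p_essential", "p_nonessential"):
            ps = [getattr(r, attr) for r in results]
            adj = multipletests(ps, method="fdr_bh")[1]
            for r, p in zip(results, adj):
                setattr(r, attr, float(p))
    return call_classes(results, alpha=alpha)


def call_classes(
    results: list[EnrichmentResult], alpha: float = 0.05
) -> list[EnrichmentResult]:
    """Set the enrichment call per class from the two raw p-values."""
    for r in results:
        ess_hit = r.p_essential < alpha
        non_hit = r.p_nonessential < alpha
        if ess_hit and non_hit:
            logger.warning(
                "class %r significant in both tails (p=%g/%g); smaller p wins",
                r.disease_class,
                r.p_essential,
                r.p_nonessential,
            )
            r.call = (
                "essential_enriched"
                if r.p_essential <= r.p_nonessential
                else "nonessential_enriched"
            )
        elif ess_hit:
            r.call = "essential_enriched"
        elif non_hit:
            r.call = "nonessential_enriched"
        else:
            r.call = "neither"
    return results


def enrichment_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])
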
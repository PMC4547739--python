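"""Gene-essentiality classification and cross-species label transfer.

A mouse gene is *essential* when its mutant phenotype annotation carries at
least one lethality/reproductive-failure term — developmental failure or death
before 50 days of life, operationalized as five phenotype-ontology terms:
embryonic lethality, prenatal lethality, postnatal survival lethality,
abnormal reproductive system morphology, abnormal reproductive system
physiology. Every other gene in the catalog (including genes with no
annotation at all) is nonessential.

Labels cross to human disease genes through a strictly one-to-one ortholog
map; disease genes without an ortholog are kept apart as *unmapped* and
excluded from every downstream essentiality analysis.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)

#: Phenotype-ontology terms whose presence makes a gene essential.
LETHAL_TERMS = frozenset(
    {
        "MP:0002080",  # embryonic lethality
        "MP:0002081",  # prenatal lethality
        "MP:0002082",  # postnatal survival lethality
        "MP:0002160",  # abnormal reproductive system morphology
        "MP:0001919",  # abnormal reproductive system physiology
    }
)

_TERM_RE = re.compile(r"^MP:\d{7}$")


def normalize_term(term: str) -> str:
    """Normalize a phenotype term id: trim and drop space after the colon.

    Published text sometimes prints ids as ``MP: 0002080``; exact matching is
    done on the canonical ``MP:0002080`` form.
    """
    return re.sub(r":\s+", ":", term.strip())


@dataclass(frozen=True)
class EssentialityLabel:
    gene_id: str
    label: str  # "essential" | "nonessential"
    triggering_terms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if (self.label == "essential") != bool(self.triggering_terms):
            raise ValueError(
                "label 'essential' iff triggering_terms nonempty "
                f"(gene {self.gene_id})"
            )


@dataclass(frozen=True)
class OrthologMap:
    """Strictly one-to-one mouse↔human ortholog pairs."""

    pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        mouse = [m for m, _ in self.pairs]
        human = [h for _, h in self.pairs]
        dup_mouse = sorted({m for m in mouse if mouse.count(m) > 1})
        dup_human = sorted({h for h in human if human.count(h) > 1})
        if dup_mouse or dup_human:
            raise InputError(
                "ortholog map is not one-to-one; duplicated mouse ids: "
                f"{dup_mouse[:10]}, duplicated human ids: {dup_human[:10]}"
            )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OrthologMap":
        mouse = df["mouse_gene_id"].astype(str)
        human = df["human_gene_id"].astype(str)
        dup_mouse = sorted(mouse[mouse.duplicated()].unique())
        dup_human = sorted(human[human.duplicated()].unique())
        if dup_mouse or dup_human:
            raise InputError(
                "ortholog table is not one-to-one; duplicated mouse ids: "
                f"{dup_mouse[:10]}, duplicated human ids: {dup_human[:10]}"
            )
        return cls(frozenset(zip(mouse, human)))

    def mouse_to_human(self) -> dict[str, str]:
        return {m: h for m, h in self.pairs}

    def human_to_mouse(self) -> dict[str, str]:
        return {h: m for m, h in self.pairs}


@dataclass(frozen=True)
class DiseaseGeneLabelSet:
    """Partition of the disease-gene universe by transferred essentiality."""

    essential: frozenset[str]
    nonessential: frozenset[str]
    unmapped: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if (
            self.essential & self.nonessential
            or self.essential & self.unmapped
            or self.nonessential & self.unmapped
        ):
            raise ValueError("label sets must be pairwise disjoint")

    @property
    def universe(self) -> frozenset[str]:
        return self.essential | self.nonessential | self.unmapped

    @property
    def mapped(self) -> frozenset[str]:
        return self.essential | self.nonessential

    def label_of(self, gene: str) -> str:
        if gene in self.essential:
            return "essential"
        if gene in self.nonessential:
            return "nonessential"
        if gene in self.unmapped:
            return "unmapped"
        raise KeyError(gene)


def classify_essentiality(
    annotations: pd.DataFrame,
    gene_universe: set[str] | None = None,
    lethal_terms: frozenset[str] = LETHAL_TERMS,
) -> dict[str, EssentialityLabel]:
    """Label every gene essential/nonessential from its phenotype terms.

    Parameters
    ----------
    annotations
        Table with columns ``gene_id`` and ``mp_term_id`` (one row per
        gene-term annotation). Malformed term ids are skipped row-wise with
        a logged count.
    gene_universe
        Genes that must receive a label even without annotations (they
        become nonessential). Defaults to the annotated genes only.
    lethal_terms
        Term ids that trigger the essential label; any single hit suffices.
    """
    universe: set[str] = set() if gene_universe is None else set(map(str, gene_universe))
    triggers: dict[str, set[str]] = {}
    n_malformed = 0
    if len(annotations) == 0 and universe:
        logger.warning("empty annotation table: all %d genes nonessential", len(universe))
    for gene, term in zip(
        annotations["gene_id"].astype(str), annotations["mp_term_id"].astype(str)
    ):
        term = normalize_term(term)
        if not _TERM_RE.match(term):
            n_malformed += 1
            continue
        universe.add(gene)
        if term in lethal_terms:
            triggers.setdefault(gene, set()).add(term)
    if n_malformed:
        logger.warning("skipped %d annotation rows with malformed term ids", n_malformed)
    labels = {}
    for gene in universe:
        hit = triggers.get(gene)
        if hit:
            labels[gene] = EssentialityLabel(gene, "essential", frozenset(hit))
        else:
            labels[gene] = EssentialityLabel(gene, "nonessential")
    return labels


def transfer_labels(
    labels: dict[str, EssentialityLabel],
    orthologs: OrthologMap,
    disease_genes: set[str],
) -> DiseaseGeneLabelSet:
    """Transfer mouse essentiality onto human disease genes via orthology.

    Each human disease gene with a mouse ortholog inherits the ortholog's
    label; the rest go to ``unmapped``. A human gene whose ortholog is absent
    from the label table is also unmapped (no evidence either way).
    """
    h2m = orthologs.human_to_mouse()
    essential, nonessential, unmapped = set(), set(), set()
    for gene in map(str, disease_genes):
        mouse = h2m.get(gene)
        if mouse is None or mouse not in labels:
            unmapped.add(gene)
        elif labels[mouse].label == "essential":
            essential.add(gene)
        else:
            nonessential.add(gene)
    return DiseaseGeneLabelSet(
        frozenset(essential), frozenset(nonessential), frozenset(unmapped)
    )


def labels_to_frame(labels: dict[str, EssentialityLabel]) -> pd.DataFrame:
    rows = [
        (lab.gene_id, lab.label, ";".join(sorted(lab.triggering_terms)))
        for lab in sorted(labels.values(), key=lambda l: l.gene_id)
    ]
    return pd.DataFrame(rows, columns=["gene_id", "label", "triggering_terms"])


def disease_labels_to_frame(label_set: DiseaseGeneLabelSet) -> pd.DataFrame:
    rows = [(g, label_set.label_of(g)) for g in sorted(label_set.universe)]
    return pd.DataFrame(rows, columns=["gene_id", "label"])
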
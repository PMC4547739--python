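"""The human disease network (HDN): subtype merging, links, triangle motifs.

Diseases are nodes; an undirected link connects two diseases whenever their
gene sets intersect. Each link is classified by the transferred essentiality
of the shared genes: *essential* when every classified shared gene is
essential, *nonessential* symmetrically, *other* when both kinds occur, and
*unclassified* when every shared gene lacks an ortholog. Triangles — the
smallest complete subgraph — are the unit of modularity: a triangle whose
three links are all essential (all nonessential) indicates an essential
(nonessential) disease cluster, and the observed motif fractions are compared
against a null in which essentiality labels are shuffled uniformly across the
mapped disease genes on the fixed network topology.
"""

from __future__ import annotations

import logging
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._rng import substream
from .errors import InputError
from .essentiality import DiseaseGeneLabelSet

logger = logging.getLogger(__name__)

LINK_CLASSES = ("essential", "nonessential", "other", "unclassified")
MOTIF_CLASSES = ("all_essential", "all_nonessential", "mixed")

# trailing subtype token: ", 3" or ", type ii" / ", type 2"
_SUBTYPE_RE = re.compile(r",\s*(?:\d+|type\s+[0-9a-z]+)\s*$")


def canonicalize_name(raw_name: str) -> str:
    """Canonical disease name: lowercase, trimmed, trailing subtype stripped."""
    name = " ".join(raw_name.strip().lower().split())
    return _SUBTYPE_RE.sub("", name).strip()


@dataclass
class Disease:
    disease_id: str
    name: str
    disease_class: str
    genes: set[str]
    raw_names: set[str] = field(default_factory=set)


@dataclass
class Diseasome:
    """Canonical diseases after subtype merging, keyed by canonical name."""

    diseases: dict[str, Disease]

    def __len__(self) -> int:
        return len(self.diseases)

    @property
    def gene_universe(self) -> set[str]:
        out: set[str] = set()
        for d in self.diseases.values():
            out |= d.genes
        return out

    def classes(self) -> dict[str, str]:
        return {k: d.disease_class for k, d in self.diseases.items()}


@dataclass(frozen=True)
class HDNEdge:
    disease_a: str
    disease_b: str
    shared_genes: frozenset[str]
    link_class: str | None = None

    @property
    def pair(self) -> tuple[str, str]:
        return (self.disease_a, self.disease_b)


@dataclass(frozen=True)
class TriangleMotif:
    nodes: tuple[str, str, str]
    edge_classes: tuple[str, str, str]
    motif_class: str


@dataclass
class MotifNullResult:
    observed_fractions: dict[str, float]
    null_fractions: list[dict[str, float]]
    n_permutations: int
    empirical_p: dict[str, float]
    seed: int
    n_triangles: int
    n_excluded_triangles: int


def merge_subtypes(morbidmap: pd.DataFrame) -> Diseasome:
    """Merge disease subtypes into canonical diseases by name string match.

    Rows whose raw names canonicalize identically merge into one disease with
    the union gene set. Class conflicts resolve to the majority class with a
    deterministic lexicographic tie-break (logged). Rows with an empty
    disease name or gene id are skipped and counted.
    """
    genes: dict[str, set[str]] = defaultdict(set)
    raw_names: dict[str, set[str]] = defaultdict(set)
    class_votes: dict[str, Counter] = defaultdict(Counter)
    n_skipped = 0
    for raw_name, gene, dclass in zip(
        morbidmap["raw_disease_name"].astype(str),
        morbidmap["gene_id"].astype(str),
        morbidmap["disease_class"].astype(str),
    ):
        if not raw_name.strip() or not gene.strip():
            n_skipped += 1
            continue
        canon = canonicalize_name(raw_name)
        if not canon:
            n_skipped += 1
            continue
        genes[canon].add(gene)
        raw_names[canon].add(raw_name)
        class_votes[canon][dclass] += 1
    if n_skipped:
        logger.warning("merge_subtypes: skipped %d malformed rows", n_skipped)
    diseases: dict[str, Disease] = {}
    for canon in sorted(genes):
        votes = class_votes[canon]
        best = max(votes.values())
        winners = sorted(c for c, v in votes.items() if v == best)
        if len(votes) > 1:
            logger.info(
                "class conflict for %r: %s -> %s", canon, dict(votes), winners[0]
            )
        diseases[canon] = Disease(
            disease_id=canon,
            name=canon,
            disease_class=winners[0],
            genes=set(genes[canon]),
            raw_names=set(raw_names[canon]),
        )
    return Diseasome(diseases)


def build_hdn(diseasome: Diseasome) -> list[HDNEdge]:
    """One edge per unordered disease pair sharing at least one gene."""
    if not diseasome.diseases:
        raise InputError("empty diseasome")
    by_gene: dict[str, list[str]] = defaultdict(list)
    for key in sorted(diseasome.diseases):
        for g in diseasome.diseases[key].genes:
            by_gene[g].append(key)
    shared: dict[tuple[str, str], set[str]] = defaultdict(set)
    for gene, ds in by_gene.items():
        for i in range(len(ds)):
            for j in range(i + 1, len(ds)):
                shared[(ds[i], ds[j])].add(gene)
    return [
        HDNEdge(a, b, frozenset(gs)) for (a, b), gs in sorted(shared.items())
    ]


def _classify_shared(shared: frozenset[str], labels: DiseaseGeneLabelSet) -> str:
    n_ess = len(shared & labels.essential)
    n_non = len(shared & labels.nonessential)
    if n_ess and n_non:
        return "other"
    if n_ess:
        return "essential"
    if n_non:
        return "nonessential"
    return "unclassified"


def classify_links(
    edges: list[HDNEdge], labels: DiseaseGeneLabelSet
) -> list[HDNEdge]:
    """Assign each edge its essentiality link class (unmapped genes ignored)."""
    return [
        HDNEdge(e.disease_a, e.disease_b, e.shared_genes,
                _classify_shared(e.shared_genes, labels))
        for e in edges
    ]


def enumerate_triangles(edges: list[HDNEdge]) -> list[tuple[str, str, str]]:
    """All node triples with all three edges present, each reported once."""
    adj: dict[str, set[str]] = defaultdict(set)
    for e in edges:
        if e.disease_a == e.disease_b:
            raise InputError(f"self-edge on {e.disease_a}")
        adj[e.disease_a].add(e.disease_b)
        adj[e.disease_b].add(e.disease_a)
    triangles = []
    for e in edges:
        u, v = sorted(e.pair)
        for w in sorted(adj[u] & adj[v]):
            if w > v:
                triangles.append((u, v, w))
    return sorted(triangles)


def _motif_class(edge_classes: tuple[str, str, str]) -> str:
    if all(c == "essential" for c in edge_classes):
        return "all_essential"
    if all(c == "nonessential" for c in edge_classes):
        return "all_nonessential"
    return "mixed"


def classify_triangles(
    triangles: list[tuple[str, str, str]], edges: list[HDNEdge]
) -> list[TriangleMotif]:
    cls = {tuple(sorted(e.pair)): e.link_class for e in edges}
    out = []
    for (u, v, w) in triangles:
        ec = (cls[(u, v)], cls[(u, w)], cls[(v, w)])
        if any(c is None for c in ec):
            raise InputError("triangle references an unclassified-edge list")
        out.append(TriangleMotif((u, v, w), ec, _motif_class(ec)))
    return out


def motif_fractions(
    motifs: list[TriangleMotif],
) -> tuple[dict[str, float], int]:
    """Motif-class fractions over triangles with no unclassified edge.

    Returns (fractions, n_excluded). Triangles containing an unclassified
    edge carry no evidence and are excluded from the denominator.
    """
    eligible = [m for m in motifs if "unclassified" not in m.edge_classes]
    n_excluded = len(motifs) - len(eligible)
    if not eligible:
        raise InputError(
            "motif fractions undefined: no triangle has fully classified edges"
        )
    counts = Counter(m.motif_class for m in eligible)
    n = len(eligible)
    return {c: counts.get(c, 0) / n for c in MOTIF_CLASSES}, n_excluded


def mixed_breakdown(motifs: list[TriangleMotif]) -> dict[str, int]:
    """Optional finer split of mixed triangles.

    ``pure_mix``: every edge essential or nonessential but both kinds occur;
    ``contains_other``: at least one edge is itself of mixed gene content.
    """
    out = {"pure_mix": 0, "contains_other": 0}
    for m in motifs:
        if m.motif_class != "mixed" or "unclassified" in m.edge_classes:
            continue
        if "other" in m.edge_classes:
            out["contains_other"] += 1
        else:
            out["pure_mix"] += 1
    return out


def _edge_incidence(
    edges: list[HDNEdge], mapped_genes: list[str]
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Sparse edge×gene incidence over mapped genes + per-edge mapped-gene counts."""
    index = {g: i for i, g in enumerate(mapped_genes)}
    rows, cols = [], []
    for i, e in enumerate(edges):
        for g in e.shared_genes:
            j = index.get(g)
            if j is not None:
                rows.append(i)
                cols.append(j)
    mat = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)),
        shape=(len(edges), len(mapped_genes)),
    )
    totals = np.asarray(mat.sum(axis=1)).ravel()
    return mat, totals


_EDGE_CODE = {"unclassified": -1, "nonessential": 0, "other": 1, "essential": 2}


def _triangle_fractions_from_codes(
    tri_edge_idx: np.ndarray, edge_codes: np.ndarray
) -> dict[str, float] | None:
    """Motif fractions given per-edge class codes; None if no eligible triangle."""
    tc = edge_codes[tri_edge_idx]  # (n_triangles, 3)
    eligible = (tc >= 0).all(axis=1)
    n = int(eligible.sum())
    if n == 0:
        return None
    tc = tc[eligible]
    all_ess = (tc == 2).all(axis=1).sum()
    all_non = (tc == 0).all(axis=1).sum()
    return {
        "all_essential": all_ess / n,
        "all_nonessential": all_non / n,
        "mixed": (n - all_ess - all_non) / n,
    }


def permutation_null(
    diseasome: Diseasome,
    labels: DiseaseGeneLabelSet,
    n_permutations: int = 1000,
    seed: int = 0,
) -> MotifNullResult:
    """Permutation null for motif fractions under label shuffling.

    Essential/nonessential labels are shuffled uniformly at random across the
    mapped disease genes (exactly preserving the label counts); the network
    topology is fixed, links and triangles are re-classified, and the
    empirical upper-tail p for each motif class is
    ``(1 + #{null >= observed}) / (n_permutations + 1)``.
    """
    if n_permutations < 1:
        raise InputError("n_permutations must be >= 1")
    mapped = sorted(labels.mapped & diseasome.gene_universe)
    n_ess = len(set(mapped) & set(labels.essential))
    if n_ess == 0 or n_ess == len(mapped):
        raise InputError(
            "permutation null needs both labels among mapped disease genes "
            f"(got {n_ess} essential of {len(mapped)})"
        )
    edges = build_hdn(diseasome)
    triangles = enumerate_triangles(edges)
    if not triangles:
        raise InputError("no triangles in the disease network")
    edge_index = {tuple(sorted(e.pair)): i for i, e in enumerate(edges)}
    tri_edge_idx = np.array(
        [
            (edge_index[(u, v)], edge_index[(u, w)], edge_index[(v, w)])
            for (u, v, w) in triangles
        ]
    )
    incidence, totals = _edge_incidence(edges, mapped)
    label_vec = np.array([g in labels.essential for g in mapped], dtype=float)

    def codes(vec: np.ndarray) -> np.ndarray:
        ess_counts = incidence @ vec
        code = np.full(len(edges), 1, dtype=np.int8)  # other
        code[totals == 0] = -1  # unclassified
        classified = totals > 0
        code[classified & (ess_counts == totals)] = 2  # essential
        code[classified & (ess_counts == 0)] = 0  # nonessential
        return code

    observed = _triangle_fractions_from_codes(tri_edge_idx, codes(label_vec))
    if observed is None:
        raise InputError(
            "motif fractions undefined: no triangle has fully classified edges"
        )
    rng = substream(seed, "motif_permutation_null")
    null_fracs: list[dict[str, float]] = []
    exceed = dict.fromkeys(MOTIF_CLASSES, 0)
    for _ in range(n_permutations):
        perm = rng.permutation(label_vec)
        frac = _triangle_fractions_from_codes(tri_edge_idx, codes(perm))
        # eligibility is label-independent, so frac is never None here
        null_fracs.append(frac)
        for c in MOTIF_CLASSES:
            if frac[c] >= observed[c]:
                exceed[c] += 1
    empirical_p = {
        c: (1 + exceed[c]) / (n_permutations + 1) for c in MOTIF_CLASSES
    }
    motifs = classify_triangles(triangles, classify_links(edges, labels))
    _, n_excluded = motif_fractions(motifs)
    return MotifNullResult(
        observed_fractions=observed,
        null_fractions=null_fracs,
        n_permutations=n_permutations,
        empirical_p=empirical_p,
        seed=seed,
        n_triangles=len(triangles),
        n_excluded_triangles=n_excluded,
    )


def edges_to_frame(edges: list[HDNEdge]) -> pd.DataFrame:
    rows = [
        (
            e.disease_a,
            e.disease_b,
            e.link_class if e.link_class is not None else "",
            ";".join(sorted(e.shared_genes)),
        )
        for e in edges
    ]
    return pd.DataFrame(
        rows, columns=["disease_a", "disease_b", "link_class", "shared_genes"]
    )


def triangles_to_frame(motifs: list[TriangleMotif]) -> pd.DataFrame:
    rows = [
        (m.nodes[0], m.nodes[1], m.nodes[2], m.motif_class) for m in motifs
    ]
    return pd.DataFrame(
        rows, columns=["disease_a", "disease_b", "disease_c", "motif_class"]
    )


def to_networkx(diseasome: Diseasome, edges: list[HDNEdge]):
    """Export the HDN as a networkx Graph (for GraphML / external viewers)."""
    import networkx as nx

    g = nx.Graph()
    for key, d in diseasome.diseases.items():
        g.add_node(key, disease_class=d.disease_class, n_genes=len(d.genes))
    for e in edges:
        g.add_edge(
            e.disease_a,
            e.disease_b,
            link_class=e.link_class or "",
            n_shared=len(e.shared_genes),
        )
    return g
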
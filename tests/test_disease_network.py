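"""Subtype merging, HDN construction, triangle motifs and the permutation null."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from essnet.disease_network import (
    Disease,
    Diseasome,
    build_hdn,
    canonicalize_name,
    classify_links,
    classify_triangles,
    enumerate_triangles,
    merge_subtypes,
    mixed_breakdown,
    motif_fractions,
    permutation_null,
)
from essnet.errors import InputError
from essnet.essentiality import DiseaseGeneLabelSet

from oracles import triangles_brute_force


def morbidmap(rows):
    return pd.DataFrame(
        rows, columns=["raw_disease_name", "disease_id", "gene_id", "disease_class"]
    )


def make_diseasome(gene_sets: dict[str, set], dclass="c") -> Diseasome:
    return Diseasome(
        {k: Disease(k, k, dclass, set(v)) for k, v in gene_sets.items()}
    )


class TestMerge:
    @pytest.mark.parametrize(
        "raw,canonical",
        [
            ("Breast cancer, 1", "breast cancer"),
            ("Breast cancer, 2", "breast cancer"),
            ("  Deafness, type II ", "deafness"),
            ("Retinitis pigmentosa", "retinitis pigmentosa"),
            ("Diabetes, type 2", "diabetes"),
            ("Charcot-Marie-Tooth disease", "charcot-marie-tooth disease"),
        ],
    )
    def test_canonicalization_rule(self, raw, canonical):
        assert canonicalize_name(raw) == canonical

    def test_subtypes_merge_to_union_gene_set(self):
        dz = merge_subtypes(
            morbidmap(
                [
                    ("Breast cancer, 1", "D1.1", "g1", "cancer"),
                    ("Breast cancer, 2", "D1.2", "g2", "cancer"),
                ]
            )
        )
        assert len(dz) == 1
        assert dz.diseases["breast cancer"].genes == {"g1", "g2"}

    def test_identical_names_merge(self):
        dz = merge_subtypes(
            morbidmap([("Asthma", "D1", "g1", "resp"), ("Asthma", "D1", "g2", "resp")])
        )
        assert len(dz) == 1

    def test_class_conflict_majority_with_lexicographic_tiebreak(self):
        dz = merge_subtypes(
            morbidmap(
                [
                    ("X, 1", "D1", "g1", "cancer"),
                    ("X, 2", "D2", "g2", "bone"),
                ]
            )
        )
        assert dz.diseases["x"].disease_class == "bone"  # tie -> lexicographic

    def test_empty_rows_skipped(self):
        dz = merge_subtypes(
            morbidmap([("", "D1", "g1", "c"), ("Y", "D2", "", "c"), ("Y", "D2", "g", "c")])
        )
        assert len(dz) == 1

    def test_zero_subtype_rate_is_identity(self):
        from essnet import SimulationConfig
        from essnet.synthetic import generate_diseasome, generate_gene_catalog

        cfg = SimulationConfig(seed=5, n_mouse_genes=300, n_diseases=30,
                               n_patients=1000, subtype_rate=0.0,
                               n_rr_pairs=0, ppi_n_proteins=400)
        _, _, gene_truth = generate_gene_catalog(cfg)
        mm, _ = generate_diseasome(cfg, gene_truth)
        assert not mm["raw_disease_name"].str.contains(",").any()
        dz = merge_subtypes(mm)
        assert len(dz) == mm["raw_disease_name"].str.lower().nunique()

    def test_merged_count_matches_generator_truth(self, small_dataset):
        dz = merge_subtypes(small_dataset.morbidmap)
        truth = small_dataset.truth["diseasome"]
        assert len(dz) == truth["n_canonical_diseases"]
        for key, rec in truth["diseases"].items():
            assert dz.diseases[key].genes == set(rec["genes"])
            assert dz.diseases[key].disease_class == rec["disease_class"]


class TestHDN:
    def test_single_shared_gene_single_edge(self):
        dz = make_diseasome({"D1": {"g1", "g2"}, "D2": {"g2"}, "D3": {"g3"}})
        edges = build_hdn(dz)
        assert len(edges) == 1
        assert edges[0].pair == ("D1", "D2")
        assert edges[0].shared_genes == {"g2"}

    def test_disjoint_gene_sets_give_empty_network(self):
        dz = make_diseasome({"D1": {"a"}, "D2": {"b"}, "D3": {"c"}})
        assert build_hdn(dz) == []

    def test_common_gene_gives_complete_graph(self):
        n = 7
        dz = make_diseasome({f"D{i}": {"g", f"x{i}"} for i in range(n)})
        edges = build_hdn(dz)
        assert len(edges) == n * (n - 1) // 2  # brute force over all pairs

    @pytest.mark.parametrize(
        "shared,expected",
        [
            ({"e1", "e2"}, "essential"),
            ({"n1", "n2"}, "nonessential"),
            ({"e1", "n1"}, "other"),
            ({"u1"}, "unclassified"),
            ({"e1", "u1"}, "essential"),  # unmapped genes carry no evidence
        ],
    )
    def test_link_classification(self, shared, expected):
        labels = DiseaseGeneLabelSet(
            frozenset({"e1", "e2"}), frozenset({"n1", "n2"}), frozenset({"u1"})
        )
        dz = make_diseasome({"A": set(shared) | {"zz"}, "B": set(shared) | {"zy"}})
        edges = classify_links(build_hdn(dz), labels)
        assert edges[0].link_class == expected


class TestTriangles:
    def test_k3_has_one_triangle(self):
        dz = make_diseasome({"A": {"g1", "g3"}, "B": {"g1", "g2"}, "C": {"g2", "g3"}})
        assert enumerate_triangles(build_hdn(dz)) == [("A", "B", "C")]

    def test_path_has_no_triangles(self):
        dz = make_diseasome(
            {"A": {"g1"}, "B": {"g1", "g2"}, "C": {"g2", "g3"}, "D": {"g3"}}
        )
        assert enumerate_triangles(build_hdn(dz)) == []

    def test_k4_has_four_triangles(self):
        dz = make_diseasome({f"D{i}": {"g"} for i in range(4)})
        assert len(enumerate_triangles(build_hdn(dz))) == 4

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force_and_networkx(self, seed):
        """Triangle set equals C(n,3) brute force and networkx cliques."""
        import networkx as nx

        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        p = float(rng.uniform(0.05, 0.5))
        nodes = [f"v{i:02d}" for i in range(n)]
        pairs = [
            (nodes[i], nodes[j])
            for i in range(n)
            for j in range(i + 1, n)
            if rng.random() < p
        ]
        dz = make_diseasome(
            {v: {f"pair{k}" for k, e in enumerate(pairs) if v in e} | {f"self{v}"}
             for v in nodes}
        )
        edges = build_hdn(dz)
        got = set(enumerate_triangles(edges))
        assert got == triangles_brute_force(nodes, [e.pair for e in edges])
        g = nx.Graph([e.pair for e in edges])
        nx_tris = {
            tuple(sorted(c)) for c in nx.enumerate_all_cliques(g) if len(c) == 3
        }
        assert got == nx_tris


class TestMotifFractions:
    def make_classified(self, link_classes):
        """Triangle over A,B,C with the given three edge classes."""
        labels = DiseaseGeneLabelSet(
            frozenset({"e1", "e2", "e3"}),
            frozenset({"n1", "n2", "n3"}),
            frozenset({"u1"}),
        )
        gene_for = {
            "essential": iter(["e1", "e2", "e3"]),
            "nonessential": iter(["n1", "n2", "n3"]),
            "unclassified": iter(["u1"]),
        }
        sets = {"A": set(), "B": set(), "C": set()}
        for (x, y), cls in zip([("A", "B"), ("A", "C"), ("B", "C")], link_classes):
            g = next(gene_for[cls])
            sets[x].add(g)
            sets[y].add(g)
        dz = make_diseasome(sets)
        edges = classify_links(build_hdn(dz), labels)
        return classify_triangles(enumerate_triangles(edges), edges)

    def test_all_essential(self):
        motifs = self.make_classified(["essential"] * 3)
        fracs, excluded = motif_fractions(motifs)
        assert fracs == {"all_essential": 1.0, "all_nonessential": 0.0, "mixed": 0.0}
        assert excluded == 0

    def test_mixed_triangle(self):
        motifs = self.make_classified(["essential", "essential", "nonessential"])
        fracs, _ = motif_fractions(motifs)
        assert fracs["mixed"] == 1.0

    def test_unclassified_edge_excluded_from_denominator(self):
        motifs = self.make_classified(["essential", "essential", "unclassified"])
        with pytest.raises(InputError):
            motif_fractions(motifs)  # the only triangle is excluded

    def test_fractions_sum_to_one_on_random_graph(self, small_dataset):
        from essnet import (
            OrthologMap,
            classify_essentiality,
            merge_subtypes,
            transfer_labels,
        )

        dz = merge_subtypes(small_dataset.morbidmap)
        labels = transfer_labels(
            classify_essentiality(small_dataset.genes_phenotypes),
            OrthologMap.from_frame(small_dataset.orthologs),
            dz.gene_universe,
        )
        edges = classify_links(build_hdn(dz), labels)
        motifs = classify_triangles(enumerate_triangles(edges), edges)
        fracs, _ = motif_fractions(motifs)
        assert sum(fracs.values()) == pytest.approx(1.0)
        breakdown = mixed_breakdown(motifs)
        n_mixed = sum(
            1
            for m in motifs
            if m.motif_class == "mixed" and "unclassified" not in m.edge_classes
        )
        assert breakdown["pure_mix"] + breakdown["contains_other"] == n_mixed


class TestPermutationNull:
    def test_degenerate_all_essential_labels_rejected(self):
        dz = make_diseasome({"A": {"e1"}, "B": {"e1"}, "C": {"e1"}})
        labels = DiseaseGeneLabelSet(frozenset({"e1"}), frozenset())
        with pytest.raises(InputError):
            permutation_null(dz, labels, n_permutations=9, seed=0)

    def test_p_bounds_and_determinism(self):
        rng = np.random.default_rng(0)
        pool = [f"g{i}" for i in range(30)]
        dz = make_diseasome(
            {f"D{i}": set(rng.choice(pool, size=4, replace=False)) for i in range(25)}
        )
        labels = DiseaseGeneLabelSet(
            frozenset(pool[:15]), frozenset(pool[15:])
        )
        r1 = permutation_null(dz, labels, n_permutations=99, seed=4)
        r2 = permutation_null(dz, labels, n_permutations=99, seed=4)
        assert r1.empirical_p == r2.empirical_p
        assert r1.observed_fractions == r2.observed_fractions
        for p in r1.empirical_p.values():
            assert 1 / 100 <= p <= 1.0

    def test_planted_modularity_detected(self, small_dataset):
        """Strong class bias makes all-essential motifs exceed the null."""
        from essnet import (
            OrthologMap,
            classify_essentiality,
            merge_subtypes,
            transfer_labels,
        )

        dz = merge_subtypes(small_dataset.morbidmap)
        labels = transfer_labels(
            classify_essentiality(small_dataset.genes_phenotypes),
            OrthologMap.from_frame(small_dataset.orthologs),
            dz.gene_universe,
        )
        res = permutation_null(dz, labels, n_permutations=199, seed=2)
        assert res.empirical_p["all_essential"] <= 0.05

    def test_vectorized_path_matches_direct_classification(self):
        """The sparse-matrix edge recoding agrees with classify_links."""
        rng = np.random.default_rng(3)
        pool = [f"g{i}" for i in range(40)]
        dz = make_diseasome(
            {f"D{i}": set(rng.choice(pool, size=5, replace=False)) for i in range(20)}
        )
        labels = DiseaseGeneLabelSet(
            frozenset(pool[:18]), frozenset(pool[18:36]), frozenset(pool[36:])
        )
        edges = classify_links(build_hdn(dz), labels)
        motifs = classify_triangles(enumerate_triangles(edges), edges)
        fracs, _ = motif_fractions(motifs)
        res = permutation_null(dz, labels, n_permutations=5, seed=0)
        for k, v in fracs.items():
            assert res.observed_fractions[k] == pytest.approx(v)
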
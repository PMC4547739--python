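"""Synthetic-data generator: determinism, contracts and planted structure."""

import numpy as np
import pandas as pd
import pytest

from essnet import SimulationConfig, generate, summarize_claims
from essnet.comorbidity import relative_risk
from essnet.config import class_names
from essnet.errors import ConfigError, GenerationError
from essnet.essentiality import LETHAL_TERMS
from essnet.synthetic import (
    generate_claims,
    generate_diseasome,
    generate_gene_catalog,
)
from essnet import io


def tiny(**kw) -> SimulationConfig:
    base = dict(
        seed=1,
        n_mouse_genes=300,
        n_diseases=30,
        n_patients=2000,
        n_rr_pairs=3,
        ppi_n_proteins=400,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestConfig:
    def test_bias_outside_unit_interval_rejected(self):
        with pytest.raises(ConfigError):
            tiny(class_essential_bias=(0.9, 0.8, 1.5, 0.2, 0.1))

    def test_bias_length_must_match_classes(self):
        with pytest.raises(ConfigError):
            tiny(n_classes=3)

    def test_rr_below_one_rejected(self):
        with pytest.raises(ConfigError):
            tiny(planted_rr=0.5)

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ConfigError):
            tiny(n_patients=0)

    def test_class_names_extend_past_pool(self):
        names = class_names(23)
        assert len(names) == len(set(names)) == 23

    def test_unknown_keys_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig.from_dict({"n_mouse_genez": 10})


class TestGeneCatalog:
    def test_deterministic_mode_exact_essential_count(self):
        cfg = tiny(essential_fraction=0.15, n_mouse_genes=1000)
        _, _, truth = generate_gene_catalog(cfg)
        assert truth["n_mouse_essential"] == 150

    def test_stochastic_mode_within_binomial_error(self):
        cfg = tiny(
            essential_fraction=0.15,
            n_mouse_genes=1000,
            deterministic_essential_assignment=False,
        )
        _, _, truth = generate_gene_catalog(cfg)
        sd = np.sqrt(1000 * 0.15 * 0.85)
        assert abs(truth["n_mouse_essential"] - 150) < 5 * sd

    def test_zero_essential_fraction_no_lethal_terms(self):
        cfg = tiny(essential_fraction=0.0)
        annotations, _, truth = generate_gene_catalog(cfg)
        assert truth["n_mouse_essential"] == 0
        assert not annotations["mp_term_id"].isin(LETHAL_TERMS).any()

    def test_every_gene_annotated(self):
        annotations, _, _ = generate_gene_catalog(tiny())
        assert annotations["gene_id"].nunique() == 300

    def test_ortholog_table_strictly_one_to_one(self):
        _, orthologs, _ = generate_gene_catalog(tiny())
        assert not orthologs["mouse_gene_id"].duplicated().any()
        assert not orthologs["human_gene_id"].duplicated().any()
        assert len(orthologs) == int(0.8 * 300)


class TestDiseasome:
    def test_every_disease_has_genes_and_one_class(self):
        cfg = tiny()
        _, _, gene_truth = generate_gene_catalog(cfg)
        mm, truth = generate_diseasome(cfg, gene_truth)
        assert len(truth["diseases"]) == 30
        for rec in truth["diseases"].values():
            assert len(rec["genes"]) >= 1

    def test_subtyped_diseases_emit_multiple_rows(self):
        cfg = tiny(subtype_rate=1.0)
        _, _, gene_truth = generate_gene_catalog(cfg)
        mm, truth = generate_diseasome(cfg, gene_truth)
        assert mm["raw_disease_name"].str.contains(r", \d+$").all()
        for rec in truth["diseases"].values():
            assert rec["n_subtypes"] >= 2


class TestClaims:
    def test_zero_patients_rejected_at_generation(self):
        cfg = tiny()
        object.__setattr__(cfg, "n_patients", 0)
        with pytest.raises(GenerationError):
            generate_claims(cfg, {"d1": {"disease_class": "cancer", "genes": ["g"]}})

    def test_infeasible_rr_names_the_pair(self):
        cfg = tiny(baseline_prevalence=0.3, planted_rr=4.0)
        _, _, gene_truth = generate_gene_catalog(cfg)
        _, truth = generate_diseasome(cfg, gene_truth)
        with pytest.raises(GenerationError, match="disease"):
            generate_claims(cfg, truth["diseases"])

    def test_unplanted_rr_near_one(self):
        """With no designated pairs every RR converges to 1.

        The disease panel is kept large enough that virtually every patient
        carries at least one diagnosis: a claims table only observes
        diagnosed patients, so a tiny panel would undercount N.
        """
        cfg = tiny(n_rr_pairs=0, n_patients=30_000, n_diseases=100)
        ds = generate(cfg)
        s = summarize_claims(ds.claims)
        rrs = [
            relative_risk(c, s.incidence[a], s.incidence[b], s.n_patients).rr
            for (a, b), c in s.cooccurrence.items()
        ]
        assert np.mean(rrs) == pytest.approx(1.0, abs=0.05)

    def test_planted_rr_recovered_within_ten_percent(self):
        cfg = SimulationConfig(
            seed=9, n_mouse_genes=400, n_diseases=100, n_patients=100_000,
            n_rr_pairs=5, ppi_n_proteins=600,
        )
        ds = generate(cfg)
        s = summarize_claims(ds.claims)
        rrs = []
        for a, b in ds.truth["claims"]["designated_pairs"]:
            rrs.append(
                relative_risk(s.c_ij(a, b), s.incidence[a], s.incidence[b],
                              s.n_patients).rr
            )
        assert np.mean(rrs) == pytest.approx(4.0, rel=0.10)

    def test_error_shrinks_with_sample_size(self):
        """Planted-parameter recovery improves monotonically with N."""
        errs = []
        for n in (2_000, 50_000):
            cfg = SimulationConfig(
                seed=13, n_mouse_genes=400, n_diseases=100, n_patients=n,
                n_rr_pairs=5, ppi_n_proteins=600,
            )
            ds = generate(cfg)
            s = summarize_claims(ds.claims)
            rrs = [
                relative_risk(s.c_ij(a, b), s.incidence[a], s.incidence[b],
                              s.n_patients).rr
                for a, b in ds.truth["claims"]["designated_pairs"]
            ]
            errs.append(abs(float(np.mean(rrs)) - 4.0))
        assert errs[1] < errs[0]


class TestPPI:
    def test_simple_graph_invariants(self, small_dataset):
        ppi = small_dataset.ppi
        assert not (ppi["protein_a"] == ppi["protein_b"]).any()
        key = ppi.apply(lambda r: tuple(sorted(r)), axis=1)
        assert not key.duplicated().any()

    def test_mean_degree_near_target(self, small_config, small_dataset):
        degrees = pd.concat(
            [small_dataset.ppi["protein_a"], small_dataset.ppi["protein_b"]]
        ).value_counts()
        mean_deg = 2 * len(small_dataset.ppi) / small_config.ppi_n_proteins
        assert mean_deg == pytest.approx(small_config.ppi_mean_degree, rel=0.25)

    def test_mean_degree_too_large_rejected(self):
        with pytest.raises(ConfigError):
            tiny(ppi_mean_degree=500, ppi_n_proteins=400)


class TestDeterminismAndRoundTrip:
    def test_identical_seed_and_config_byte_identical(self, tmp_path):
        cfg = tiny()
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate(cfg).write(d1)
        generate(cfg).write(d2)
        files = sorted(p.name for p in d1.iterdir())
        assert files
        for name in files:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_different_seeds_differ(self, tmp_path):
        a = generate(tiny(seed=1)).morbidmap
        b = generate(tiny(seed=2)).morbidmap
        assert not a.equals(b)

    def test_tables_round_trip_through_readers(self, tmp_path):
        ds = generate(tiny())
        paths = ds.write(tmp_path)
        readers = {
            "genes_phenotypes": io.read_genes_phenotypes,
            "orthologs": io.read_orthologs,
            "morbidmap": io.read_morbidmap,
            "claims": io.read_claims,
            "ppi": io.read_ppi,
        }
        for name, reader in readers.items():
            back = reader(paths[name])
            orig = getattr(ds, name).astype(str).reset_index(drop=True)
            pd.testing.assert_frame_equal(back, orig)
        cf = io.read_case_fatality(paths["case_fatality"])
        pd.testing.assert_frame_equal(
            cf, ds.case_fatality.reset_index(drop=True), check_dtype=False
        )
        cd = io.read_crude_death(paths["crude_death"])
        pd.testing.assert_frame_equal(
            cd, ds.crude_death.reset_index(drop=True), check_dtype=False
        )
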
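"""End-to-end orchestration: simulate (or load) inputs, run every stage,
write a machine-readable results bundle.

Stage order follows the analysis: essentiality transfer → disease network and
motif null → class enrichment → severity → comorbidity → pleiotropy / PPI
degree. Stages whose optional inputs (claims, case fatality, PPI) are absent
are skipped with an explicit log entry. All randomness flows from the single
config seed; reruns with the same config produce byte-identical bundles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import (
    class_enrichment,
    comorbidity,
    disease_network,
    essentiality,
    io,
    pleiotropy_ppi,
    severity,
    synthetic,
)
from .config import PipelineConfig
from .errors import ConfigError

logger = logging.getLogger(__name__)


@dataclass
class ResultsBundle:
    """Output paths plus the in-memory stage results of one pipeline run."""

    output_dir: str
    outputs: dict[str, str] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)
    # in-memory objects for programmatic use
    labels: essentiality.DiseaseGeneLabelSet | None = None
    diseasome: disease_network.Diseasome | None = None
    motif_null: disease_network.MotifNullResult | None = None
    enrichment: list | None = None
    comparisons: dict = field(default_factory=dict)
    partner_counts: dict | None = None
    truth: dict | None = None


def _load_inputs(config: PipelineConfig, outdir: Path) -> tuple[dict, dict | None]:
    """Return table map (pandas frames) and truth (for simulated runs)."""
    tables: dict[str, pd.DataFrame] = {}
    truth = None
    if config.simulate is not None:
        dataset = synthetic.generate(config.simulate)
        paths = dataset.write(outdir / "inputs")
        logger.info("simulated inputs written to %s", outdir / "inputs")
        tables = {
            "genes_phenotypes": dataset.genes_phenotypes,
            "orthologs": dataset.orthologs,
            "morbidmap": dataset.morbidmap,
            "claims": dataset.claims,
            "case_fatality": dataset.case_fatality,
            "crude_death": dataset.crude_death,
            "ppi": dataset.ppi,
        }
        truth = dataset.truth
        return tables, truth
    readers = {
        "genes_phenotypes": io.read_genes_phenotypes,
        "orthologs": io.read_orthologs,
        "morbidmap": io.read_morbidmap,
        "claims": io.read_claims,
        "case_fatality": io.read_case_fatality,
        "crude_death": io.read_crude_death,
        "ppi": io.read_ppi,
    }
    for key, path in config.inputs.items():
        tables[key] = readers[key](path)
    return tables, truth


def run_all(config: PipelineConfig, output_dir: str | Path | None = None) -> ResultsBundle:
    """Execute every stage; returns the bundle (files under ``output_dir``)."""
    outdir = Path(output_dir if output_dir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables, truth = _load_inputs(config, outdir)
    if "morbidmap" not in tables:
        raise ConfigError("morbidmap input is required")
    for required in ("genes_phenotypes", "orthologs"):
        if required not in tables:
            raise ConfigError(f"{required} input is required (or use a simulate block)")
    bundle = ResultsBundle(output_dir=str(outdir), truth=truth)

    # --- essentiality ---
    diseasome = disease_network.merge_subtypes(tables["morbidmap"])
    mouse_labels = essentiality.classify_essentiality(tables["genes_phenotypes"])
    orthomap = essentiality.OrthologMap.from_frame(tables["orthologs"])
    labels = essentiality.transfer_labels(
        mouse_labels, orthomap, diseasome.gene_universe
    )
    bundle.labels = labels
    bundle.diseasome = diseasome
    bundle.counts.update(
        n_mouse_genes=len(mouse_labels),
        n_mouse_essential=sum(
            1 for l in mouse_labels.values() if l.label == "essential"
        ),
        n_diseases=len(diseasome),
        n_disease_genes=len(labels.universe),
        n_essential_disease_genes=len(labels.essential),
        n_nonessential_disease_genes=len(labels.nonessential),
        n_unmapped_disease_genes=len(labels.unmapped),
    )
    path = outdir / "disease_gene_labels.tsv"
    io.write_tsv(essentiality.disease_labels_to_frame(labels), path)
    bundle.outputs["disease_gene_labels"] = str(path)
    logger.info(
        "essentiality: %d essential / %d nonessential / %d unmapped disease genes",
        len(labels.essential),
        len(labels.nonessential),
        len(labels.unmapped),
    )

    # --- disease network & motifs ---
    edges = disease_network.classify_links(disease_network.build_hdn(diseasome), labels)
    triangles = disease_network.enumerate_triangles(edges)
    motifs = disease_network.classify_triangles(triangles, edges)
    path = outdir / "hdn_edges.tsv"
    io.write_tsv(disease_network.edges_to_frame(edges), path)
    bundle.outputs["hdn_edges"] = str(path)
    path = outdir / "triangles.tsv"
    io.write_tsv(disease_network.triangles_to_frame(motifs), path)
    bundle.outputs["triangles"] = str(path)
    bundle.counts.update(n_hdn_edges=len(edges), n_triangles=len(triangles))
    null = disease_network.permutation_null(
        diseasome, labels, n_permutations=config.n_permutations, seed=config.seed
    )
    bundle.motif_null = null
    io.write_json(
        {
            "observed_fractions": null.observed_fractions,
            "empirical_p": null.empirical_p,
            "n_permutations": null.n_permutations,
            "seed": null.seed,
            "n_triangles": null.n_triangles,
            "n_excluded_triangles": null.n_excluded_triangles,
            "mixed_breakdown": disease_network.mixed_breakdown(motifs),
        },
        outdir / "motif_null.json",
    )
    bundle.outputs["motif_null"] = str(outdir / "motif_null.json")

    # --- class enrichment ---
    enrichment = class_enrichment.enrich_classes(diseasome, labels, alpha=config.alpha)
    bundle.enrichment = enrichment
    path = outdir / "class_enrichment.tsv"
    io.write_tsv(class_enrichment.enrichment_to_frame(enrichment), path)
    bundle.outputs["class_enrichment"] = str(path)

    # --- severity ---
    severity_out: dict = {}
    if "case_fatality" in tables:
        groups = severity.group_case_fatality(
            tables["case_fatality"], enrichment, diseasome
        )
        cmp = severity.compare_case_fatality(
            tables["case_fatality"], enrichment, diseasome,
            alternative=config.alternative,
        )
        bundle.comparisons["case_fatality"] = cmp
        severity_out["case_fatality_groups"] = groups
        severity_out["case_fatality_comparison"] = cmp.to_dict()
    else:
        bundle.skipped.append("severity: no case_fatality input")
        logger.info("severity stage skipped: no case_fatality input")
    if "crude_death" in tables:
        joined = severity.join_crude_death(enrichment, tables["crude_death"])
        severity_out["crude_death_by_class"] = joined.to_dict(orient="records")

    # --- comorbidity ---
    if "claims" in tables and len(tables["claims"]) > 0:
        summary = comorbidity.summarize_claims(tables["claims"])
        rr = comorbidity.rr_table(summary, threshold=config.rr_threshold)
        partner_counts = comorbidity.count_comorbid_partners(
            summary, threshold=config.rr_threshold
        )
        bundle.partner_counts = partner_counts
        path = outdir / "rr_pairs.tsv"
        io.write_tsv(comorbidity.rr_to_frame(rr), path)
        bundle.outputs["rr_pairs"] = str(path)
        path = outdir / "comorbid_counts.tsv"
        io.write_tsv(
            pd.DataFrame(
                sorted(partner_counts.items()),
                columns=["disease_id", "n_comorbid_partners"],
            ),
            path,
        )
        bundle.outputs["comorbid_counts"] = str(path)
        cmp = comorbidity.compare_comorbidity(
            partner_counts, enrichment, diseasome, alternative=config.alternative
        )
        bundle.comparisons["comorbidity"] = cmp
        io.write_json(
            {"comparison": cmp.to_dict(), "rr_threshold": config.rr_threshold},
            outdir / "comorbidity_comparison.json",
        )
        bundle.outputs["comorbidity_comparison"] = str(
            outdir / "comorbidity_comparison.json"
        )
        bias = severity.patient_count_bias_check(
            summary.incidence, enrichment, diseasome, alternative=config.alternative
        )
        bundle.comparisons["patient_count_bias"] = bias
        severity_out["patient_count_bias_check"] = bias.to_dict()
    else:
        bundle.skipped.append("comorbidity: no claims input")
        logger.info("comorbidity stage skipped: no claims input")
    if severity_out:
        io.write_json(severity_out, outdir / "severity_comparison.json")
        bundle.outputs["severity_comparison"] = str(outdir / "severity_comparison.json")

    # --- pleiotropy & PPI degree ---
    records = pleiotropy_ppi.compute_pleiotropy(diseasome, labels)
    path = outdir / "pleiotropy.tsv"
    io.write_tsv(pleiotropy_ppi.pleiotropy_to_frame(records), path)
    bundle.outputs["pleiotropy"] = str(path)
    cmp = pleiotropy_ppi.compare_pleiotropy(
        records, labels, alternative=config.alternative
    )
    bundle.comparisons["pleiotropy"] = cmp
    degree_out = {"pleiotropy_comparison": cmp.to_dict()}
    if "ppi" in tables:
        degrees, absent = pleiotropy_ppi.ppi_degree(
            tables["ppi"], set(labels.mapped)
        )
        cmp = pleiotropy_ppi.compare_degrees(
            degrees, labels, alternative=config.alternative
        )
        bundle.comparisons["ppi_degree"] = cmp
        degree_out["degree_comparison"] = cmp.to_dict()
        degree_out["n_genes_absent_from_ppi"] = len(absent)
    else:
        bundle.skipped.append("ppi_degree: no ppi input")
        logger.info("PPI degree comparison skipped: no ppi input")
    io.write_json(degree_out, outdir / "degree_comparison.json")
    bundle.outputs["degree_comparison"] = str(outdir / "degree_comparison.json")

    # --- manifest ---
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "outputs": {k: str(Path(v).name) for k, v in sorted(bundle.outputs.items())},
        "skipped": bundle.skipped,
        "counts": bundle.counts,
    }
    io.write_json(manifest, outdir / "manifest.json")
    bundle.outputs["manifest"] = str(outdir / "manifest.json")
    return bundle
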
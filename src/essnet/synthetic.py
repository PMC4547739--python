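"""Synthetic study population with planted, parameterized structure.

Every input table the pipeline consumes is generated here with a known ground
truth, so each downstream stage can be validated against what was planted:

* a mouse gene catalog with phenotype-term annotations in which a chosen
  fraction of genes carries lethal terms, and a strictly one-to-one ortholog
  map onto synthetic human gene ids;
* a morbid-map-style disease-gene table whose classes draw essential genes
  with per-class bias (the planted enrichment), a fraction of diseases being
  emitted as numbered subtypes so the merging step has work to do;
* per-patient diagnosis lists in which designated disjoint disease pairs
  co-occur with a planted relative risk while all other diseases are
  independent;
* case-fatality and crude-death tables whose means differ between
  essential- and nonessential-biased classes;
* a simple protein-interaction edge list (Chung-Lu random graph) in which
  essential disease genes receive a planted expected-degree multiplier.

Identical (seed, config) pairs produce byte-identical output files; every
generator draws from its own named substream of the single global seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import substream
from .config import SimulationConfig
from .disease_network import canonicalize_name
from .errors import GenerationError
from . import io

LETHAL_TERM_NAMES = {
    "MP:0002080": "embryonic lethality",
    "MP:0002081": "prenatal lethality",
    "MP:0002082": "postnatal survival lethality",
    "MP:0002160": "abnormal reproductive system morphology",
    "MP:0001919": "abnormal reproductive system physiology",
}

#: Non-lethal filler terms so nonessential genes also carry annotations.
NONLETHAL_TERMS = {
    f"MP:{i:07d}": f"synthetic benign phenotype {i - 100000:02d}"
    for i in range(100001, 100031)
}


@dataclass
class SyntheticDataset:
    """In-memory bundle of all generated tables plus the ground truth."""

    genes_phenotypes: pd.DataFrame
    orthologs: pd.DataFrame
    morbidmap: pd.DataFrame
    claims: pd.DataFrame
    case_fatality: pd.DataFrame
    crude_death: pd.DataFrame
    ppi: pd.DataFrame
    truth: dict

    def write(self, outdir: str | Path) -> dict[str, str]:
        """Write all tables and truth.json; returns name -> path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in [
            ("genes_phenotypes", self.genes_phenotypes),
            ("orthologs", self.orthologs),
            ("morbidmap", self.morbidmap),
            ("claims", self.claims),
            ("case_fatality", self.case_fatality),
            ("crude_death", self.crude_death),
            ("ppi", self.ppi),
        ]:
            path = outdir / f"{name}.tsv"
            io.write_tsv(df, path)
            paths[name] = str(path)
        truth_path = outdir / "truth.json"
        io.write_json(self.truth, truth_path)
        paths["truth"] = str(truth_path)
        return paths


def generate_gene_catalog(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Mouse phenotype annotations, one-to-one ortholog map, and gene truth.

    Every mouse gene receives at least one phenotype term; essential genes
    (an ``essential_fraction`` of the catalog — exact count in deterministic
    assignment mode, binomial otherwise) carry one or two lethal terms.
    ``ortholog_fraction`` of mouse genes map one-to-one onto synthetic human
    ids; the human universe is padded with human-only genes (no ortholog) so
    downstream analyses see unmapped disease genes.
    """
    rng = substream(config.seed, "gene_catalog")
    n = config.n_mouse_genes
    mouse_ids = [f"Mmu{i:05d}" for i in range(1, n + 1)]
    if config.deterministic_essential_assignment:
        k = round(config.essential_fraction * n)
        ess_idx = np.zeros(n, dtype=bool)
        if k:
            ess_idx[rng.choice(n, size=k, replace=False)] = True
    else:
        ess_idx = rng.random(n) < config.essential_fraction

    lethal_ids = sorted(LETHAL_TERM_NAMES)
    nonlethal_ids = sorted(NONLETHAL_TERMS)
    rows = []
    for i, gene in enumerate(mouse_ids):
        n_benign = 1 + rng.poisson(0.5)
        for t in rng.choice(nonlethal_ids, size=n_benign, replace=False):
            rows.append((gene, t, NONLETHAL_TERMS[t]))
        if ess_idx[i]:
            n_lethal = int(rng.integers(1, 3))
            for t in rng.choice(lethal_ids, size=n_lethal, replace=False):
                rows.append((gene, t, LETHAL_TERM_NAMES[t]))
    genes_phenotypes = pd.DataFrame(rows, columns=io.GENES_PHENOTYPES_COLS)

    m = int(np.floor(config.ortholog_fraction * n))
    mapped_idx = np.sort(rng.choice(n, size=m, replace=False))
    human_ids = [f"Hsa{i:05d}" for i in range(1, m + 1)]
    # shuffle which human id each mouse gene gets, still one-to-one
    assignment = rng.permutation(m)
    pairs = [(mouse_ids[mi], human_ids[assignment[j]]) for j, mi in enumerate(mapped_idx)]
    orthologs = pd.DataFrame(sorted(pairs), columns=io.ORTHOLOGS_COLS)
    if orthologs["mouse_gene_id"].duplicated().any() or orthologs[
        "human_gene_id"
    ].duplicated().any():
        raise GenerationError("ortholog table violates one-to-one mapping")

    human_label = {}
    for j, mi in enumerate(mapped_idx):
        human_label[human_ids[assignment[j]]] = (
            "essential" if ess_idx[mi] else "nonessential"
        )
    n_extra = n - m
    human_only = [f"Hsa{i:05d}" for i in range(m + 1, m + n_extra + 1)]
    truth = {
        "mouse_essential": sorted(mouse_ids[i] for i in range(n) if ess_idx[i]),
        "n_mouse_essential": int(ess_idx.sum()),
        "human_gene_labels": dict(sorted(human_label.items())),
        "human_unmapped_pool": human_only,
    }
    return genes_phenotypes, orthologs, truth


def generate_diseasome(
    config: SimulationConfig, gene_truth: dict
) -> tuple[pd.DataFrame, dict]:
    """Morbid-map rows with planted per-class essentiality bias and subtypes."""
    rng = substream(config.seed, "diseasome")
    labels = gene_truth["human_gene_labels"]
    essential_pool = sorted(g for g, l in labels.items() if l == "essential")
    nonessential_pool = sorted(g for g, l in labels.items() if l == "nonessential")
    unmapped_pool = list(gene_truth["human_unmapped_pool"])
    if not essential_pool and not nonessential_pool:
        raise GenerationError("no mapped human genes to draw diseases from")
    classes = config.class_labels
    rows = []
    disease_truth = {}
    for i in range(config.n_diseases):
        dclass = classes[i % config.n_classes]
        bias = config.bias_of(dclass)
        name = f"Disease {i + 1:04d}"
        canon = canonicalize_name(name)
        n_genes = 1 + int(rng.poisson(config.genes_per_disease_lambda))
        genes: list[str] = []
        seen: set[str] = set()
        attempts = 0
        while len(genes) < n_genes and attempts < 50 * n_genes:
            attempts += 1
            u = rng.random()
            if unmapped_pool and u < config.unmapped_gene_rate:
                g = unmapped_pool[int(rng.integers(len(unmapped_pool)))]
            elif essential_pool and rng.random() < bias:
                g = essential_pool[int(rng.integers(len(essential_pool)))]
            elif nonessential_pool:
                g = nonessential_pool[int(rng.integers(len(nonessential_pool)))]
            else:
                g = essential_pool[int(rng.integers(len(essential_pool)))]
            if g not in seen:
                seen.add(g)
                genes.append(g)
        is_subtyped = bool(rng.random() < config.subtype_rate)
        if is_subtyped:
            n_sub = int(rng.integers(2, 4))
            assignment = rng.integers(0, n_sub, size=len(genes))
            for s in range(n_sub):
                sub_genes = [g for g, a in zip(genes, assignment) if a == s]
                if not sub_genes:  # every subtype row needs >= 1 gene
                    sub_genes = [genes[int(rng.integers(len(genes)))]]
                for g in sub_genes:
                    rows.append((f"{name}, {s + 1}", f"D{i + 1:04d}.{s + 1}", g, dclass))
        else:
            for g in genes:
                rows.append((name, f"D{i + 1:04d}", g, dclass))
        disease_truth[canon] = {
            "disease_class": dclass,
            "genes": sorted(genes),
            "n_subtypes": n_sub if is_subtyped else 1,
        }
    morbidmap = pd.DataFrame(rows, columns=io.MORBIDMAP_COLS)
    truth = {
        "diseases": disease_truth,
        "n_canonical_diseases": len(disease_truth),
        "class_essential_bias": {
            c: config.class_essential_bias[k] for k, c in enumerate(classes)
        },
        # planted expectation for the enrichment caller; classes at exactly
        # 0.5 carry no expectation (their call depends on the realized
        # unique-gene background, not on a plant)
        "expected_call": {
            c: (
                "essential_enriched"
                if config.class_essential_bias[k] > 0.5
                else "nonessential_enriched"
                if config.class_essential_bias[k] < 0.5
                else None
            )
            for k, c in enumerate(classes)
        },
    }
    return morbidmap, truth


def designated_rr_pairs(
    config: SimulationConfig, disease_truth: dict
) -> list[tuple[str, str]]:
    """Disjoint disease pairs receiving the planted relative risk.

    Pairs are drawn inside classes with essential bias > 0.5 (the planted
    comorbidity excess of essential-biased diseases); the pool widens to all
    diseases if those classes are too small.
    """
    rng = substream(config.seed, "rr_pairs")
    bias = {
        c: config.class_essential_bias[k]
        for k, c in enumerate(config.class_labels)
    }
    candidates = sorted(
        d
        for d, rec in disease_truth.items()
        if bias.get(rec["disease_class"], 0.0) > 0.5
    )
    if len(candidates) < 2 * config.n_rr_pairs:
        candidates = sorted(disease_truth)
    if len(candidates) < 2 * config.n_rr_pairs:
        raise GenerationError(
            f"cannot place {config.n_rr_pairs} disjoint pairs among "
            f"{len(candidates)} diseases"
        )
    chosen = rng.choice(len(candidates), size=2 * config.n_rr_pairs, replace=False)
    pairs = []
    for k in range(config.n_rr_pairs):
        a, b = candidates[chosen[2 * k]], candidates[chosen[2 * k + 1]]
        pairs.append((a, b) if a < b else (b, a))
    return sorted(pairs)


def generate_claims(
    config: SimulationConfig, disease_truth: dict
) -> tuple[pd.DataFrame, dict]:
    """Per-patient diagnosis lists with planted pairwise relative risk.

    Each patient acquires each disease independently with
    ``baseline_prevalence`` except the designated pairs, which are drawn
    jointly so P(both) = RR * p^2 while both marginals stay at p — the
    population relative risk of the pair equals ``planted_rr`` in
    expectation, and plants do not interact because pairs are disjoint.
    """
    if config.n_patients <= 0:
        raise GenerationError("n_patients must be positive (N > 0)")
    rng = substream(config.seed, "claims")
    diseases = sorted(disease_truth)
    index = {d: i for i, d in enumerate(diseases)}
    p = config.baseline_prevalence
    pairs = designated_rr_pairs(config, disease_truth)
    p_both = config.planted_rr * p * p
    for a, b in pairs:
        if p_both > p or 2 * p - p_both > 1:
            raise GenerationError(
                f"planted_rr={config.planted_rr} with prevalence {p} implies "
                f"a probability outside [0, 1] for pair ({a}, {b})"
            )
    partner: dict[int, int] = {}
    for a, b in pairs:
        partner[index[a]] = index[b]
    paired_second = set(partner.values())

    n = config.n_patients
    matrix = np.zeros((n, len(diseases)), dtype=bool)
    for j in range(len(diseases)):
        if j in paired_second:
            continue  # filled together with its partner
        if j in partner:
            k = partner[j]
            u = rng.random(n)
            both = u < p_both
            only_j = (u >= p_both) & (u < p)
            only_k = (u >= p) & (u < 2 * p - p_both)
            matrix[:, j] = both | only_j
            matrix[:, k] = both | only_k
        else:
            matrix[:, j] = rng.random(n) < p
    pat_idx, dis_idx = np.nonzero(matrix)
    claims = pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:06d}" for i in pat_idx],
            "disease_id": [diseases[j] for j in dis_idx],
        }
    )
    truth = {
        "designated_pairs": [list(pr) for pr in pairs],
        "planted_rr": config.planted_rr,
        "baseline_prevalence": p,
        "n_patients": n,
    }
    return claims, truth


def generate_mortality(
    config: SimulationConfig, disease_truth: dict
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Case-fatality and crude-death tables with a planted severity gap.

    Diseases in classes with essential bias > 0.5 draw their true 8-year CFR
    from a Beta around ``cfr_essential_mean``; bias < 0.5 around
    ``cfr_nonessential_mean``; bias exactly 0.5 around the midpoint. The
    observed fraction adds binomial sampling noise over
    ``n_diagnosed_per_disease`` patients. The crude-death table is a
    deterministic per-class transform of the mean true CFR on a per-100,000
    scale (descriptive only).
    """
    rng = substream(config.seed, "mortality")
    bias = {
        c: config.class_essential_bias[k]
        for k, c in enumerate(config.class_labels)
    }
    kappa = config.cfr_concentration
    cf_rows = []
    true_cfr = {}
    class_cfrs: dict[str, list[float]] = {}
    for d in sorted(disease_truth):
        dclass = disease_truth[d]["disease_class"]
        b = bias.get(dclass, 0.5)
        if b > 0.5:
            mean = config.cfr_essential_mean
        elif b < 0.5:
            mean = config.cfr_nonessential_mean
        else:
            mean = (config.cfr_essential_mean + config.cfr_nonessential_mean) / 2
        if mean <= 0.0 or mean >= 1.0:
            cfr = mean
        else:
            cfr = float(rng.beta(mean * kappa, (1 - mean) * kappa))
        n_diag = config.n_diagnosed_per_disease
        observed = int(rng.binomial(n_diag, cfr)) / n_diag
        cf_rows.append((d, observed))
        true_cfr[d] = cfr
        class_cfrs.setdefault(dclass, []).append(cfr)
    case_fatality = pd.DataFrame(cf_rows, columns=io.CASE_FATALITY_COLS)
    cd_rows = [
        (dclass, round(1000.0 * float(np.mean(vals)), 2))
        for dclass, vals in sorted(class_cfrs.items())
    ]
    crude_death = pd.DataFrame(cd_rows, columns=io.CRUDE_DEATH_COLS)
    truth = {
        "true_cfr": true_cfr,
        "cfr_essential_mean": config.cfr_essential_mean,
        "cfr_nonessential_mean": config.cfr_nonessential_mean,
    }
    return case_fatality, crude_death, truth


def generate_ppi(
    config: SimulationConfig, gene_truth: dict, disease_truth: dict
) -> tuple[pd.DataFrame, dict]:
    """Chung-Lu protein-interaction graph with a planted degree multiplier.

    Every protein u has weight w_u (its expected degree up to capping);
    essential disease genes get w multiplied by
    ``degree_multiplier_essential``. Edges are independent with probability
    min(1, w_u w_v / sum(w)); no self-loops, no duplicate pairs.
    """
    rng = substream(config.seed, "ppi")
    labels = gene_truth["human_gene_labels"]
    disease_genes: set[str] = set()
    for rec in disease_truth.values():
        disease_genes.update(rec["genes"])
    human_genes = sorted(labels) + list(gene_truth["human_unmapped_pool"])
    if config.ppi_n_proteins < len(human_genes):
        raise GenerationError(
            f"ppi_n_proteins={config.ppi_n_proteins} smaller than the human "
            f"gene universe ({len(human_genes)})"
        )
    fillers = [
        f"Prt{i:05d}" for i in range(1, config.ppi_n_proteins - len(human_genes) + 1)
    ]
    proteins = human_genes + fillers
    w = np.full(len(proteins), config.ppi_mean_degree, dtype=float)
    essential_disease = {
        g for g in disease_genes if labels.get(g) == "essential"
    }
    for i, prot in enumerate(proteins):
        if prot in essential_disease:
            w[i] *= config.degree_multiplier_essential
    s = w.sum()
    rows_a, rows_b = [], []
    for i in range(len(proteins) - 1):
        prob = np.minimum(w[i] * w[i + 1 :] / s, 1.0)
        hits = np.nonzero(rng.random(len(prob)) < prob)[0]
        for h in hits:
            rows_a.append(proteins[i])
            rows_b.append(proteins[i + 1 + h])
    ppi = pd.DataFrame({"protein_a": rows_a, "protein_b": rows_b})
    expected = {
        g: float(w[i] * (s - w[i]) / s)
        for i, g in enumerate(proteins)
        if g in disease_genes
    }
    truth = {
        "expected_degree": expected,
        "degree_multiplier_essential": config.degree_multiplier_essential,
        "essential_disease_genes_in_ppi": sorted(essential_disease),
    }
    return ppi, truth


def generate(config: SimulationConfig) -> SyntheticDataset:
    """Run all generators and assemble the full synthetic dataset."""
    genes_phenotypes, orthologs, gene_truth = generate_gene_catalog(config)
    morbidmap, disease_truth = generate_diseasome(config, gene_truth)
    claims, claims_truth = generate_claims(config, disease_truth["diseases"])
    case_fatality, crude_death, mortality_truth = generate_mortality(
        config, disease_truth["diseases"]
    )
    ppi, ppi_truth = generate_ppi(config, gene_truth, disease_truth["diseases"])
    truth = {
        "config": config.to_dict(),
        "genes": gene_truth,
        "diseasome": disease_truth,
        "claims": claims_truth,
        "mortality": mortality_truth,
        "ppi": ppi_truth,
    }
    return SyntheticDataset(
        genes_phenotypes=genes_phenotypes,
        orthologs=orthologs,
        morbidmap=morbidmap,
        claims=claims,
        case_fatality=case_fatality,
        crude_death=crude_death,
        ppi=ppi,
        truth=truth,
    )
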
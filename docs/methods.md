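# Methods

This note documents the models and procedures implemented in `essnet`, the
design choices made where the design was genuinely open, and what the
synthetic data does and does not establish.

## Essentiality classification and orthology transfer

A mouse gene is labelled **essential** iff at least one of its
phenotype-ontology annotations belongs to the lethal-term set

```
MP:0002080  embryonic lethality
MP:0002081  prenatal lethality
MP:0002082  postnatal survival lethality
MP:0002160  abnormal reproductive system morphology
MP:0001919  abnormal reproductive system physiology
```

Every other gene in the catalog — including genes with no annotation at
all — is **nonessential**. The "death before ~50 days of life" notion of
essentiality is operationalized entirely through term membership; no
lifespan data is consumed. Term ids are matched by exact string equality
after trimming and normalizing an internal space (`MP: 0002080` →
`MP:0002080`), since that form appears in print. Rows with malformed term
ids are skipped and counted, never guessed at.

Labels transfer to human disease genes through a **strictly one-to-one**
ortholog map. A table containing a duplicated mouse or human id is rejected
with the offending ids listed — silent filtering would hide upstream data
errors. Disease genes without an ortholog (or whose ortholog is absent from
the label table) form a third, *unmapped* category that is excluded from all
essentiality analyses; the three categories always partition the
disease-gene universe.

## Disease subtype merging

Raw morbid-map names are canonicalized by lowercasing, whitespace
normalization, and stripping one trailing subtype token matching
`, <integer>` or `, type <token>` (`"Breast cancer, 1"` → `"breast
cancer"`). Rows with equal canonical names merge into one disease whose gene
set is the union of the rows' genes. When merged rows disagree on the
disease class, the majority class wins with a deterministic lexicographic
tie-break, and the conflict is logged. The one-pass strip is a deliberate,
testable proxy for manual subtype curation; it does not attempt to merge
differently-worded synonyms.

## The disease network and motif null

Nodes are canonical diseases; an undirected link joins two diseases whose
gene sets intersect. Each link is classed by the transferred labels of its
shared genes: *essential* (all classified shared genes essential, at least
one), *nonessential* (symmetric), *other* (both kinds present), or
*unclassified* (only unmapped genes). Unmapped genes are ignored when at
least one classified gene is present — they carry no evidence either way —
and "other" is reserved for genuine mixtures, never for ignorance.

Triangles (the smallest complete subgraph) are classed *all-essential*,
*all-nonessential*, or *mixed* from their three link classes. Triangles
containing an unclassified link are excluded from the motif denominator and
reported separately. An optional breakdown splits *mixed* into triangles
whose links are pure but of both kinds versus triangles containing an
"other" link; this finer split is an interpretation, reported but never
tested.

The modularity null shuffles the essential/nonessential labels uniformly at
random across the mapped disease genes — exactly preserving the label
counts — on the fixed network topology, then re-classes every link and
triangle. The empirical upper-tail p-value for a motif class uses the
add-one correction, `p = (1 + #{null ≥ observed}) / (B + 1)`, which cannot
return 0. Default `B = 1000`; the seed is mandatory. Internally the
re-classification is a sparse edge×gene matrix product, which equals the
direct per-edge classification (tested) and makes 999 permutations on the
default network take well under a second.

## Class enrichment

For each disease class, the mapped genes associated with ≥ 1 disease of the
class (set semantics: once per class, but a gene may count in several
classes) are tested for over-representation of essential genes and,
separately, of nonessential genes, with the upper-tail hypergeometric
probability `P(X ≥ k)` for `X ~ Hypergeom(M, K, n)`. The background `M` is
the set of all mapped disease genes — the comparison is within the
disease-gene universe, not against the genome; this is an assumption, made
explicit here. A class is called essential-enriched (nonessential-enriched)
when the corresponding raw p falls below α = 0.05. No multiple-testing
correction is applied by default, matching the raw-p convention of this
analysis style; a Benjamini-Hochberg option exists but is off.

## Severity

The 8-year case fatality rate of a disease is the fraction of its diagnosed
patients deceased within 8 years of first diagnosis. The unit of analysis
is the disease (one CFR value per disease), diseases inherit their class's
enrichment call, and the essential-enriched and nonessential-enriched CFR
vectors are compared with the Mann-Whitney U test. Per-class crude death
rates (deaths per 100,000 population) are joined and displayed as given —
they are descriptive inputs and are never recomputed or tested. A companion
check compares per-disease patient counts between the two enriched groups;
under an unbiased design it should not reject.

**Mann-Whitney details.** Midrank tie handling; exact null distribution when
the combined sample is ≤ 20 and tie-free, otherwise the normal approximation
with tie and continuity corrections. Groups smaller than 2 raise an
insufficient-data error rather than returning a meaningless p. The default
alternative is two-sided everywhere — directional findings are reported via
the group summaries, not by one-sided testing; a one-sided option exists.

## Comorbidity

From per-patient diagnosis lists the pipeline counts `N` (distinct patients
in the table), `I_i` (patients with disease i) and `C_ij` (patients with
both i and j; stored sparsely, absent pairs are zero). The relative risk of
a pair is

```
RR = C_ij / C*_ij,   C*_ij = I_i I_j / N
```

and a pair is **comorbid** when `RR ≥ 2` (inclusive; configurable). Pairs
with zero co-occurrence have RR = 0; pairs involving a zero-incidence
disease have RR undefined and are never comorbid. No continuity or
small-sample correction is applied. Per-disease comorbid-partner counts are
compared between the enriched groups with the shared Mann-Whitney test.

Note on `N`: a claims table observes exactly the patients with at least one
record, which is what the reference population count of such data means.
With the default synthetic disease panel (200 diseases at prevalence 0.05)
the probability that a simulated patient is silent is ≈ 3×10⁻⁵, so the
planted relative risk is recovered essentially unbiased; with very small
panels the silent fraction becomes visible and RR deflates by the
observed/true patient ratio — the package's tests therefore use panels of
≥ 100 diseases for RR recovery checks.

## Pleiotropy and PPI degree

A gene is pleiotropic when associated with ≥ 2 *canonical* diseases —
counted after subtype merging, so numbered subtypes of one disorder never
inflate the count. Pleiotropy frequency in essential vs nonessential
disease genes is tested with Fisher's exact test (two-sided, point-
probability method). PPI degree is the number of distinct partners after
removing self-loops and duplicate rows (removals are counted and logged);
genes absent from the graph reflect assay coverage, not biology, and are
excluded with a reported count rather than assigned degree 0.

## The synthetic-data generator

The generator's defaults define the reference experiment:

| parameter | default | meaning |
|---|---|---|
| `n_mouse_genes` | 2000 | mouse gene catalog size |
| `essential_fraction` | 0.15 | fraction carrying lethal terms (≈ the real-catalog proportion) |
| `ortholog_fraction` | 0.8 | mouse genes with a one-to-one human ortholog |
| `n_diseases`, `n_classes` | 200, 5 | canonical diseases, disease classes |
| `class_essential_bias` | 0.9, 0.8, 0.5, 0.2, 0.1 | P(disease-gene draw is essential) per class |
| `genes_per_disease_lambda` | 3.0 | genes per disease ~ 1 + Poisson(λ) |
| `subtype_rate` | 0.3 | diseases emitted as ≥ 2 numbered subtype rows |
| `unmapped_gene_rate` | 0.05 | draws from the no-ortholog human pool |
| `n_patients` | 100 000 | claims population |
| `baseline_prevalence` | 0.05 | per-disease marginal probability |
| `planted_rr`, `n_rr_pairs` | 4.0, 20 | relative risk planted on disjoint pairs |
| `cfr_essential_mean` / `cfr_nonessential_mean` | 0.8 / 0.5 | Beta means of true CFR by class group |
| `cfr_concentration` | 100 | Beta concentration (per-disease CFR spread ≈ 0.04) |
| `n_diagnosed_per_disease` | 500 | binomial n behind the observed CFR |
| `ppi_n_proteins`, `ppi_mean_degree` | 2500, 6 | Chung-Lu graph size and mean degree |
| `degree_multiplier_essential` | 3.0 | expected-degree multiplier for essential disease genes |

One global seed drives a named substream per generator (CRC-32 of the
substream name mixed into a `SeedSequence`), so adding a generator never
perturbs the draws of the others, and identical (seed, config) pairs yield
byte-identical files.

Planting mechanisms:

* **Essentiality** — deterministic mode assigns exactly
  `round(fraction × n)` essential genes (the default; an independent
  Bernoulli mode exists). Essential genes carry 1–2 lethal terms; every
  gene carries ≥ 1 benign term.
* **Class bias** — each disease-gene draw is essential with its class's
  bias, from the mapped pools, with a small probability of drawing a
  no-ortholog gene. Because the essential pool is smaller, essential genes
  are reused across more diseases; this reuse is what produces
  essential-linked network modules and the higher pleiotropy of essential
  genes — the same mechanism the real data is thought to reflect.
* **Relative risk** — designated disjoint pairs are drawn jointly:
  P(both) = RR·p², with both marginals kept at p, so the population RR
  equals the plant in expectation and plants cannot interact. Infeasible
  combinations (RR·p > 1) are rejected naming the pair. Pairs are placed
  inside the essential-biased classes.
* **Severity** — classes with bias > 0.5 draw true CFR around the essential
  mean, < 0.5 around the nonessential mean, = 0.5 around the midpoint;
  observed CFR adds binomial noise. The crude-death table is a
  deterministic transform (1000 × class mean CFR) since it is descriptive.
* **PPI** — a Chung-Lu random graph: edge (u, v) with probability
  min(1, w_u w_v / Σw), where w is the target expected degree; essential
  disease genes' w is multiplied by the planted factor.

The truth file records the planted labels, designated pairs, true CFRs,
expected degrees, and the expected enrichment call per class
(bias > 0.5 → essential-enriched, < 0.5 → nonessential-enriched, exactly
0.5 → no expectation: such a class may legitimately drift relative to the
unique-gene background).

**What the generator does not emulate:** real ontology structure (term
hierarchies, genotype-level annotations), many-to-many orthology,
synonym-level disease-name variation, age structure and temporal ordering of
diagnoses, ICD-code semantics, assortative or scale-free PPI topology, and
correlated noise between stages. Passing tests therefore demonstrate that
the pipeline's estimators and tests recover the structures they claim to
measure — not that any specific biological conclusion holds in real
databases.

## Numerical and degenerate-input choices

* Empirical permutation p-values use the add-one correction; their floor is
  `1/(B+1)`.
* Class-call conflicts (both tails significant — pathological inputs only)
  resolve to the smaller p with a warning.
* Degenerate 2×2 tables (a zero margin) return p = 1 with a warning.
* Zero eligible triangles, single-label gene sets, empty claims, and groups
  of size < 2 raise explicit errors instead of producing NaNs.
* All output tables are TSV (UTF-8, LF, header); JSON outputs have sorted
  keys; reruns with the same config are byte-identical. Run timestamps go
  to the log stream only, never into bundle files, to keep bundles
  reproducible.

## Problem sizes used by the test and acceptance runs

Unit tests run a reduced configuration (300–400 mouse genes, 30–60 diseases,
2 000–5 000 patients) chosen so every stage still has its planted signal;
the end-to-end recovery checks and the acceptance script use the full
default configuration above (999 permutations, 100 000 patients), and the
estimator-accuracy run uses 50 designated pairs. Calibration checks use
200 replicate seeds for permutation-p uniformity (KS), 150×12 class tests
for enrichment (compared against the exact achievable level of the discrete
hypergeometric test), and 500 replicates each for Mann-Whitney and Fisher
type-I rates (Fisher's exact test is conservative on discrete tables, so
its rate is asserted to sit at or below the nominal level).

## Known limitations

* The subtype-merging rule is a syntactic proxy; differently-worded subtype
  names do not merge.
* Enrichment uses raw p-values by design fidelity; with 21 classes and two
  tails, expect ≈ 2 false calls per analysis under the null unless the BH
  option is enabled.
* The crude-death join assumes the disease-class vocabulary is shared
  between the enrichment table and the death-rate table; no code-system
  crosswalk is provided.
* RR estimates from claims inherit the observed-N semantics discussed
  above and apply no small-sample correction.
* The permutation null fixes the network topology and shuffles labels only;
  it tests label placement, not degree-sequence effects.
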
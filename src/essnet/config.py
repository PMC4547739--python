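"""Configuration objects for the synthetic-data generator and the pipeline.

A single YAML/JSON document configures a run. Unknown keys are hard errors:
a silently ignored typo in ``rr_threshold`` or ``alpha`` would corrupt the
fidelity of every downstream number.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigError

# Synthetic disease classes are named after phenotype-level physiological
# systems; the default bias vector plants cancer/cardiovascular as
# essential-biased and ophthalmological/ear-nose-throat as nonessential-biased,
# mirroring the direction such classes show in real morbid-map data.
CLASS_NAME_POOL = [
    "cancer",
    "cardiovascular",
    "metabolic",
    "ophthalmological",
    "ear_nose_throat",
    "endocrine",
    "developmental",
    "respiratory",
    "gastrointestinal",
    "psychiatric",
    "immunological",
    "connective_tissue",
    "neurological",
    "hematological",
    "renal",
    "skeletal",
    "muscular",
    "dermatological",
    "bone",
    "nutritional",
    "multiple",
]


def class_names(n: int) -> list[str]:
    """First ``n`` synthetic disease-class names (extends past the pool)."""
    if n <= len(CLASS_NAME_POOL):
        return CLASS_NAME_POOL[:n]
    extra = [f"class_{i:02d}" for i in range(len(CLASS_NAME_POOL) + 1, n + 1)]
    return CLASS_NAME_POOL + extra


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study population.

    Defaults define the reference planted-structure experiment: ~2,000 mouse
    genes with 15% essential, 200 diseases in 5 classes with essential bias
    (0.9, 0.8, 0.5, 0.2, 0.1), 100,000 patients, relative risk 4 planted on
    20 disjoint disease pairs inside the essential-biased classes, an 8-year
    case-fatality gap of 0.8 vs 0.5 between essential- and
    nonessential-biased classes, and a 3x protein-interaction degree
    multiplier for essential disease genes.
    """

    seed: int = 0
    # gene catalog
    n_mouse_genes: int = 2000
    essential_fraction: float = 0.15
    ortholog_fraction: float = 0.8
    deterministic_essential_assignment: bool = True
    # diseasome
    n_diseases: int = 200
    n_classes: int = 5
    genes_per_disease_lambda: float = 3.0  # genes per disease ~ 1 + Poisson(lambda)
    class_essential_bias: tuple[float, ...] = (0.9, 0.8, 0.5, 0.2, 0.1)
    subtype_rate: float = 0.3
    unmapped_gene_rate: float = 0.05
    # patient claims
    n_patients: int = 100_000
    baseline_prevalence: float = 0.05
    planted_rr: float = 4.0
    n_rr_pairs: int = 20
    # mortality
    cfr_essential_mean: float = 0.8
    cfr_nonessential_mean: float = 0.5
    cfr_concentration: float = 100.0
    n_diagnosed_per_disease: int = 500
    # protein-protein interaction network
    ppi_n_proteins: int = 2500
    ppi_mean_degree: float = 6.0
    degree_multiplier_essential: float = 3.0

    def __post_init__(self) -> None:
        proportions = {
            "essential_fraction": self.essential_fraction,
            "ortholog_fraction": self.ortholog_fraction,
            "subtype_rate": self.subtype_rate,
            "unmapped_gene_rate": self.unmapped_gene_rate,
            "baseline_prevalence": self.baseline_prevalence,
            "cfr_essential_mean": self.cfr_essential_mean,
            "cfr_nonessential_mean": self.cfr_nonessential_mean,
        }
        for name, value in proportions.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        counts = {
            "n_mouse_genes": self.n_mouse_genes,
            "n_diseases": self.n_diseases,
            "n_classes": self.n_classes,
            "n_patients": self.n_patients,
            "ppi_n_proteins": self.ppi_n_proteins,
            "n_diagnosed_per_disease": self.n_diagnosed_per_disease,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ConfigError(f"{name} must be a positive count, got {value}")
        if self.n_rr_pairs < 0:
            raise ConfigError("n_rr_pairs must be nonnegative")
        if self.planted_rr < 1.0:
            raise ConfigError(f"planted_rr must be >= 1, got {self.planted_rr}")
        if self.degree_multiplier_essential < 1.0:
            raise ConfigError("degree_multiplier_essential must be >= 1")
        if self.genes_per_disease_lambda < 0:
            raise ConfigError("genes_per_disease_lambda must be >= 0")
        if self.cfr_concentration <= 0:
            raise ConfigError("cfr_concentration must be > 0")
        if self.ppi_mean_degree <= 0:
            raise ConfigError("ppi_mean_degree must be > 0")
        if self.ppi_mean_degree >= self.ppi_n_proteins:
            raise ConfigError("ppi_mean_degree must be < ppi_n_proteins")
        bias = tuple(float(b) for b in self.class_essential_bias)
        object.__setattr__(self, "class_essential_bias", bias)
        if len(bias) != self.n_classes:
            raise ConfigError(
                f"class_essential_bias has {len(bias)} entries for "
                f"{self.n_classes} classes"
            )
        for b in bias:
            if not 0.0 <= b <= 1.0:
                raise ConfigError(f"class bias outside [0, 1]: {b}")
        if 2 * self.n_rr_pairs > self.n_diseases:
            raise ConfigError(
                "n_rr_pairs too large: designated pairs must be disjoint "
                f"({self.n_rr_pairs} pairs need {2 * self.n_rr_pairs} diseases, "
                f"have {self.n_diseases})"
            )

    @property
    def class_labels(self) -> list[str]:
        return class_names(self.n_classes)

    def bias_of(self, disease_class: str) -> float:
        return self.class_essential_bias[self.class_labels.index(disease_class)]

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["class_essential_bias"] = list(d["class_essential_bias"])
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown simulate keys: {sorted(unknown)}")
        if "class_essential_bias" in d and isinstance(d["class_essential_bias"], list):
            d = dict(d, class_essential_bias=tuple(d["class_essential_bias"]))
        return cls(**d)


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end run configuration.

    Either ``simulate`` embeds a :class:`SimulationConfig` or the ``inputs``
    map points at existing tables (keys: genes_phenotypes, orthologs,
    morbidmap, claims, case_fatality, crude_death, ppi). Optional inputs that
    are absent cause the corresponding stage to be skipped with a log entry.
    """

    seed: int = 0
    simulate: SimulationConfig | None = None
    inputs: dict[str, str] = field(default_factory=dict)
    alpha: float = 0.05
    rr_threshold: float = 2.0
    n_permutations: int = 1000
    alternative: str = "two_sided"
    output_dir: str = "results"

    _INPUT_KEYS = frozenset(
        {
            "genes_phenotypes",
            "orthologs",
            "morbidmap",
            "claims",
            "case_fatality",
            "crude_death",
            "ppi",
        }
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.rr_threshold <= 0:
            raise ConfigError("rr_threshold must be positive")
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be >= 1")
        if self.alternative not in {"two_sided", "greater", "less"}:
            raise ConfigError(f"unknown alternative: {self.alternative!r}")
        unknown = set(self.inputs) - self._INPUT_KEYS
        if unknown:
            raise ConfigError(f"unknown input keys: {sorted(unknown)}")
        if self.simulate is None and "morbidmap" not in self.inputs:
            raise ConfigError(
                "config must either embed a simulate block or point at a "
                "morbidmap input"
            )

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls) if not f.name.startswith("_")}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "simulate" in d and d["simulate"] is not None:
            sim = dict(d["simulate"])
            sim.setdefault("seed", d.get("seed", 0))
            d["simulate"] = SimulationConfig.from_dict(sim)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise ConfigError(f"{path}: config document must be a mapping")
        return cls.from_dict(doc)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"] = self.simulate.to_dict()
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode("utf-8")
        return hashlib.sha256(blob).hexdigest()[:16]
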
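"""Readers and writers for the pipeline's tab-separated interchange files.

All files are TSV with a header row, UTF-8, LF line endings. Every table the
synthetic-data generator emits round-trips through these readers without loss.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

# column contracts, one per interchange file
GENES_PHENOTYPES_COLS = ["gene_id", "mp_term_id", "mp_term_name"]
ORTHOLOGS_COLS = ["mouse_gene_id", "human_gene_id"]
MORBIDMAP_COLS = ["raw_disease_name", "disease_id", "gene_id", "disease_class"]
CLAIMS_COLS = ["patient_id", "disease_id"]
CASE_FATALITY_COLS = ["disease_id", "fraction_deceased_8yr"]
CRUDE_DEATH_COLS = ["disease_class", "deaths_per_100k"]
PPI_COLS = ["protein_a", "protein_b"]


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a TSV with header, UTF-8 and LF endings (byte-stable output)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", encoding="utf-8")


def read_tsv(path: str | Path, columns: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if columns is not None:
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
    return df


def read_genes_phenotypes(path: str | Path) -> pd.DataFrame:
    return read_tsv(path, GENES_PHENOTYPES_COLS)


def read_orthologs(path: str | Path) -> pd.DataFrame:
    return read_tsv(path, ORTHOLOGS_COLS)


def read_morbidmap(path: str | Path) -> pd.DataFrame:
    return read_tsv(path, MORBIDMAP_COLS)


def read_claims(path: str | Path) -> pd.DataFrame:
    return read_tsv(path, CLAIMS_COLS)


def read_case_fatality(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path, CASE_FATALITY_COLS)
    df["fraction_deceased_8yr"] = df["fraction_deceased_8yr"].astype(float)
    return df


def read_crude_death(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path, CRUDE_DEATH_COLS)
    df["deaths_per_100k"] = df["deaths_per_100k"].astype(float)
    return df


def read_ppi(path: str | Path) -> pd.DataFrame:
    return read_tsv(path, PPI_COLS)


def write_json(obj, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
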
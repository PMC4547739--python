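"""Clinical severity of diseases by transferred gene essentiality.

Two severity measures: the 8-year case fatality rate (fraction of diagnosed
patients deceased within 8 years of initial diagnosis; one value per disease)
and the per-class crude death rate (deaths per 100,000 population — taken as
given and joined, never recomputed). Diseases inherit the enrichment call of
their class, and case-fatality distributions of the essential-enriched and
nonessential-enriched groups are compared with the Mann-Whitney U test.
"""

from __future__ import annotations

import logging

import pandas as pd

from .class_enrichment import EnrichmentResult
from .disease_network import Diseasome
from .errors import InputError
from .stats import GroupComparisonResult, mann_whitney

logger = logging.getLogger(__name__)


def compute_case_fatality(records: pd.DataFrame) -> pd.DataFrame:
    """Per-disease 8-year case fatality from patient-level outcome records.

    ``records`` has one row per diagnosed patient with columns ``disease_id``
    and ``deceased_8yr`` (truthy flag). Returns a table
    (disease_id, fraction_deceased_8yr, n_patients); diseases with zero
    diagnosed patients simply do not appear.
    """
    if "disease_id" not in records or "deceased_8yr" not in records:
        raise InputError("records need disease_id and deceased_8yr columns")
    flags = records["deceased_8yr"].astype(int)
    if (flags < 0).any():
        raise InputError("negative death flags")
    grouped = records.assign(deceased_8yr=flags).groupby("disease_id")["deceased_8yr"]
    out = grouped.agg(["mean", "size"]).reset_index()
    out.columns = ["disease_id", "fraction_deceased_8yr", "n_patients"]
    return out


def _call_by_disease(
    enrichment: list[EnrichmentResult], diseasome: Diseasome
) -> dict[str, str]:
    call_by_class = {r.disease_class: r.call for r in enrichment}
    out = {}
    for key, disease in diseasome.diseases.items():
        call = call_by_class.get(disease.disease_class)
        if call is None:
            logger.warning(
                "disease %r: class %r has no enrichment call; assigned neither",
                key,
                disease.disease_class,
            )
            call = "neither"
        out[key] = call
    return out


def group_case_fatality(
    cfr: pd.DataFrame,
    enrichment: list[EnrichmentResult],
    diseasome: Diseasome,
) -> dict[str, list[float]]:
    """Partition per-disease CFR values by the class enrichment call.

    Returns {"essential_enriched": [...], "nonessential_enriched": [...],
    "neither": [...]}; together the three vectors hold every disease with a
    CFR value that belongs to the diseasome.
    """
    calls = _call_by_disease(enrichment, diseasome)
    groups: dict[str, list[float]] = {
        "essential_enriched": [],
        "nonessential_enriched": [],
        "neither": [],
    }
    for disease_id, frac in zip(
        cfr["disease_id"].astype(str), cfr["fraction_deceased_8yr"].astype(float)
    ):
        if not 0.0 <= frac <= 1.0:
            raise InputError(f"case fatality outside [0,1] for {disease_id}: {frac}")
        if disease_id not in calls:
            logger.warning("CFR for unknown disease %r ignored", disease_id)
            continue
        groups[calls[disease_id]].append(frac)
    return groups


def compare_case_fatality(
    cfr: pd.DataFrame,
    enrichment: list[EnrichmentResult],
    diseasome: Diseasome,
    alternative: str = "two_sided",
) -> GroupComparisonResult:
    """Mann-Whitney U on CFR: essential- vs nonessential-enriched diseases."""
    groups = group_case_fatality(cfr, enrichment, diseasome)
    return mann_whitney(
        groups["essential_enriched"],
        groups["nonessential_enriched"],
        alternative=alternative,
    )


def join_crude_death(
    enrichment: list[EnrichmentResult], crude_death: pd.DataFrame
) -> pd.DataFrame:
    """Join per-class crude death rates onto enrichment calls (descriptive)."""
    calls = pd.DataFrame(
        [(r.disease_class, r.call) for r in enrichment],
        columns=["disease_class", "call"],
    )
    return calls.merge(crude_death, on="disease_class", how="left")


def patient_count_bias_check(
    incidence: dict[str, int],
    enrichment: list[EnrichmentResult],
    diseasome: Diseasome,
    alternative: str = "two_sided",
) -> GroupComparisonResult:
    """Compare per-disease patient counts between the two enriched groups.

    A sanity check that observed severity differences are not an artifact of
    patient volume: under an unbiased sampling design this comparison should
    not reject.
    """
    calls = _call_by_disease(enrichment, diseasome)
    a = [n for d, n in incidence.items() if calls.get(d) == "essential_enriched"]
    b = [n for d, n in incidence.items() if calls.get(d) == "nonessential_enriched"]
    return mann_whitney(a, b, alternative=alternative)
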
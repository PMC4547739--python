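"""Disease comorbidity from patient claims via relative risk.

For diseases *i*, *j* with incidences I_i, I_j among N patients and observed
co-occurrence C_ij, the relative risk is

    RR = C_ij / C*_ij,    C*_ij = I_i * I_j / N,

the observed co-occurrence over its expectation under independence. Pairs
with RR >= 2 (inclusive, configurable) are comorbid. Comorbid-partner counts
per disease are compared between essential- and nonessential-enriched
diseases with the Mann-Whitney U test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .class_enrichment import EnrichmentResult
from .disease_network import Diseasome
from .errors import InputError
from .severity import _call_by_disease
from .stats import GroupComparisonResult, mann_whitney

logger = logging.getLogger(__name__)

DEFAULT_RR_THRESHOLD = 2.0


@dataclass
class ClaimsSummary:
    """Sparse claims counts: absent pairs have C_ij = 0 by contract."""

    n_patients: int
    incidence: dict[str, int]
    cooccurrence: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise InputError("total patient count N must be positive")
        for d, i in self.incidence.items():
            if not 0 <= i <= self.n_patients:
                raise InputError(f"incidence of {d} outside [0, N]: {i}")
        for (a, b), c in self.cooccurrence.items():
            if a >= b:
                raise InputError(f"co-occurrence key not sorted: {(a, b)}")
            if c > min(self.incidence.get(a, 0), self.incidence.get(b, 0)):
                raise InputError(
                    f"impossible counts: C({a},{b})={c} exceeds an incidence"
                )

    def c_ij(self, a: str, b: str) -> int:
        key = (a, b) if a < b else (b, a)
        return self.cooccurrence.get(key, 0)


@dataclass(frozen=True)
class RRResult:
    pair: tuple[str, str]
    c_ij: int
    expected: float
    rr: float | None  # None when either incidence is zero
    comorbid: bool


def summarize_claims(claims: pd.DataFrame) -> ClaimsSummary:
    """Count N, I_i and C_ij from per-patient diagnosis rows.

    ``claims`` has columns ``patient_id`` and ``disease_id``, one row per
    diagnosis. Duplicate (patient, disease) rows are deduplicated with a
    warning. Co-occurrence is stored sparsely: only pairs with C_ij > 0.

    N is the number of distinct patients appearing in the table — a claims
    database observes exactly the patients with at least one record, which
    is what the reference population count of such data means.
    """
    if len(claims) == 0:
        raise InputError("empty claims table: N must be positive")
    df = claims[["patient_id", "disease_id"]].astype(str)
    n_before = len(df)
    df = df.drop_duplicates()
    if len(df) < n_before:
        logger.warning(
            "deduplicated %d repeated (patient, disease) rows", n_before - len(df)
        )
    patients, _ = pd.factorize(df["patient_id"])
    disease_codes, diseases = pd.factorize(df["disease_id"])
    n_patients = int(patients.max()) + 1
    mat = sp.csr_matrix(
        (np.ones(len(df), dtype=np.int64), (patients, disease_codes)),
        shape=(n_patients, len(diseases)),
    )
    incidence_vec = np.asarray(mat.sum(axis=0)).ravel()
    co = sp.triu(mat.T @ mat, k=1).tocoo()
    names = [str(d) for d in diseases]
    cooccurrence = {}
    for i, j, c in zip(co.row, co.col, co.data):
        a, b = names[i], names[j]
        key = (a, b) if a < b else (b, a)
        cooccurrence[key] = int(c)
    incidence = {names[i]: int(incidence_vec[i]) for i in range(len(names))}
    return ClaimsSummary(n_patients, incidence, cooccurrence)


def relative_risk(
    c_ij: int,
    i_i: int,
    i_j: int,
    n: int,
    pair: tuple[str, str] = ("i", "j"),
    threshold: float = DEFAULT_RR_THRESHOLD,
) -> RRResult:
    """RR of one pair from its counts (Eq: RR = C_ij * N / (I_i * I_j))."""
    if n <= 0:
        raise InputError("N must be positive")
    if c_ij < 0 or i_i < 0 or i_j < 0:
        raise InputError("counts must be nonnegative")
    if c_ij > min(i_i, i_j):
        raise InputError(
            f"impossible counts for {pair}: C={c_ij} > min(I)={min(i_i, i_j)}"
        )
    key = tuple(sorted(pair))
    if i_i == 0 or i_j == 0:
        return RRResult(key, c_ij, 0.0, None, False)
    expected = i_i * i_j / n
    rr = c_ij / expected
    return RRResult(key, c_ij, expected, rr, rr >= threshold)


def rr_table(
    summary: ClaimsSummary, threshold: float = DEFAULT_RR_THRESHOLD
) -> list[RRResult]:
    """RR for every pair with C_ij > 0 (absent pairs have RR = 0)."""
    return [
        relative_risk(
            c,
            summary.incidence[a],
            summary.incidence[b],
            summary.n_patients,
            pair=(a, b),
            threshold=threshold,
        )
        for (a, b), c in sorted(summary.cooccurrence.items())
    ]


def count_comorbid_partners(
    summary: ClaimsSummary, threshold: float = DEFAULT_RR_THRESHOLD
) -> dict[str, int]:
    """Comorbid-partner count per disease (RR >= threshold).

    Diseases with zero incidence cannot form comorbid pairs; they are
    excluded with a warning. Only observed pairs (C_ij > 0) can reach the
    threshold, so the sparse summary suffices.
    """
    counts = {d: 0 for d, i in summary.incidence.items() if i > 0}
    n_zero = len(summary.incidence) - len(counts)
    if n_zero:
        logger.warning("%d diseases with zero incidence excluded", n_zero)
    for res in rr_table(summary, threshold=threshold):
        if res.comorbid:
            a, b = res.pair
            counts[a] += 1
            counts[b] += 1
    return counts


def compare_comorbidity(
    partner_counts: dict[str, int],
    enrichment: list[EnrichmentResult],
    diseasome: Diseasome,
    alternative: str = "two_sided",
) -> GroupComparisonResult:
    """Mann-Whitney U on partner counts: essential- vs nonessential-enriched."""
    calls = _call_by_disease(enrichment, diseasome)
    a = [n for d, n in partner_counts.items() if calls.get(d) == "essential_enriched"]
    b = [
        n
        for d, n in partner_counts.items()
        if calls.get(d) == "nonessential_enriched"
    ]
    return mann_whitney(a, b, alternative=alternative)


def rr_to_frame(results: list[RRResult]) -> pd.DataFrame:
    rows = [
        (
            r.pair[0],
            r.pair[1],
            r.c_ij,
            r.expected,
            r.rr if r.rr is not None else "",
            r.comorbid,
        )
        for r in results
    ]
    return pd.DataFrame(
        rows, columns=["disease_a", "disease_b", "C", "expected", "rr", "comorbid"]
    )
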
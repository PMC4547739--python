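"""Shared two-group comparisons: Mann-Whitney U and Fisher's exact test.

All group comparisons in the pipeline (case fatality, patient counts,
comorbid partner counts, PPI degree, pleiotropy frequency) report through one
result type so outputs are uniform and machine-readable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats as sps

from .errors import InsufficientDataError

logger = logging.getLogger(__name__)

_ALTERNATIVES = {"two_sided": "two-sided", "greater": "greater", "less": "less"}


@dataclass(frozen=True)
class GroupComparisonResult:
    test_name: str  # "mann_whitney_u" | "fisher_exact"
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    summary_a: float  # median (Mann-Whitney) or proportion (Fisher)
    summary_b: float
    alternative: str

    def to_dict(self) -> dict:
        return asdict(self)


def mann_whitney(
    values_a,
    values_b,
    alternative: str = "two_sided",
) -> GroupComparisonResult:
    """Mann-Whitney U rank-sum test with midrank tie handling.

    Uses the exact null distribution when the combined sample is small
    (n_a + n_b <= 20) and tie-free, otherwise the normal approximation with
    tie correction and continuity correction.
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"unknown alternative {alternative!r}")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError(
            f"Mann-Whitney needs both groups >= 2 (got {a.size}, {b.size})"
        )
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size + b.size <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative=_ALTERNATIVES[alternative], method=method
    )
    return GroupComparisonResult(
        test_name="mann_whitney_u",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n_a=int(a.size),
        n_b=int(b.size),
        summary_a=float(np.median(a)),
        summary_b=float(np.median(b)),
        alternative=alternative,
    )


def fisher_exact_2x2(
    a: int, b: int, c: int, d: int, alternative: str = "two_sided"
) -> GroupComparisonResult:
    """Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    Two-sided p by the point-probability method: the sum of the conditional
    hypergeometric probabilities of all tables (with the observed margins) no
    more probable than the observed one. A zero row or column margin makes
    the table degenerate; p = 1 is returned with a warning.
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"unknown alternative {alternative!r}")
    cells = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in cells):
        raise ValueError(f"table cells must be nonnegative integers, got {cells}")
    a, b, c, d = (int(x) for x in cells)
    prop_a = a / (a + b) if a + b else float("nan")
    prop_b = c / (c + d) if c + d else float("nan")
    degenerate = (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0)
    if degenerate:
        logger.warning("degenerate 2x2 table %s: p = 1", ((a, b), (c, d)))
        odds, p = float("nan"), 1.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            odds, p = sps.fisher_exact(
                [[a, b], [c, d]], alternative=_ALTERNATIVES[alternative]
            )
    return GroupComparisonResult(
        test_name="fisher_exact",
        statistic=float(odds),
        p_value=float(min(p, 1.0)),
        n_a=a + b,
        n_b=c + d,
        summary_a=prop_a,
        summary_b=prop_b,
        alternative=alternative,
    )
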
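"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid scipy and the package's own code paths: exact
rational arithmetic and exhaustive enumeration only.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations

import numpy as np


def mann_whitney_exact(a: list[float], b: list[float], alternative: str) -> float:
    """Exact Mann-Whitney p by enumerating all rank assignments (no ties)."""
    pooled = list(a) + list(b)
    n, na = len(pooled), len(a)

    def u_of(ga, gb):
        return sum(1.0 for x in ga for y in gb if x > y)

    u_obs = u_of(a, b)
    us = []
    allidx = set(range(n))
    for comb in combinations(range(n), na):
        ga = [pooled[i] for i in comb]
        gb = [pooled[i] for i in allidx - set(comb)]
        us.append(u_of(ga, gb))
    us = np.array(us)
    p_greater = float((us >= u_obs).mean())
    p_less = float((us <= u_obs).mean())
    if alternative == "greater":
        return p_greater
    if alternative == "less":
        return p_less
    return min(1.0, 2 * min(p_greater, p_less))


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by summing the conditional hypergeometric pmf
    over all tables with the observed margins no more probable than the
    observed table (point-probability method)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def pmf(k: int) -> Fraction:
        return Fraction(
            math.comb(r1, k) * math.comb(r2, c1 - k), math.comb(n, c1)
        )

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = pmf(a) * Fraction(10**7 + 1, 10**7)  # tolerance for fp comparison
    return float(sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs))


def hypergeom_upper_tail(k: int, n: int, K: int, M: int) -> float:
    """P(X >= k) for X ~ Hypergeom(M, K, n), exact rational summation."""
    total = sum(
        Fraction(math.comb(K, i) * math.comb(M - K, n - i), math.comb(M, n))
        for i in range(k, min(n, K) + 1)
    )
    return float(total)


def triangles_brute_force(nodes, edge_pairs) -> set[tuple]:
    """All triangles by scanning every C(n, 3) node triple."""
    edges = {tuple(sorted(e)) for e in edge_pairs}
    out = set()
    for u, v, w in combinations(sorted(nodes), 3):
        if (
            (u, v) in edges
            and (u, w) in edges
            and (v, w) in edges
        ):
            out.add((u, v, w))
    return out


def rr_from_patient_table(patient_diseases: dict[str, set[str]], a: str, b: str):
    """Relative risk computed directly from an enumerable patient table.

    Returns None when either disease has zero incidence.
    """
    n = len(patient_diseases)
    i_a = sum(1 for ds in patient_diseases.values() if a in ds)
    i_b = sum(1 for ds in patient_diseases.values() if b in ds)
    c_ab = sum(1 for ds in patient_diseases.values() if a in ds and b in ds)
    if i_a == 0 or i_b == 0:
        return None
    return c_ab / (i_a * i_b / n)
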
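"""Spearman rank correlation (exact small-sample P values) and SEM.

Cohort-level associations (mean dN/dS vs genome size, coding density vs
size, dN/dS vs ANI) are reported as Spearman's rank correlation with a
two-sided P value.  For n <= 9 the P value is exact, by enumeration of all
n! rank permutations; beyond that the usual t approximation
``t = rs * sqrt((n - 2) / (1 - rs^2))`` on n - 2 degrees of freedom is
used, except that a perfect correlation (|rs| = 1, where the t statistic
degenerates) falls back to its exact enumeration value 2/n!.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats as sps

EXACT_N_MAX = 9


@dataclass
class CorrelationResult:
    rs: float
    p_two_sided: float
    n: int
    method: str  # "exact-permutation" or "t-approximation"


@lru_cache(maxsize=8)
def _permutation_index(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.int8)


def _rank(v: np.ndarray) -> np.ndarray:
    return sps.rankdata(v, method="average")


def spearman(x, y) -> CorrelationResult:
    """Spearman's rs with a two-sided P value (midranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("Spearman correlation needs n >= 3")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values must be dropped by the caller")
    rx, ry = _rank(x), _rank(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("zero variance in a rank vector; rs undefined")
    rs = float(np.corrcoef(rx, ry)[0, 1])

    if n <= EXACT_N_MAX:
        # rs is linear in sum(rx * ry_perm), so enumerate via dot products
        perms = _permutation_index(n)
        dots = ry[perms] @ rx
        sx = rx.std()
        sy = ry.std()
        rs_all = (dots / n - rx.mean() * ry.mean()) / (sx * sy)
        p = float(np.mean(np.abs(rs_all) >= abs(rs) - 1e-12))
        return CorrelationResult(rs=rs, p_two_sided=p, n=n, method="exact-permutation")

    if abs(rs) >= 1.0 - 1e-12:
        return CorrelationResult(
            rs=rs,
            p_two_sided=2.0 / math.factorial(n),
            n=n,
            method="exact-permutation",
        )
    t = rs * math.sqrt((n - 2) / (1.0 - rs * rs))
    p = 2.0 * float(sps.t.sf(abs(t), df=n - 2))
    return CorrelationResult(
        rs=rs, p_two_sided=min(p, 1.0), n=n, method="t-approximation"
    )


def sem(values) -> float:
    """Standard error of the mean (sample SD with n-1 denominator / sqrt n)."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("SEM needs at least two values")
    return float(np.std(v, ddof=1) / math.sqrt(len(v)))
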
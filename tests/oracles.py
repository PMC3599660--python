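"""Independent reference computations used by the test suite.

Everything here is deliberately written without reusing the package's
code paths: arbitrary-precision summation of the exact-test formula,
exact rational tail sums for small counts, brute-force alignment
scoring, and the textbook Welch t statistic.
"""

from __future__ import annotations

import math
from fractions import Fraction

import mpmath as mp

_DPS = 60


def mp_pmf(y: int, x: int, n1: int, n2: int) -> mp.mpf:
    """Direct arbitrary-precision evaluation of p(y|x)."""
    with mp.workdps(_DPS):
        r = mp.mpf(n2) / n1
        return r**y * mp.binomial(x + y, y) / (1 + r) ** (x + y + 1)


def mp_lower_tail(x: int, y: int, n1: int, n2: int) -> mp.mpf:
    with mp.workdps(_DPS):
        r = mp.mpf(n2) / n1
        q = r / (1 + r)
        t = (1 + r) ** mp.mpf(-(x + 1))  # p(0|x)
        s = mp.mpf(0)
        for k in range(y + 1):
            s += t
            t = t * (x + k + 1) / (k + 1) * q
        return s


def mp_upper_tail(x: int, y: int, n1: int, n2: int) -> mp.mpf:
    with mp.workdps(_DPS):
        r = mp.mpf(n2) / n1
        q = r / (1 + r)
        t = r**y * mp.binomial(x + y, y) / (1 + r) ** (x + y + 1)
        s = mp.mpf(0)
        mean = (x + 1) * float(r)
        k = y
        while True:
            s += t
            t = t * (x + k + 1) / (k + 1) * q
            k += 1
            if k > mean and t < s * mp.mpf("1e-45"):
                return s


def mp_two_sided(x: int, y: int, n1: int, n2: int) -> mp.mpf:
    with mp.workdps(_DPS):
        p = 2 * min(mp_lower_tail(x, y, n1, n2), mp_upper_tail(x, y, n1, n2))
        return min(mp.mpf(1), p)


def rational_pmf(y: int, x: int, n1: int, n2: int) -> Fraction:
    """Exact rational p(y|x) for small counts."""
    r = Fraction(n2, n1)
    return r**y * Fraction(math.comb(x + y, y)) / (1 + r) ** (x + y + 1)


def rational_lower_tail(x: int, y: int, n1: int, n2: int) -> Fraction:
    return sum(rational_pmf(k, x, n1, n2) for k in range(y + 1))


def brute_force_match(tag: str, ref: str, max_sub: int = 2, max_shift: int = 2):
    """Enumerate every shift; return the best (mismatches, offset) hit."""
    hits = []
    for off in range(-max_shift, max_shift + 1):
        pairs = [
            (ref[r], tag[r - off])
            for r in range(max(0, off), min(len(ref), off + len(tag)))
        ]
        if len(pairs) < max(1, min(len(tag), len(ref)) - max_shift):
            continue
        mism = sum(a != b for a, b in pairs)
        if mism <= max_sub:
            hits.append((mism, abs(off), off))
    if not hits:
        return None
    mism, _, off = min(hits)
    return (mism, off)


def brute_force_trim(read: str, adapter: str, min_overlap: int, rate: float):
    """Enumerate all adapter placements; apply the scoring rule literally."""
    candidates = []
    for pos in range(len(read) - min_overlap + 1):
        span = min(len(adapter), len(read) - pos)
        mism = sum(a != b for a, b in zip(read[pos : pos + span], adapter[:span]))
        if mism <= rate * span:
            candidates.append((-span, mism, pos))
    if not candidates:
        return None
    return read[: min(candidates)[2]]


def welch_t_pvalue(a, b) -> float:
    """Textbook Welch statistic with Welch-Satterthwaite degrees of freedom."""
    import numpy as np
    from scipy.stats import t as t_dist

    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return 2 * t_dist.sf(abs(t), df)
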
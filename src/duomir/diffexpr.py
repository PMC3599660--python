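"""Normalization, exact count-based differential expression and reporting.

Counts from two pooled libraries (one per condition, no replicates) are
normalized to reads per million (NE = count / clean_total * 1e6).  A zero
NE is revised to 0.01 before the log2 fold change log2(NE_A / NE_B);
records whose NE stays below 1 in both libraries are excluded from
testing.  Significance comes from the exact conditional test on raw
counts: given x reads of a miRNA among N1 clean reads in library 1, the
count y among N2 clean reads in library 2 follows

    p(y|x) = (N2/N1)^y * (x+y)! / (x! y!) * (1 + N2/N1)^-(x+y+1),

the negative-binomial distribution with x+1 successes and success
probability N1/(N1+N2).  Lower (C) and upper (D) tail sums of p(y|x)
give one-sided P-values; the default two-sided P doubles the smaller
tail (capped at 1).  Records are labelled "**" (|log2 FC| > 1 and
P < 0.01), "*" (|log2 FC| > 1 and 0.01 <= P < 0.05) or "none".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

SIDEDNESS = ("lower", "upper", "two_sided_min_doubled")


@dataclass(frozen=True)
class TailTestInput:
    """The (x, y, N1, N2) quadruple of the exact test."""

    x: int
    y: int
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError("library totals must be positive")
        if not (0 <= self.x <= self.n1 and 0 <= self.y <= self.n2):
            raise ValueError("counts must satisfy 0 <= x <= N1 and 0 <= y <= N2")


def normalize(count: int, total_clean: int) -> float:
    """Reads-per-million normalized expression: count / total * 1e6."""
    if total_clean <= 0:
        raise ValueError("total clean read count must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / total_clean * 1e6


def apply_zero_rule(ne_a: float, ne_b: float) -> tuple[float, float]:
    """Revise a zero normalized expression to 0.01; nonzero values pass."""
    return (0.01 if ne_a == 0 else ne_a, 0.01 if ne_b == 0 else ne_b)


def expression_floor(ne_a: float, ne_b: float, floor: float = 1.0) -> bool:
    """Keep a record iff at least one library reaches the NE floor.

    Excluding only when both values are sub-floor keeps library-specific
    miRNAs (absent-library NE revised to 0.01) testable.
    """
    return max(ne_a, ne_b) >= floor


def fold_change(ne_a: float, ne_b: float) -> float:
    """log2(NE_A / NE_B); library A is the treatment."""
    if ne_a <= 0 or ne_b <= 0:
        raise ValueError("fold change requires positive normalized expressions")
    return math.log2(ne_a / ne_b)


def _log_pmf(ks: np.ndarray, x: int, n1: int, n2: int) -> np.ndarray:
    log_r = math.log(n2) - math.log(n1)
    log_1pr = math.log1p(n2 / n1)
    return (
        ks * log_r
        + gammaln(x + ks + 1)
        - gammaln(x + 1)
        - gammaln(ks + 1)
        - (x + ks + 1) * log_1pr
    )


def ac_probability(y: int, x: int, n1: int, n2: int) -> float:
    """p(y|x): probability of y counts in library 2 given x in library 1.

    Evaluated through log-gamma, so counts up to 1e7 cannot overflow;
    values below the double-precision floor underflow to 0.0 (use
    :func:`ac_log_probability` for those).
    """
    return float(np.exp(ac_log_probability(y, x, n1, n2)))


def ac_log_probability(y: int, x: int, n1: int, n2: int) -> float:
    # the conditional law is defined for every y >= 0, beyond N2 included
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    return float(_log_pmf(np.asarray([y]), x, n1, n2)[0])


def _log_lower_tail(x: int, y: int, n1: int, n2: int) -> float:
    ks = np.arange(0, y + 1)
    return float(logsumexp(_log_pmf(ks, x, n1, n2)))


def _log_upper_tail(x: int, y: int, n1: int, n2: int) -> float:
    """log of sum_{k >= y} p(k|x), summed directly in log space.

    Chunked summation; terminates once past the distribution mean with a
    geometric bound on the remaining mass below 1e-17 of the accumulated
    sum.
    """
    q = n2 / (n1 + n2)
    mean = (x + 1) * n2 / n1
    total = -np.inf
    k0 = y
    # first chunk sized to reach past the mode plus a dispersion margin,
    # so typical calls finish in one pass
    chunk = max(64, int(mean - y + 12.0 * math.sqrt(mean + 1.0) + 16.0))
    while True:
        ks = np.arange(k0, k0 + chunk)
        lt = _log_pmf(ks, x, n1, n2)
        total = np.logaddexp(total, logsumexp(lt))
        k_last = k0 + chunk - 1
        ratio = (x + k_last + 1) / (k_last + 1) * q
        if k_last > mean and ratio < 1.0:
            log_rest = lt[-1] + math.log(ratio / (1.0 - ratio))
            if log_rest < total + math.log(1e-17):
                break
        k0 += chunk
        chunk = 1024
    return float(total)


def ac_pvalue(
    x: int,
    y: int,
    n1: int,
    n2: int,
    sided: str = "two_sided_min_doubled",
    log: bool = False,
) -> float:
    """Exact-test P-value for observing y given x.

    ``lower`` is C(y' <= y | x), ``upper`` is D(y' >= y | x);
    ``two_sided_min_doubled`` is min(1, 2 * min(C, D)).  With
    ``log=True`` the natural log of the P-value is returned, which stays
    meaningful when the tail underflows double precision.
    """
    TailTestInput(x, y, n1, n2)
    if sided not in SIDEDNESS:
        raise ValueError(f"sided must be one of {SIDEDNESS}")
    if sided in ("lower", "two_sided_min_doubled"):
        log_lower = _log_lower_tail(x, y, n1, n2)
    if sided in ("upper", "two_sided_min_doubled"):
        log_upper = _log_upper_tail(x, y, n1, n2)
    if sided == "lower":
        log_p = log_lower
    elif sided == "upper":
        log_p = log_upper
    else:
        log_p = math.log(2.0) + min(log_lower, log_upper)
    log_p = min(log_p, 0.0)
    return log_p if log else float(min(1.0, np.exp(log_p)))


def label_significance(fc: float, p_value: float) -> str:
    """Additional-file-6 label rule: ** / * / none."""
    if not (math.isfinite(fc) and math.isfinite(p_value)):
        raise ValueError("fold change and P-value must be finite")
    if abs(fc) > 1.0 and p_value < 0.01:
        return "**"
    if abs(fc) > 1.0 and 0.01 <= p_value < 0.05:
        return "*"
    return "none"


def percent(part: int, whole: int) -> float:
    """100 * part / whole, rounded half-up to two decimals."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    if not 0 <= part <= whole:
        raise ValueError("part must lie in [0, whole]")
    return float(
        (Decimal(100 * part) / Decimal(whole)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


def _category(count_a: int, count_b: int) -> str:
    if count_a > 0 and count_b == 0:
        return "A_specific"
    if count_b > 0 and count_a == 0:
        return "B_specific"
    return "co_expressed"


def build_expression_table(
    counts: pd.DataFrame,
    total_a: int,
    total_b: int,
    floor: float = 1.0,
    sided: str = "two_sided_min_doubled",
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Per-record normalization, fold change, exact test and labels.

    ``counts`` needs columns ``record_id``, ``count_A``, ``count_B`` (raw
    read counts of each miRNA or miRNA* product).  The exact test runs on
    raw counts with the library clean totals; NE values (zero-revised)
    feed the fold change and the floor rule.  Excluded records keep their
    fold change but carry no P-value.  ``bh_correction`` optionally adds
    Benjamini-Hochberg adjusted values in a ``q_value`` column (off by
    default: the original analysis applies no correction).
    """
    rows = []
    for rec in counts.itertuples(index=False):
        ca, cb = int(rec.count_A), int(rec.count_B)
        ne_a, ne_b = apply_zero_rule(normalize(ca, total_a), normalize(cb, total_b))
        included = expression_floor(ne_a, ne_b, floor)
        fc = fold_change(ne_a, ne_b)
        p = ac_pvalue(ca, cb, total_a, total_b, sided=sided) if included else np.nan
        label = label_significance(fc, p) if included else "none"
        rows.append(
            {
                "record_id": rec.record_id,
                "count_A": ca,
                "count_B": cb,
                "ne_A": ne_a,
                "ne_B": ne_b,
                "fold_change": fc,
                "p_value": p,
                "sig_label": label,
                "category": _category(ca, cb),
                "included": included,
            }
        )
    table = pd.DataFrame(rows)
    if bh_correction and len(table):
        from scipy.stats import false_discovery_control

        mask = table["included"].to_numpy()
        q = np.full(len(table), np.nan)
        if mask.any():
            q[mask] = false_discovery_control(table.loc[mask, "p_value"], method="bh")
        table["q_value"] = q
    return table


def categorize(table: pd.DataFrame) -> dict:
    """Venn categories and up/down tallies with reporting percentages.

    A record is library-specific when its raw count is zero in exactly
    one library; significant means sig_label != "none"; up/down splits
    significant records by fold-change sign.
    """
    n = len(table)
    if n == 0:
        return {
            "n_total": 0,
            "co_expressed": 0,
            "A_specific": 0,
            "B_specific": 0,
            "co_expressed_pct": None,
            "A_specific_pct": None,
            "B_specific_pct": None,
            "significant": 0,
            "significant_pct": None,
            "up": 0,
            "down": 0,
        }
    cats = table["category"].value_counts()
    sig = table[table["sig_label"] != "none"]
    summary = {
        "n_total": n,
        "co_expressed": int(cats.get("co_expressed", 0)),
        "A_specific": int(cats.get("A_specific", 0)),
        "B_specific": int(cats.get("B_specific", 0)),
        "significant": len(sig),
        "up": int((sig["fold_change"] > 0).sum()),
        "down": int((sig["fold_change"] < 0).sum()),
    }
    for key in ("co_expressed", "A_specific", "B_specific", "significant"):
        summary[f"{key}_pct"] = percent(summary[key], n)
    return summary


def top_n(table: pd.DataFrame, library: str, n: int = 10) -> pd.DataFrame:
    """Records ranked by NE in one library ('A' or 'B'), ties by id."""
    if library not in ("A", "B"):
        raise ValueError("library must be 'A' or 'B'")
    if n < 1:
        raise ValueError("n must be >= 1")
    col = f"ne_{library}"
    ranked = table.sort_values(
        [col, "record_id"], ascending=[False, True], kind="mergesort"
    )
    return ranked.head(n)[["record_id", "ne_A", "ne_B", "fold_change"]].reset_index(
        drop=True
    )
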
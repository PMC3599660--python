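"""qPCR validation arithmetic: U6-normalized expression and group tests.

Relative expression of a target miRNA against the U6 snRNA reference is
2^-(Ct_target - Ct_U6); technical replicates are averaged on the Ct
scale first.  Groups (A = treatment, B = control) are compared per
target with Welch's t-test on per-sample relative expressions, and the
log2 ratio of group means is checked for sign concordance with the
sequencing fold change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ["sample_id", "group", "target", "tech_rep", "ct_target", "ct_u6"]


class InsufficientReplicatesError(ValueError):
    pass


@dataclass(frozen=True)
class QpcrMeasurement:
    sample_id: str
    group: str  # "A" or "B"
    target: str
    ct_target: float
    ct_reference: float
    tech_rep: int = 1

    def __post_init__(self) -> None:
        if self.group not in ("A", "B"):
            raise ValueError("group must be 'A' or 'B'")
        for name in ("ct_target", "ct_reference"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive")


@dataclass(frozen=True)
class QpcrResult:
    target: str
    log2_ratio: float
    p_value: float
    significant: bool
    mean_a: float
    mean_b: float


def relative_expression(ct_target: float, ct_reference: float) -> float:
    """2^-(Ct_target - Ct_reference); one extra cycle halves expression."""
    return float(2.0 ** -(ct_target - ct_reference))


def _per_sample_expressions(measurements: list[QpcrMeasurement]) -> dict[str, list[float]]:
    """Average technical replicates on the Ct scale, then exponentiate."""
    by_sample: dict[tuple[str, str], list[QpcrMeasurement]] = {}
    for m in measurements:
        by_sample.setdefault((m.group, m.sample_id), []).append(m)
    groups: dict[str, list[float]] = {"A": [], "B": []}
    for (group, _), ms in sorted(by_sample.items()):
        ct_t = float(np.mean([m.ct_target for m in ms]))
        ct_r = float(np.mean([m.ct_reference for m in ms]))
        groups[group].append(relative_expression(ct_t, ct_r))
    return groups


def compare_groups(measurements: list[QpcrMeasurement], alpha: float = 0.05) -> QpcrResult:
    """Welch t-test of per-sample relative expressions between groups.

    Needs at least two biological replicates (samples) per group.  When
    both groups are zero-variance constants the degenerate P-value is 1
    for equal means and 0 otherwise.
    """
    targets = {m.target for m in measurements}
    if len(targets) != 1:
        raise ValueError(f"measurements must cover exactly one target, got {targets}")
    target = targets.pop()
    groups = _per_sample_expressions(measurements)
    a, b = np.asarray(groups["A"]), np.asarray(groups["B"])
    if len(a) < 2 or len(b) < 2:
        raise InsufficientReplicatesError(
            f"{target}: need >=2 biological replicates per group "
            f"(got {len(a)} in A, {len(b)} in B)"
        )
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    log2_ratio = float(np.log2(a.mean() / b.mean()))
    return QpcrResult(target, log2_ratio, p, p < alpha, float(a.mean()), float(b.mean()))


def read_ct_table(path: str) -> list[QpcrMeasurement]:
    """Load a Ct TSV with columns sample_id, group, target, tech_rep,
    ct_target, ct_u6."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    return [
        QpcrMeasurement(
            sample_id=str(r.sample_id),
            group=str(r.group),
            target=str(r.target),
            ct_target=float(r.ct_target),
            ct_reference=float(r.ct_u6),
            tech_rep=int(r.tech_rep),
        )
        for r in df.itertuples(index=False)
    ]


def analyze_ct_table(measurements: list[QpcrMeasurement]) -> list[QpcrResult]:
    by_target: dict[str, list[QpcrMeasurement]] = {}
    for m in measurements:
        by_target.setdefault(m.target, []).append(m)
    return [compare_groups(by_target[t]) for t in sorted(by_target)]


def concordance(
    results: list[QpcrResult], expression_table: pd.DataFrame
) -> pd.DataFrame:
    """Sign agreement between qPCR log2 ratios and sequencing fold changes.

    Targets missing from the sequencing table are reported with
    ``status="missing"`` rather than failing; the summary fraction covers
    matched targets only (available via the ``concordant`` column).
    """
    seq_fc = expression_table.set_index("record_id")["fold_change"]
    rows = []
    for res in results:
        if res.target in seq_fc.index:
            fc = float(seq_fc[res.target])
            rows.append(
                {
                    "target": res.target,
                    "qpcr_log2_ratio": res.log2_ratio,
                    "seq_fold_change": fc,
                    "concordant": np.sign(res.log2_ratio) == np.sign(fc),
                    "status": "matched",
                }
            )
        else:
            rows.append(
                {
                    "target": res.target,
                    "qpcr_log2_ratio": res.log2_ratio,
                    "seq_fold_change": np.nan,
                    "concordant": pd.NA,
                    "status": "missing",
                }
            )
    return pd.DataFrame(rows)


def results_to_frame(results: list[QpcrResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def plot_log2_ratios(
    results: list[QpcrResult],
    expression_table: pd.DataFrame | None = None,
    path: str | None = None,
):
    """Bar plot of qPCR log2 ratios, optionally beside sequencing fold
    changes for the same targets."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    targets = [r.target for r in results]
    x = np.arange(len(targets))
    fig, ax = plt.subplots(figsize=(1.2 * len(targets) + 2, 4))
    width = 0.38 if expression_table is not None else 0.6
    ax.bar(x, [r.log2_ratio for r in results], width, label="qPCR", color="0.3")
    if expression_table is not None:
        seq_fc = expression_table.set_index("record_id")["fold_change"]
        seq = [float(seq_fc.get(t, np.nan)) for t in targets]
        ax.bar(x + width, seq, width, label="sequencing", color="0.7")
        ax.legend()
    ax.axhline(0, color="black", lw=0.8)
    ax.set_xticks(x + (width / 2 if expression_table is not None else 0))
    ax.set_xticklabels(targets, rotation=45, ha="right")
    ax.set_ylabel("log2 ratio (A / B)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
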
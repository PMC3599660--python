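"""End-to-end orchestration: preprocess -> annotate -> diffexpr -> report.

A run directory holds one TSV per stage artifact plus a human-readable
summary; every number in the summary is recomputed from the stage TSVs
(only sorting and percentage formatting happen at report time), and a
rerun with the same config writes byte-identical artifacts.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import annotate, diffexpr, preprocess
from .catalog import read_catalog, read_contaminants

ARTIFACTS = (
    "clean_stats.tsv",
    "length_distribution.tsv",
    "mirna_counts.tsv",
    "composition_A.tsv",
    "composition_B.tsv",
    "duplex_pairs.tsv",
    "expression.tsv",
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    fastq_a: str
    fastq_b: str
    catalog_fasta: str
    arm_table: str
    contaminant_fastas: dict[str, str]
    out_dir: str
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    five_prime_adapter: str | None = None
    quality_threshold: int = 20
    max_low_quality_frac: float = 0.2
    max_n: int = 2
    min_len: int = 15
    max_len: int = 35
    min_overlap: int = 6
    max_mismatch_rate: float = 0.1
    priority: tuple[str, ...] = annotate.DEFAULT_PRIORITY
    max_sub: int = 2
    max_shift: int = 2
    sided: str = "two_sided_min_doubled"
    floor: float = 1.0
    bh_correction: bool = False
    seed: int = 0
    log: list[str] = field(default_factory=list, repr=False)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "priority" in raw:
            raw["priority"] = tuple(raw["priority"])
        return cls(**raw)

    def validate(self) -> None:
        paths = [self.fastq_a, self.fastq_b, self.catalog_fasta, self.arm_table]
        paths += list(self.contaminant_fastas.values())
        missing = [p for p in paths if not os.path.exists(p)]
        if missing:
            raise PipelineError("config", f"missing input files: {missing}")
        if not 0 < self.min_len <= self.max_len:
            raise PipelineError("config", "length window must satisfy 0 < min <= max")
        if self.sided not in diffexpr.SIDEDNESS:
            raise PipelineError("config", f"unknown test sidedness {self.sided!r}")

    def _log(self, message: str) -> None:
        self.log.append(message)


def run_pipeline(config: PipelineConfig) -> str:
    """Execute all stages; returns the run directory."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    out = config.out_dir

    # --- preprocess ---------------------------------------------------
    clean: dict[str, list[str]] = {}
    stats: dict[str, preprocess.CleanStats] = {}
    tags: dict[str, list[preprocess.UniqueTag]] = {}
    lengths = []
    try:
        for lib, path in (("A", config.fastq_a), ("B", config.fastq_b)):
            reads = preprocess.read_fastq(path)
            clean[lib], stats[lib] = preprocess.clean_reads(
                reads,
                adapter=config.adapter,
                quality_threshold=config.quality_threshold,
                max_low_quality_frac=config.max_low_quality_frac,
                max_n=config.max_n,
                five_prime_adapter=config.five_prime_adapter,
                min_overlap=config.min_overlap,
                max_mismatch_rate=config.max_mismatch_rate,
                min_len=config.min_len,
                max_len=config.max_len,
            )
            tags[lib] = preprocess.collapse(clean[lib])
            preprocess.write_collapsed_fasta(
                tags[lib], os.path.join(out, f"tags_{lib}.fa")
            )
            for length, frac in preprocess.length_distribution(clean[lib]).items():
                lengths.append({"library": lib, "length": length, "fraction": frac})
            config._log(
                f"preprocess[{lib}]: {stats[lib].total_raw} raw -> "
                f"{stats[lib].clean_total} clean ({stats[lib].unique_count} unique)"
            )
    except Exception as exc:
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError("preprocess", str(exc)) from exc
    preprocess.clean_stats_to_frame(stats).to_csv(
        os.path.join(out, "clean_stats.tsv"), sep="\t"
    )
    pd.DataFrame(lengths).to_csv(
        os.path.join(out, "length_distribution.tsv"), sep="\t", index=False
    )

    # --- annotate -----------------------------------------------------
    try:
        catalog = read_catalog(config.catalog_fasta, config.arm_table)
        contaminants = read_contaminants(config.contaminant_fastas)
        annotations = {
            lib: annotate.classify_tags(
                tags[lib],
                contaminants,
                catalog,
                priority=config.priority,
                max_sub=config.max_sub,
                max_shift=config.max_shift,
            )
            for lib in ("A", "B")
        }
        counts = annotate.aggregate_mirna_counts(annotations)
        duplexes = annotate.find_duplex_pairs(counts)
        for lib in ("A", "B"):
            annotate.annotations_to_frame(annotations[lib]).to_csv(
                os.path.join(out, f"annotations_{lib}.tsv"), sep="\t", index=False
            )
            comp = annotate.composition_summary(annotations[lib])
            comp.index.name = "rna_class"
            comp.to_csv(os.path.join(out, f"composition_{lib}.tsv"), sep="\t")
        annotate.mirna_counts_to_frame(counts).to_csv(
            os.path.join(out, "mirna_counts.tsv"), sep="\t", index=False
        )
        pd.DataFrame(
            [
                {"library": lib, "mirna_id": mid}
                for lib in sorted(duplexes)
                for mid in duplexes[lib]
            ],
            columns=["library", "mirna_id"],
        ).to_csv(os.path.join(out, "duplex_pairs.tsv"), sep="\t", index=False)
        config._log(f"annotate: {len(counts)} miRNAs with assigned reads")
    except Exception as exc:
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError("annotate", str(exc)) from exc

    # --- diffexpr -----------------------------------------------------
    try:
        records = []
        for mc in counts:
            records.append(
                {
                    "record_id": mc.mirna_id,
                    "count_A": mc.mature.get("A", 0),
                    "count_B": mc.mature.get("B", 0),
                }
            )
            if sum(mc.star.values()) > 0:
                records.append(
                    {
                        "record_id": mc.mirna_id + "*",
                        "count_A": mc.star.get("A", 0),
                        "count_B": mc.star.get("B", 0),
                    }
                )
        record_df = pd.DataFrame(records, columns=["record_id", "count_A", "count_B"])
        record_df = record_df[(record_df.count_A > 0) | (record_df.count_B > 0)]
        table = diffexpr.build_expression_table(
            record_df,
            total_a=stats["A"].clean_total,
            total_b=stats["B"].clean_total,
            floor=config.floor,
            sided=config.sided,
            bh_correction=config.bh_correction,
        )
        table.to_csv(os.path.join(out, "expression.tsv"), sep="\t", index=False)
        summary = diffexpr.categorize(table)
        config._log(
            f"diffexpr: {summary['n_total']} records, "
            f"{summary['significant']} significant"
        )
    except Exception as exc:
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError("diffexpr", str(exc)) from exc

    with open(os.path.join(out, "summary.txt"), "w") as fh:
        fh.write(make_report(out))
    with open(os.path.join(out, "pipeline.log"), "w") as fh:
        fh.write("\n".join(config.log) + "\n")
    return out


def make_report(run_dir: str) -> str:
    """Render the human-readable summary from a completed run directory."""
    missing = [a for a in ARTIFACTS if not os.path.exists(os.path.join(run_dir, a))]
    if missing:
        raise PipelineError("report", f"incomplete run directory, missing: {missing}")
    stats = pd.read_csv(os.path.join(run_dir, "clean_stats.tsv"), sep="\t", index_col=0)
    table = pd.read_csv(os.path.join(run_dir, "expression.tsv"), sep="\t")
    duplexes = pd.read_csv(os.path.join(run_dir, "duplex_pairs.tsv"), sep="\t")
    summary = diffexpr.categorize(table)

    lines = ["# Two-library small RNA differential expression summary", ""]
    for lib in stats.index:
        row = stats.loc[lib]
        lines.append(
            f"library {lib}: {int(row.total_raw)} raw reads, "
            f"{int(row.clean_total)} clean, {int(row.unique_count)} unique tags"
        )
    lines.append("")
    n = summary["n_total"]
    lines.append(f"unique miRNA/miRNA* records: {n}")
    if n:
        lines.append(
            f"co-expressed: {summary['co_expressed']} ({summary['co_expressed_pct']}%)"
        )
        lines.append(
            f"A-specific: {summary['A_specific']} ({summary['A_specific_pct']}%)"
        )
        lines.append(
            f"B-specific: {summary['B_specific']} ({summary['B_specific_pct']}%)"
        )
        lines.append(
            f"significant: {summary['significant']} ({summary['significant_pct']}%), "
            f"up {summary['up']} / down {summary['down']}"
        )
        for lib in ("A", "B"):
            lines.append("")
            lines.append(f"top 10 by normalized expression in library {lib}:")
            for rec in diffexpr.top_n(table, lib, 10).itertuples(index=False):
                lines.append(
                    f"  {rec.record_id}\tNE_A={rec.ne_A:.2f}\tNE_B={rec.ne_B:.2f}"
                    f"\tlog2FC={rec.fold_change:+.2f}"
                )
    else:
        lines.append("no miRNAs detected")
    lines.append("")
    lines.append(f"duplex-like miRNA:miRNA* pairs: {len(duplexes)}")
    for rec in duplexes.itertuples(index=False):
        lines.append(f"  library {rec.library}: {rec.mirna_id}")
    return "\n".join(lines) + "\n"
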
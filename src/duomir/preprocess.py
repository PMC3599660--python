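"""Raw-read cleaning, tag collapsing and length summaries.

Cleaning follows a fixed order: whole-read quality filter, 5'-adapter
contaminant removal, 3' adapter trimming (reads without a recognizable
adapter are dropped), then an insert length window.  The surviving
"clean reads" define the normalization denominator used downstream;
identical clean reads are collapsed into unique tags with counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple

import pandas as pd
from Bio import SeqIO


class ReadRecord(NamedTuple):
    id: str
    seq: str
    qual: str  # Sanger-encoded quality string (offset 33)


class FastqParseError(ValueError):
    pass


def read_fastq(path: str) -> Iterator[ReadRecord]:
    """Iterate FASTQ records; parse failures name the record index."""
    index = 0
    try:
        for rec in SeqIO.parse(path, "fastq"):
            quals = rec.letter_annotations["phred_quality"]
            yield ReadRecord(
                rec.id,
                str(rec.seq).upper(),
                "".join(chr(q + 33) for q in quals),
            )
            index += 1
    except ValueError as exc:
        raise FastqParseError(f"malformed FASTQ record at index {index}: {exc}") from exc


def write_fastq(reads: Iterable[ReadRecord], path: str) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")


@dataclass
class CleanStats:
    """Read accounting through the cleaning pipeline.

    ``clean_total`` is the "N" used as the reads-per-million denominator.
    """

    total_raw: int = 0
    removed_low_quality: int = 0
    removed_no_adapter: int = 0
    removed_5prime_contaminant: int = 0
    removed_length: int = 0
    clean_total: int = 0
    unique_count: int = 0

    def validate(self) -> None:
        removed = (
            self.removed_low_quality
            + self.removed_no_adapter
            + self.removed_5prime_contaminant
            + self.removed_length
        )
        if self.clean_total != self.total_raw - removed:
            raise ValueError(
                f"count accounting broken: {self.total_raw} raw != "
                f"{self.clean_total} clean + {removed} removed"
            )
        for name, value in vars(self).items():
            if value < 0:
                raise ValueError(f"{name} is negative")


@dataclass(frozen=True, order=True)
class UniqueTag:
    seq: str
    count: int = field(compare=False, default=0)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def trim_adapter(
    read_seq: str,
    adapter: str,
    min_overlap: int = 6,
    max_mismatch_rate: float = 0.1,
) -> str | None:
    """Return the insert preceding the best 3' adapter match, or ``None``.

    Candidate matches place the adapter at every position of the read;
    matches running off the read end count if at least ``min_overlap``
    bases align.  A candidate is valid when its mismatch fraction over the
    aligned span is <= ``max_mismatch_rate``.  Among valid candidates the
    longest overlap wins, then fewest mismatches, then the leftmost
    position (deterministic tie-break).
    """
    if len(adapter) < min_overlap:
        raise ValueError("adapter shorter than min_overlap")
    read = read_seq.upper()
    adapter = adapter.upper()
    best: tuple[int, int, int] | None = None  # (-overlap, mismatches, position)
    for pos in range(0, len(read) - min_overlap + 1):
        overlap = min(len(adapter), len(read) - pos)
        mism = _hamming(read[pos : pos + overlap], adapter[:overlap])
        if mism <= max_mismatch_rate * overlap:
            cand = (-overlap, mism, pos)
            if best is None or cand < best:
                best = cand
    if best is None:
        return None
    return read[: best[2]]


def is_low_quality(
    read: ReadRecord,
    quality_threshold: int = 20,
    max_low_quality_frac: float = 0.2,
    max_n: int = 2,
) -> bool:
    """A read fails if >``max_low_quality_frac`` of bases are below the
    Phred threshold or it contains more than ``max_n`` ambiguous bases."""
    if read.seq.count("N") > max_n:
        return True
    if not read.qual:
        return False
    n_low = sum(1 for c in read.qual if ord(c) - 33 < quality_threshold)
    return n_low > max_low_quality_frac * len(read.qual)


def _matches_5prime(seq: str, p5_adapter: str, min_overlap: int, rate: float) -> bool:
    overlap = min(len(seq), len(p5_adapter))
    if overlap < min_overlap:
        return False
    return _hamming(seq[:overlap], p5_adapter[:overlap]) <= rate * overlap


def clean_reads(
    reads: Iterable[ReadRecord],
    adapter: str,
    quality_threshold: int = 20,
    max_low_quality_frac: float = 0.2,
    max_n: int = 2,
    five_prime_adapter: str | None = None,
    min_overlap: int = 6,
    max_mismatch_rate: float = 0.1,
    min_len: int = 15,
    max_len: int = 35,
) -> tuple[list[str], CleanStats]:
    """Run the full cleaning cascade; returns clean inserts plus accounting.

    Pipeline order is fixed: quality filter -> 5'-adapter contaminant
    removal -> 3' adapter trim (no-adapter reads dropped) -> length window
    ``[min_len, max_len]``.  Reads trimming to an empty or sub-length
    insert (pure adapter) are counted under ``removed_length``.
    """
    stats = CleanStats()
    clean: list[str] = []
    adapter = adapter.upper()
    for read in reads:
        stats.total_raw += 1
        if is_low_quality(read, quality_threshold, max_low_quality_frac, max_n):
            stats.removed_low_quality += 1
            continue
        if five_prime_adapter is not None and _matches_5prime(
            read.seq, five_prime_adapter.upper(), min_overlap, max_mismatch_rate
        ):
            stats.removed_5prime_contaminant += 1
            continue
        insert = trim_adapter(read.seq, adapter, min_overlap, max_mismatch_rate)
        if insert is None:
            stats.removed_no_adapter += 1
            continue
        if not min_len <= len(insert) <= max_len:
            stats.removed_length += 1
            continue
        clean.append(insert)
    stats.clean_total = len(clean)
    stats.unique_count = len(set(clean))
    stats.validate()
    return clean, stats


def collapse(clean_reads: Iterable[str]) -> list[UniqueTag]:
    """Group identical reads into unique tags.

    Sorted by descending count, ties broken lexicographically; total
    counts conserve the number of input reads.
    """
    counts: dict[str, int] = {}
    for seq in clean_reads:
        counts[seq] = counts.get(seq, 0) + 1
    return [
        UniqueTag(seq, n)
        for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def length_distribution(clean_reads: Iterable[str]) -> dict[int, float]:
    """Fraction of reads at each insert length; fractions sum to 1."""
    counts: dict[int, int] = {}
    total = 0
    for seq in clean_reads:
        counts[len(seq)] = counts.get(len(seq), 0) + 1
        total += 1
    if total == 0:
        raise ValueError("length_distribution of empty read list")
    return {length: n / total for length, n in sorted(counts.items())}


def write_collapsed_fasta(tags: list[UniqueTag], path: str) -> None:
    """Collapsed-FASTA dialect: headers ``tag{rank}_x{count}``."""
    with open(path, "w") as fh:
        for rank, tag in enumerate(tags, start=1):
            fh.write(f">tag{rank}_x{tag.count}\n{tag.seq}\n")


def read_collapsed_fasta(path: str) -> list[UniqueTag]:
    tags = []
    for rec in SeqIO.parse(path, "fasta"):
        count = int(rec.id.rsplit("_x", 1)[1])
        tags.append(UniqueTag(str(rec.seq).upper(), count))
    return tags


def clean_stats_to_frame(stats_by_library: dict[str, CleanStats]) -> pd.DataFrame:
    df = pd.DataFrame({lib: vars(s) for lib, s in stats_by_library.items()}).T
    df.index.name = "library"
    return df
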
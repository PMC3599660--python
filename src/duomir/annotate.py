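"""Classify unique tags into small-RNA classes and count miRNA/miRNA* reads.

Tags are assigned by a priority cascade: contaminant ncRNA classes (rRNA,
tRNA, snRNA, snoRNA, repeat) are checked first, then known miRNAs;
anything left is unannotated.  Contaminant hits require the tag to be a
full substring of a reference with at most one mismatch.  miRNA hits use
a mismatch-tolerant, indel-free alignment against catalog arm sequences:
up to ``max_sub`` substitutions, with the tag start allowed to shift by
up to ``max_shift`` nt relative to the arm (isomiR-style 5'/3' wobble).
A tag matching the arm opposite the annotated mature arm is a miRNA*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import CONTAMINANT_CLASSES, HairpinEntry, normalize_seq
from .preprocess import UniqueTag

DEFAULT_PRIORITY = ("rRNA", "tRNA", "snRNA", "snoRNA", "repeat", "miRNA")

#: classes that partition the tag set in a composition summary
PARTITION_CLASSES = (
    "rRNA",
    "tRNA",
    "snRNA",
    "snoRNA",
    "repeat",
    "miRNA",
    "miRNA_star",
    "unannotated",
)


@dataclass(frozen=True)
class TagAnnotation:
    """Class assignment of one unique tag."""

    tag: UniqueTag
    rna_class: str
    assigned_id: str | None = None
    n_mismatches: int | None = None
    offset: int | None = None


@dataclass
class MirnaCount:
    """Per-miRNA read counts, split by arm, keyed by library name."""

    mirna_id: str
    mature: dict[str, int]
    star: dict[str, int]


def match_tag(
    tag_seq: str,
    reference_seq: str,
    max_sub: int = 2,
    max_shift: int = 2,
) -> tuple[int, int] | None:
    """Best indel-free alignment of a tag against one reference sequence.

    The tag start may sit at offsets ``-max_shift .. +max_shift`` relative
    to the reference start.  A hit requires the aligned overlap to cover at
    least ``min(len(tag), len(ref)) - max_shift`` positions with at most
    ``max_sub`` mismatches.  Among hits the one with fewest mismatches is
    chosen, ties broken by smaller ``|offset|``, then by the negative
    offset.  Returns ``(n_mismatches, offset)`` or ``None``.
    """
    tag = normalize_seq(tag_seq)
    ref = normalize_seq(reference_seq)
    if not tag or not ref:
        raise ValueError("empty sequence")
    lt, lr = len(tag), len(ref)
    min_overlap = max(1, min(lt, lr) - max_shift)
    best: tuple[tuple[int, int, int], tuple[int, int]] | None = None
    for off in range(-max_shift, max_shift + 1):
        lo = max(0, off)
        hi = min(lr, off + lt)
        overlap = hi - lo
        if overlap < min_overlap:
            continue
        mism = 0
        for r in range(lo, hi):
            if ref[r] != tag[r - off]:
                mism += 1
                if mism > max_sub:
                    break
        if mism > max_sub:
            continue
        key = (mism, abs(off), off)
        if best is None or key < best[0]:
            best = (key, (mism, off))
    return None if best is None else best[1]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


class ArmIndex:
    """Vectorized mismatch-tolerant matcher of tags against catalog arms.

    Hits follow the same rules as :func:`match_tag`; when several arms tie
    on (mismatches, |offset|, offset), the arm occurring earlier in the
    catalog wins, with the mature arm of a hairpin ahead of its star arm.
    """

    def __init__(self, catalog: list[HairpinEntry], max_sub: int = 2, max_shift: int = 2):
        self.max_sub = max_sub
        self.max_shift = max_shift
        self.arms: list[tuple[str, str, str]] = []  # (mirna_id, kind, seq)
        for h in catalog:
            self.arms.append((h.id, "mature", h.mature_seq))
            self.arms.append((h.id, "star", h.star_seq))
        self._lens = np.array([len(s) for _, _, s in self.arms])
        lmax = int(self._lens.max()) if self.arms else 0
        self._mat = np.zeros((len(self.arms), lmax), dtype=np.uint8)
        for i, (_, _, s) in enumerate(self.arms):
            self._mat[i, : len(s)] = _encode(s)
        # exact-sequence fast path; first occurrence wins, matching the
        # catalog-order tie-break for (0, 0) hits
        self._exact: dict[str, int] = {}
        for i, (_, _, s) in enumerate(self.arms):
            self._exact.setdefault(s, i)

    def best_hit(self, tag_seq: str) -> tuple[str, str, int, int] | None:
        """Return ``(mirna_id, kind, n_mismatches, offset)`` or ``None``."""
        tag = normalize_seq(tag_seq)
        if not self.arms or not tag:
            return None
        i = self._exact.get(tag)
        if i is not None:
            mid, kind, _ = self.arms[i]
            return (mid, kind, 0, 0)
        t = _encode(tag)
        lt = len(t)
        lmax = self._mat.shape[1]
        min_ov = np.maximum(1, np.minimum(lt, self._lens) - self.max_shift)
        best_key = None
        best_arm = None
        for off in range(-self.max_shift, self.max_shift + 1):
            row = np.zeros(lmax, dtype=np.uint8)
            lo = max(0, off)
            hi = min(lmax, off + lt)
            if hi <= lo:
                continue
            row[lo:hi] = t[lo - off : hi - off]
            valid = (self._mat != 0) & (row != 0)
            mism = ((self._mat != row) & valid).sum(axis=1)
            ov = valid.sum(axis=1)
            ok = (ov >= min_ov) & (mism <= self.max_sub)
            for i in np.flatnonzero(ok):
                key = (int(mism[i]), abs(off), off, int(i))
                if best_key is None or key < best_key:
                    best_key = key
                    best_arm = (self.arms[i][0], self.arms[i][1], int(mism[i]), off)
        return best_arm


class ContaminantIndex:
    """Substring matcher (<=1 mismatch, full tag coverage) per ncRNA class."""

    _SEP = ord("#")

    def __init__(self, refs_by_class: dict[str, list[tuple[str, str]]]):
        self._classes: dict[str, tuple] = {}
        for cls, refs in refs_by_class.items():
            refs = [(rid, normalize_seq(seq)) for rid, seq in refs]
            concat = "#".join(seq for _, seq in refs)
            starts = []
            pos = 0
            for _, seq in refs:
                starts.append(pos)
                pos += len(seq) + 1
            arr = _encode(concat) if concat else np.zeros(0, dtype=np.uint8)
            sep_cum = np.concatenate([[0], np.cumsum(arr == self._SEP)])
            self._classes[cls] = (refs, concat, arr, np.array(starts), sep_cum)

    def classes(self):
        return self._classes.keys()

    def hit(self, tag_seq: str, cls: str) -> tuple[str, int] | None:
        """Return ``(ref_id, n_mismatches)`` if the tag sits fully inside a
        reference of the class with at most one mismatch."""
        refs, concat, arr, starts, sep_cum = self._classes[cls]
        if not refs:
            return None
        tag = normalize_seq(tag_seq)
        pos = concat.find(tag)  # exact fast path; tags never contain '#'
        if pos >= 0:
            return (refs[int(np.searchsorted(starts, pos, side="right")) - 1][0], 0)
        lt = len(tag)
        if lt > arr.size:
            return None
        windows = np.lib.stride_tricks.sliding_window_view(arr, lt)
        mism = (windows != _encode(tag)).sum(axis=1)
        # exclude windows spanning the '#' separators between references
        no_sep = (sep_cum[lt:] - sep_cum[:-lt]) == 0
        ok = np.flatnonzero(no_sep & (mism <= 1))
        if ok.size == 0:
            return None
        start = int(ok[0])
        return (refs[int(np.searchsorted(starts, start, side="right")) - 1][0],
                int(mism[start]))


def classify_tags(
    tags: list[UniqueTag],
    contaminant_refs: dict[str, list[tuple[str, str]]],
    catalog: list[HairpinEntry],
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
    max_sub: int = 2,
    max_shift: int = 2,
) -> list[TagAnnotation]:
    """Assign each tag the first class in ``priority`` where it has a hit.

    ``priority`` must list contaminant classes before ``"miRNA"``; the
    ``"miRNA"`` step covers both arms (class ``miRNA`` or ``miRNA_star``).
    Tags hitting nothing are ``unannotated``.  Classification of one tag
    does not depend on the others, so output order follows input order.
    """
    known = set(CONTAMINANT_CLASSES) | {"miRNA"}
    for cls in priority:
        if cls not in known:
            raise ValueError(f"unknown class in priority order: {cls!r}")
    if "miRNA" in priority:
        mirna_pos = priority.index("miRNA")
        late = [c for c in priority[mirna_pos + 1 :]]
        if late:
            raise ValueError(f"contaminant classes must precede miRNA: {late}")
    arm_index = ArmIndex(catalog, max_sub=max_sub, max_shift=max_shift)
    cont_index = ContaminantIndex(
        {cls: contaminant_refs.get(cls, []) for cls in priority if cls != "miRNA"}
    )
    out = []
    for tag in tags:
        ann = None
        for cls in priority:
            if cls == "miRNA":
                hit = arm_index.best_hit(tag.seq)
                if hit is not None:
                    mid, kind, mism, off = hit
                    rna_class = "miRNA" if kind == "mature" else "miRNA_star"
                    ann = TagAnnotation(tag, rna_class, mid, mism, off)
                    break
            else:
                chit = cont_index.hit(tag.seq, cls)
                if chit is not None:
                    ann = TagAnnotation(tag, cls, chit[0], chit[1], None)
                    break
        if ann is None:
            ann = TagAnnotation(tag, "unannotated")
        out.append(ann)
    return out


def aggregate_mirna_counts(
    annotations_by_library: dict[str, list[TagAnnotation]],
) -> list[MirnaCount]:
    """Sum tag counts per miRNA and arm for each library.

    Only miRNAs with at least one assigned read in some arm of some
    library appear in the output (sorted by id).
    """
    libs = list(annotations_by_library)
    acc: dict[str, MirnaCount] = {}
    for lib, annotations in annotations_by_library.items():
        for ann in annotations:
            if ann.rna_class not in ("miRNA", "miRNA_star"):
                continue
            mc = acc.get(ann.assigned_id)
            if mc is None:
                mc = MirnaCount(
                    ann.assigned_id,
                    {l: 0 for l in libs},
                    {l: 0 for l in libs},
                )
                acc[ann.assigned_id] = mc
            side = mc.mature if ann.rna_class == "miRNA" else mc.star
            side[lib] += ann.tag.count
    return [acc[k] for k in sorted(acc)]


def find_duplex_pairs(
    counts: list[MirnaCount], min_count: int = 1
) -> dict[str, list[str]]:
    """miRNAs whose mature and star arm are both detected in a library.

    Returns library -> sorted list of miRNA ids with mature and star read
    counts both >= ``min_count`` in that library.
    """
    libs = sorted({lib for mc in counts for lib in mc.mature})
    return {
        lib: sorted(
            mc.mirna_id
            for mc in counts
            if mc.mature.get(lib, 0) >= min_count and mc.star.get(lib, 0) >= min_count
        )
        for lib in libs
    }


def composition_summary(annotations: list[TagAnnotation]) -> pd.DataFrame:
    """Per-class fractions of total reads and of unique tags.

    Rows are the partition classes (fractions sum to 1 in each column)
    plus an extra ``miRNA_total`` row merging miRNA and miRNA*.
    """
    reads = {cls: 0 for cls in PARTITION_CLASSES}
    uniq = {cls: 0 for cls in PARTITION_CLASSES}
    for ann in annotations:
        reads[ann.rna_class] += ann.tag.count
        uniq[ann.rna_class] += 1
    total_reads = sum(reads.values())
    total_uniq = sum(uniq.values())
    if total_reads == 0:
        raise ValueError("no annotations to summarize")
    rows = {
        cls: (reads[cls] / total_reads, uniq[cls] / total_uniq)
        for cls in PARTITION_CLASSES
    }
    rows["miRNA_total"] = (
        (reads["miRNA"] + reads["miRNA_star"]) / total_reads,
        (uniq["miRNA"] + uniq["miRNA_star"]) / total_uniq,
    )
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["read_fraction", "unique_fraction"]
    )


def annotations_to_frame(annotations: list[TagAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "seq": [a.tag.seq for a in annotations],
            "count": [a.tag.count for a in annotations],
            "rna_class": [a.rna_class for a in annotations],
            "assigned_id": [a.assigned_id for a in annotations],
            "n_mismatches": [a.n_mismatches for a in annotations],
            "offset": [a.offset for a in annotations],
        }
    )


def mirna_counts_to_frame(counts: list[MirnaCount]) -> pd.DataFrame:
    """Table-style layout: id, mature count per library, star count per library."""
    libs = sorted({lib for mc in counts for lib in mc.mature})
    data = {"mirna_id": [mc.mirna_id for mc in counts]}
    for lib in libs:
        data[f"mature_{lib}"] = [mc.mature.get(lib, 0) for mc in counts]
    for lib in libs:
        data[f"star_{lib}"] = [mc.star.get(lib, 0) for mc in counts]
    return pd.DataFrame(data)
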
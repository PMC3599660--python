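"""Reference catalog of miRNA hairpins with annotated mature/star arms.

A catalog entry ties together a precursor (hairpin) sequence, the
coordinates of its 5p and 3p arms, and which arm is the annotated mature
miRNA.  The opposite arm is the miRNA* ("star") species.  Catalogs are
persisted as a hairpin FASTA plus a tab-separated arm-coordinate table
(0-based, half-open intervals).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ARM_TABLE_COLUMNS = [
    "id",
    "arm5p_start",
    "arm5p_end",
    "arm3p_start",
    "arm3p_end",
    "mature_arm",
]

CONTAMINANT_CLASSES = ("rRNA", "tRNA", "snRNA", "snoRNA", "repeat")


def normalize_seq(seq: str) -> str:
    """Uppercase and map U->T so RNA and DNA spellings compare equal."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class HairpinEntry:
    """One precursor with its two arms.

    Parameters
    ----------
    id :
        Catalog identifier, e.g. ``"mir-0001"``.
    hairpin_seq :
        Precursor sequence, 60-80 nt (DNA alphabet; U is normalized to T).
    arm5p, arm3p :
        Half-open 0-based intervals of the 5p and 3p arms on the hairpin.
        Each arm is 20-24 nt; the 5p arm precedes and does not overlap the
        3p arm.
    mature_arm :
        ``"5p"`` or ``"3p"``: which arm is the annotated mature miRNA.
        The other arm is the miRNA*.
    """

    id: str
    hairpin_seq: str
    arm5p: tuple[int, int]
    arm3p: tuple[int, int]
    mature_arm: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "hairpin_seq", normalize_seq(self.hairpin_seq))
        n = len(self.hairpin_seq)
        s5, e5 = self.arm5p
        s3, e3 = self.arm3p
        if not (0 <= s5 < e5 <= s3 < e3 <= n):
            raise ValueError(
                f"{self.id}: arms must be disjoint, ordered 5p before 3p and "
                f"within the hairpin (got {self.arm5p}, {self.arm3p}, len {n})"
            )
        for name, (s, e) in (("arm5p", self.arm5p), ("arm3p", self.arm3p)):
            if not 20 <= e - s <= 24:
                raise ValueError(f"{self.id}: {name} must be 20-24 nt, got {e - s}")
        if self.mature_arm not in ("5p", "3p"):
            raise ValueError(f"{self.id}: mature_arm must be '5p' or '3p'")

    def arm_seq(self, which: str) -> str:
        s, e = self.arm5p if which == "5p" else self.arm3p
        return self.hairpin_seq[s:e]

    @property
    def mature_seq(self) -> str:
        """Sequence of the annotated mature arm."""
        return self.arm_seq(self.mature_arm)

    @property
    def star_seq(self) -> str:
        """Sequence of the arm opposite the annotated mature arm."""
        return self.arm_seq("3p" if self.mature_arm == "5p" else "5p")


def write_catalog(
    catalog: list[HairpinEntry], fasta_path: str, arm_table_path: str
) -> None:
    """Write hairpin FASTA plus the arm-coordinate TSV."""
    records = [
        SeqRecord(Seq(h.hairpin_seq), id=h.id, description="") for h in catalog
    ]
    SeqIO.write(records, fasta_path, "fasta")
    rows = [
        (h.id, h.arm5p[0], h.arm5p[1], h.arm3p[0], h.arm3p[1], h.mature_arm)
        for h in catalog
    ]
    pd.DataFrame(rows, columns=ARM_TABLE_COLUMNS).to_csv(
        arm_table_path, sep="\t", index=False
    )


def read_catalog(fasta_path: str, arm_table_path: str) -> list[HairpinEntry]:
    """Load a catalog written by :func:`write_catalog`."""
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(fasta_path, "fasta")}
    table = pd.read_csv(arm_table_path, sep="\t")
    catalog = []
    for row in table.itertuples(index=False):
        if row.id not in seqs:
            raise ValueError(f"arm table id {row.id!r} missing from hairpin FASTA")
        catalog.append(
            HairpinEntry(
                id=row.id,
                hairpin_seq=seqs[row.id],
                arm5p=(int(row.arm5p_start), int(row.arm5p_end)),
                arm3p=(int(row.arm3p_start), int(row.arm3p_end)),
                mature_arm=str(row.mature_arm),
            )
        )
    return catalog


def write_contaminants(
    contaminants: dict[str, list[tuple[str, str]]], out_dir: str
) -> dict[str, str]:
    """Write one FASTA per contaminant class; return class -> path."""
    paths = {}
    for cls, refs in contaminants.items():
        path = os.path.join(out_dir, f"{cls}.fa")
        records = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in refs]
        SeqIO.write(records, path, "fasta")
        paths[cls] = path
    return paths


def read_contaminants(paths: dict[str, str]) -> dict[str, list[tuple[str, str]]]:
    return {
        cls: [(rec.id, normalize_seq(str(rec.seq))) for rec in SeqIO.parse(p, "fasta")]
        for cls, p in paths.items()
    }
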
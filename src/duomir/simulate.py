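"""Synthetic two-library small-RNA-seq data with known per-miRNA truth.

The generator emulates the structure of a pooled-library small RNA
sequencing experiment comparing two conditions: a catalog of hairpin
precursors with annotated mature/star arms, contaminant ncRNA references
(rRNA, tRNA, snRNA, snoRNA, repeat), and read libraries dominated by
21-24 nt miRNA-derived tags (mode 22 nt) with heavy-tailed per-miRNA
abundances, a minority of contaminant and random ("unannotated") tags,
planted log2 fold effects on a chosen miRNA subset, and library-specific
miRNAs forced absent from one library.

Truth bookkeeping is exact: every emitted read is attributed to its
source, and the generator rejection-samples arms and random sequences so
that no planted sequence is claimable by more than one class under the
downstream matching rules.  Under zero noise (no substitution errors, no
length jitter, no low-quality reads) the annotation stage therefore
recovers the truth table exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import ArmIndex, ContaminantIndex
from .catalog import CONTAMINANT_CLASSES, HairpinEntry
from .preprocess import ReadRecord

#: Illumina TruSeq small-RNA 3' adapter
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

#: arm length law: concentrated on 22 nt as in Dicer-product libraries
ARM_LENGTHS = np.array([20, 21, 22, 23, 24])
ARM_LENGTH_PROBS = np.array([0.06, 0.18, 0.45, 0.19, 0.12])

#: per-class (reference length range, read length range), chosen to keep
#: contaminant read lengths mostly outside the 21-24 nt miRNA band while
#: surviving a 15-35 nt size selection
CONTAMINANT_LAYOUT = {
    "rRNA": ((80, 120), (28, 32)),
    "tRNA": ((70, 90), (30, 35)),
    "snRNA": ((100, 150), (25, 28)),
    "snoRNA": ((70, 120), (25, 30)),
    "repeat": ((100, 200), (18, 20)),
}

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

_HIGH_QUAL = "I"  # Phred 40
_LOW_QUAL = "#"  # Phred 2


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, length))


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Plant exactly ``n_subs`` substitutions at distinct positions."""
    chars = list(seq)
    for pos in rng.choice(len(chars), size=n_subs, replace=False):
        alternatives = [b for b in _BASES if b != chars[pos]]
        chars[pos] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


@dataclass
class LibrarySpec:
    """Parameters of one simulated library.

    Per-miRNA baseline abundances are log-normal(``abundance_mu``,
    ``abundance_sigma``) draws seeded by ``abundance_seed``; share that
    seed between two libraries so the same miRNA has the same baseline in
    both, with ``de_effects`` (id -> log2 fold multiplier applied in this
    library) and ``specific_absent`` (ids forced to zero reads here) the
    only systematic differences.
    """

    n_reads: int
    adapter: str = DEFAULT_ADAPTER
    seed: int = 0
    abundance_seed: int | None = None
    abundance_mu: float = 0.0
    abundance_sigma: float = 1.5
    de_effects: dict[str, float] = field(default_factory=dict)
    specific_absent: frozenset[str] = frozenset()
    star_fraction: float = 0.1
    contaminant_fraction: float = 0.05
    unannotated_fraction: float = 0.12
    error_rate: float = 0.001
    len_jitter: dict[int, float] = field(default_factory=lambda: {0: 1.0})
    low_quality_fraction: float = 0.0
    read_id_prefix: str = "read"

    def validate(self) -> None:
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if len(self.adapter) < 6:
            raise ValueError("adapter shorter than 6 nt is untrimmable")
        for name in (
            "star_fraction",
            "contaminant_fraction",
            "unannotated_fraction",
            "error_rate",
            "low_quality_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.contaminant_fraction + self.unannotated_fraction > 1.0:
            raise ValueError("contaminant + unannotated fractions exceed 1")
        if abs(sum(self.len_jitter.values()) - 1.0) > 1e-9:
            raise ValueError("len_jitter probabilities must sum to 1")
        if any(not -2 <= k <= 2 for k in self.len_jitter):
            raise ValueError("len_jitter offsets must lie in -2..+2")


@dataclass
class LibraryTruth:
    """Exact source accounting for one simulated library.

    Counts refer to emitted reads, before any downstream filtering;
    planted low-quality reads are additionally tallied in
    ``n_low_quality``.
    """

    mature: dict[str, int]
    star: dict[str, int]
    contaminant: dict[str, int]
    n_unannotated: int = 0
    n_low_quality: int = 0

    @property
    def n_reads(self) -> int:
        return (
            sum(self.mature.values())
            + sum(self.star.values())
            + sum(self.contaminant.values())
            + self.n_unannotated
        )


def baseline_weights(
    n_mirnas: int,
    abundance_seed: int,
    mu: float = 0.0,
    sigma: float = 1.5,
) -> np.ndarray:
    """The heavy-tailed baseline abundance weights a library pair shares."""
    rng = np.random.default_rng(abundance_seed)
    return rng.lognormal(mu, sigma, n_mirnas)


def generate_catalog(
    n_mirnas: int,
    n_contaminants_per_class: int = 4,
    seed: int = 0,
) -> tuple[list[HairpinEntry], dict[str, list[tuple[str, str]]]]:
    """Generate hairpins with duplex-like arms plus contaminant references.

    Each hairpin carries a mature arm (random 20-24 nt, mode 22) and a
    star arm equal to the reverse complement of the mature arm with 1-3
    planted substitutions, on opposite sides of a loop sized so the
    precursor spans 60-80 nt.  Which arm is mature is random.  Arms are
    rejection-sampled so that no arm matches another hairpin's arms under
    the annotation rules (<=2 substitutions within a +/-2 nt shift) nor
    sits inside a contaminant reference at <=1 mismatch, keeping planted
    truth unambiguous.
    """
    from .annotate import match_tag  # local import to keep module load light

    if n_mirnas < 1 or n_contaminants_per_class < 1:
        raise ValueError("catalog sizes must be positive")
    rng = np.random.default_rng(seed)

    contaminants: dict[str, list[tuple[str, str]]] = {}
    for cls in CONTAMINANT_CLASSES:
        (ref_lo, ref_hi), _ = CONTAMINANT_LAYOUT[cls]
        contaminants[cls] = [
            (f"{cls}-{i + 1:03d}", _random_seq(rng, int(rng.integers(ref_lo, ref_hi + 1))))
            for i in range(n_contaminants_per_class)
        ]
    cont_index = ContaminantIndex(contaminants)

    def collides(arm: str, accepted: list[str]) -> bool:
        for cls in CONTAMINANT_CLASSES:
            if cont_index.hit(arm, cls) is not None:
                return True
        return any(
            match_tag(arm, other) is not None or match_tag(other, arm) is not None
            for other in accepted
        )

    catalog: list[HairpinEntry] = []
    accepted_arms: list[str] = []
    for i in range(n_mirnas):
        for _ in range(100):
            arm_len = int(rng.choice(ARM_LENGTHS, p=ARM_LENGTH_PROBS))
            mature = _random_seq(rng, arm_len)
            star = _mutate(rng, _revcomp(mature), int(rng.integers(1, 4)))
            if match_tag(mature, star) is not None or match_tag(star, mature) is not None:
                continue
            if collides(mature, accepted_arms) or collides(star, accepted_arms):
                continue
            break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not place a collision-free hairpin")
        mature_arm = "5p" if rng.random() < 0.5 else "3p"
        arm5_seq, arm3_seq = (mature, star) if mature_arm == "5p" else (star, mature)
        loop_len = int(rng.integers(60 - 2 * arm_len, 80 - 2 * arm_len + 1))
        loop = _random_seq(rng, loop_len)
        hairpin = arm5_seq + loop + arm3_seq
        catalog.append(
            HairpinEntry(
                id=f"mir-{i + 1:04d}",
                hairpin_seq=hairpin,
                arm5p=(0, arm_len),
                arm3p=(arm_len + loop_len, 2 * arm_len + loop_len),
                mature_arm=mature_arm,
            )
        )
        accepted_arms.extend([mature, star])
    return catalog, contaminants


def library_weights(
    catalog: list[HairpinEntry], spec: LibrarySpec
) -> np.ndarray:
    """Per-miRNA sampling probabilities for one library.

    Shared baseline weights scaled by ``2**de_effect`` and zeroed for
    ``specific_absent`` ids, then normalized.
    """
    seed = spec.abundance_seed if spec.abundance_seed is not None else spec.seed
    w = baseline_weights(len(catalog), seed, spec.abundance_mu, spec.abundance_sigma)
    for j, h in enumerate(catalog):
        if h.id in spec.specific_absent:
            w[j] = 0.0
        elif h.id in spec.de_effects:
            w[j] *= 2.0 ** spec.de_effects[h.id]
    total = w.sum()
    if total <= 0:
        raise ValueError("all miRNAs absent: no positive abundance weight")
    return w / total


def _jittered_insert(
    hairpin: HairpinEntry, which: str, offset: int
) -> str:
    start, end = hairpin.arm5p if which == "5p" else hairpin.arm3p
    new_end = min(len(hairpin.hairpin_seq), max(start + 15, end + offset))
    return hairpin.hairpin_seq[start:new_end]


def simulate_library(
    catalog: list[HairpinEntry],
    spec: LibrarySpec,
    contaminants: dict[str, list[tuple[str, str]]] | None = None,
) -> tuple[list[ReadRecord], LibraryTruth]:
    """Emit one library's reads (insert + 3' adapter) and its truth table.

    Each read is a jittered arm substring, a contaminant reference
    substring, or a random sequence, with per-base substitution errors at
    ``error_rate``; the full adapter is appended to every read.  Random
    "unannotated" sequences (15-25 nt, uniform over ACGT) are
    rejection-sampled against the catalog arms and contaminant references
    so they stay unannotatable.  The output is fully determined by the
    spec's seeds.
    """
    if not catalog:
        raise ValueError("catalog must be non-empty")
    spec.validate()
    if spec.contaminant_fraction > 0 and not contaminants:
        raise ValueError("contaminant_fraction > 0 requires contaminant references")
    contaminants = contaminants or {}

    rng = np.random.default_rng(spec.seed)
    probs = library_weights(catalog, spec)
    arm_index = ArmIndex(catalog)
    cont_index = ContaminantIndex(contaminants)
    cont_classes = [cls for cls in CONTAMINANT_CLASSES if contaminants.get(cls)]

    n = spec.n_reads
    p_cont = spec.contaminant_fraction
    p_unk = spec.unannotated_fraction
    categories = rng.choice(3, size=n, p=[1.0 - p_cont - p_unk, p_cont, p_unk])
    mirna_idx = rng.choice(len(catalog), size=n, p=probs)
    star_flags = rng.random(n) < spec.star_fraction
    jitter_offsets = np.array(sorted(spec.len_jitter), dtype=int)
    jitter_probs = np.array([spec.len_jitter[k] for k in sorted(spec.len_jitter)])
    jitters = rng.choice(jitter_offsets, size=n, p=jitter_probs)
    lowq_flags = rng.random(n) < spec.low_quality_fraction

    truth = LibraryTruth(
        mature={h.id: 0 for h in catalog},
        star={h.id: 0 for h in catalog},
        contaminant={cls: 0 for cls in CONTAMINANT_CLASSES},
    )

    def is_annotatable(seq: str) -> bool:
        if arm_index.best_hit(seq) is not None:
            return True
        return any(cont_index.hit(seq, cls) is not None for cls in cont_classes)

    reads: list[ReadRecord] = []
    for i in range(n):
        cat = categories[i]
        if cat == 0:
            h = catalog[mirna_idx[i]]
            if star_flags[i]:
                which = "3p" if h.mature_arm == "5p" else "5p"
                truth.star[h.id] += 1
            else:
                which = h.mature_arm
                truth.mature[h.id] += 1
            insert = _jittered_insert(h, which, int(jitters[i]))
        elif cat == 1:
            cls = cont_classes[rng.integers(0, len(cont_classes))]
            refs = contaminants[cls]
            _, ref_seq = refs[rng.integers(0, len(refs))]
            lo, hi = CONTAMINANT_LAYOUT[cls][1]
            length = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(0, len(ref_seq) - length + 1))
            insert = ref_seq[start : start + length]
            truth.contaminant[cls] += 1
        else:
            while True:
                insert = _random_seq(rng, int(rng.integers(15, 26)))
                if not is_annotatable(insert):
                    break
            truth.n_unannotated += 1
        if spec.error_rate > 0:
            n_err = rng.binomial(len(insert), spec.error_rate)
            if n_err:
                insert = _mutate(rng, insert, min(n_err, len(insert)))
        seq = insert + spec.adapter
        if lowq_flags[i]:
            qual = _LOW_QUAL * len(seq)
            truth.n_low_quality += 1
        else:
            qual = _HIGH_QUAL * len(seq)
        reads.append(ReadRecord(f"{spec.read_id_prefix}_{i + 1}", seq, qual))
    assert truth.n_reads == n
    return reads, truth


def pair_truth_table(
    catalog: list[HairpinEntry],
    truth_a: LibraryTruth,
    truth_b: LibraryTruth,
    spec_a: LibrarySpec,
    spec_b: LibrarySpec,
) -> pd.DataFrame:
    """Merge two library truths into one per-miRNA table.

    Columns: mature/star counts per library, the planted log2 effect
    (library A relative to B) and the realized category, defined from
    mature counts: ``A_specific`` when library B saw zero mature reads
    and A saw some, symmetrically ``B_specific``, ``co_expressed`` when
    both saw reads and ``undetected`` when neither did.
    """
    rows = []
    for h in catalog:
        ma, mb = truth_a.mature[h.id], truth_b.mature[h.id]
        if ma > 0 and mb > 0:
            category = "co_expressed"
        elif ma > 0:
            category = "A_specific"
        elif mb > 0:
            category = "B_specific"
        else:
            category = "undetected"
        rows.append(
            {
                "mirna_id": h.id,
                "mature_A": ma,
                "mature_B": mb,
                "star_A": truth_a.star[h.id],
                "star_B": truth_b.star[h.id],
                "log2_effect": spec_a.de_effects.get(h.id, 0.0)
                - spec_b.de_effects.get(h.id, 0.0),
                "category": category,
            }
        )
    return pd.DataFrame(rows).set_index("mirna_id")


def paired_specs(
    catalog: list[HairpinEntry],
    n_reads: int,
    n_de: int = 20,
    de_effect: float = 2.0,
    n_specific: int = 10,
    error_rate: float = 0.001,
    seed: int = 0,
    min_expected_count: int = 100,
    max_share: float = 0.01,
    **kwargs,
) -> tuple[LibrarySpec, LibrarySpec]:
    """Build a matched pair of library specs with planted truth.

    The ``n_de`` most abundant miRNAs whose expected mature count reaches
    ``min_expected_count`` receive alternating +/-``de_effect`` log2
    multipliers in library A; the next ``n_specific`` abundant miRNAs are
    made library-specific (half absent from B, half from A).  Planting is
    restricted to miRNAs holding at most ``max_share`` of the baseline
    abundance: perturbing a library-dominating species would shift every
    other miRNA's relative abundance (count data are compositional) and
    blur the planted truth.  Both specs share the abundance seed; extra
    keyword arguments pass through to :class:`LibrarySpec`.
    """
    template = LibrarySpec(n_reads=n_reads, error_rate=error_rate, **kwargs)
    w = baseline_weights(
        len(catalog), seed, template.abundance_mu, template.abundance_sigma
    )
    share = w / w.sum()
    mirna_frac = 1.0 - template.contaminant_fraction - template.unannotated_fraction
    expected = n_reads * mirna_frac * (1.0 - template.star_fraction) * share
    order = np.argsort(-w)
    eligible = [
        int(j)
        for j in order
        if expected[j] >= min_expected_count and share[j] <= max_share
    ]
    if len(eligible) < n_de + n_specific:
        raise ValueError(
            f"only {len(eligible)} miRNAs reach an expected mature count of "
            f"{min_expected_count}; cannot plant {n_de} DE + {n_specific} specific"
        )
    de_ids = [catalog[j].id for j in eligible[:n_de]]
    de_effects = {
        mid: (de_effect if i % 2 == 0 else -de_effect) for i, mid in enumerate(de_ids)
    }
    specific = [catalog[j].id for j in eligible[n_de : n_de + n_specific]]
    absent_b = frozenset(specific[: n_specific // 2])  # A-specific
    absent_a = frozenset(specific[n_specific // 2 :])  # B-specific
    spec_a = LibrarySpec(
        n_reads=n_reads,
        seed=(2 * seed + 1) % 2**31,
        abundance_seed=seed,
        de_effects=de_effects,
        specific_absent=absent_a,
        error_rate=error_rate,
        read_id_prefix="A",
        **kwargs,
    )
    spec_b = LibrarySpec(
        n_reads=n_reads,
        seed=(2 * seed + 2) % 2**31,
        abundance_seed=seed,
        specific_absent=absent_b,
        error_rate=error_rate,
        read_id_prefix="B",
        **kwargs,
    )
    return spec_a, spec_b


def simulate_pair(
    catalog: list[HairpinEntry],
    contaminants: dict[str, list[tuple[str, str]]],
    spec_a: LibrarySpec,
    spec_b: LibrarySpec,
) -> tuple[list[ReadRecord], list[ReadRecord], LibraryTruth, LibraryTruth, pd.DataFrame]:
    """Simulate both libraries of a comparison and their joint truth."""
    if spec_a.abundance_seed is None or spec_a.abundance_seed != spec_b.abundance_seed:
        raise ValueError(
            "library specs must share an explicit abundance_seed so baseline "
            "abundances are common to the pair"
        )
    reads_a, truth_a = simulate_library(catalog, spec_a, contaminants)
    reads_b, truth_b = simulate_library(catalog, spec_b, contaminants)
    truth = pair_truth_table(catalog, truth_a, truth_b, spec_a, spec_b)
    return reads_a, reads_b, truth_a, truth_b, truth
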
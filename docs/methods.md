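# Methods

## Scope and design

`duomir` implements the two-pooled-library small RNA-seq comparison
design: one sequencing library per biological condition, no replicates,
differential expression assessed per miRNA by an exact test on the two
raw counts given the two library depths. The pipeline stages are
preprocess → annotate → diffexpr, orchestrated by `duomir.pipeline`,
with `duomir.qpcr` covering the ΔCt validation arithmetic and
`duomir.simulate` providing synthetic data with known truth. The
command-line interface (`duomir …`) is a thin layer over these modules.

This design cannot estimate within-group biological variance; the exact
test treats each library as a multinomial sample of its pool, so its
P-values speak to sequencing sampling noise only. Replicate-aware count
models (negative binomial GLMs etc.) are deliberately out of scope.

## Read cleaning

Cleaning order is fixed: whole-read quality filter → 5'-adapter
contaminant removal → 3' adapter trimming → insert length window.

- *Quality filter.* A read fails if more than 20% of its bases are
  below Phred 20 or it has more than two `N` bases. These thresholds
  are configurable; whole-read filtering only, no quality trimming.
- *5' contaminant.* A read whose 5' end matches the 5' adapter
  (prefix match, ≥ 6 nt, mismatch fraction ≤ 0.1) is removed. Off by
  default (no 5' adapter configured).
- *3' adapter.* Candidate placements at every position, including
  suffix overlaps of at least `min_overlap` (default 6) nt; a placement
  is valid when its mismatch fraction over the aligned span is at most
  `max_mismatch_rate` (default 0.1). Ties break by longest overlap,
  then fewest mismatches, then leftmost position, making trimming
  deterministic. Reads with no valid placement are dropped (small-RNA
  inserts are shorter than the read, so a missing adapter indicates a
  failed ligation or a non-small-RNA molecule). Pure-adapter reads trim
  to an empty insert and fall to the length filter.
- *Length window.* Inserts outside 15–35 nt are dropped, mirroring the
  PAGE size selection of small-RNA library preparation.

The surviving reads are the *clean reads*; their count `N` is the
normalization denominator. Identical clean reads collapse into unique
tags (descending count, ties lexicographic). Accounting is exact:
`total_raw = clean_total + Σ removed`, enforced at run time.

## Annotation

Unique tags are classified by a priority cascade, default
rRNA > tRNA > snRNA > snoRNA > repeat > miRNA > unannotated, mirroring
the convention of removing known non-miRNA ncRNA classes before
searching a miRNA catalog. Matching rules:

- *Contaminant classes*: the tag must lie fully inside a reference
  sequence with at most one mismatch (substring matching; replaces the
  external BLASTN searches of the original workflow with an in-repo
  equivalent over user-supplied reference FASTAs).
- *miRNA catalog*: indel-free alignment of the tag against each
  hairpin arm at start offsets −2…+2, requiring overlap of at least
  `min(len(tag), len(arm)) − 2` and at most 2 substitutions. Among hits
  the fewest mismatches win, then smallest |offset|, then the negative
  offset, then catalog order (mature arm before star arm of the same
  hairpin). Substitutions and end-shifts are separate parameters
  (`max_sub`, `max_shift`) because published "1–2 mismatches" criteria
  are ambiguous about isomiR-like end variation. A tag's count is never
  split across references.
- A tag matching the arm opposite the annotated mature arm is classed
  `miRNA_star`; mature/star identity comes from the catalog annotation,
  never from relative abundance (star arms can dominate, as miR-199b
  does in the goat ovary data).

Per-miRNA, per-arm counts aggregate tag counts per library. A
duplex-like miRNA:miRNA\* pair is called in a library when both arms
have at least `min_count` (default 1) reads there. Composition
summaries report per-class fractions of reads and of unique tags; the
eight partition classes sum to 1 and a merged miRNA+miRNA\* row is
added for convenience.

## Differential expression

- `NE = count / N × 10⁶` (reads per million).
- A zero NE is revised to 0.01 so fold changes of library-specific
  miRNAs stay finite; substitution happens on the NE scale, raw counts
  feed the test.
- A record is excluded when **both** NE values are below 1.0. Excluding
  on `max(NE_A, NE_B) < 1` rather than `min` keeps library-specific
  miRNAs (absent-library NE = 0.01) testable, which the original
  analysis evidently did (library-specific miRNAs appear among its
  significant sets).
- Fold change `log2(NE_A/NE_B)`, A being the treatment library.
- Exact test: `p(y|x) = (N2/N1)^y (x+y)!/(x!y!) (1+N2/N1)^-(x+y+1)`,
  the negative binomial nbinom(y; x+1, N1/(N1+N2)). The published
  formula leaves open how the two printed tails combine; the default
  here is the two-sided `min(1, 2·min(C, D))` with one-sided options
  exposed.
- Labels: `**` iff |log2FC| > 1 and P < 0.01; `*` iff |log2FC| > 1 and
  0.01 ≤ P < 0.05; `none` otherwise. "Significant" means label ≠ none.
- Categories from raw counts: A-specific (count_B = 0 < count_A),
  B-specific (symmetric), co-expressed. Reporting percentages are
  rounded half-up to two decimals, matching the printed style of this
  literature.
- No multiple-testing correction by default (the classic analysis used
  none); a Benjamini–Hochberg `q_value` column is available behind a
  flag.

### Numerics of the tail sums

All pmf terms are computed in log space from log-gamma; tails are
accumulated by log-sum-exp. The lower tail is a finite sum over
`0…y`; the upper tail is summed directly upward from `y` in chunks, the
first chunk sized to reach past the distribution mean, terminating when
a geometric bound on the remaining mass falls below 1e-17 of the
accumulated sum. Summing each tail directly (rather than by complement
of the other) keeps full relative accuracy for whichever tail is small
— the one that matters for the P-value. Tails smaller than roughly
1e-308 underflow the linear scale; `ac_pvalue(..., log=True)` returns
the natural-log P-value, which remains exact to ~1e-13 relative in the
log. Validated against arbitrary-precision summation at 1e-10 relative
over a grid of counts up to 5000 and depth ratios 0.5–2, and against
the closed-form Bin(x+y, ½)/2 limit at equal depths.

The test is conservative: under equal Poisson rates the two-sided
rejection rate at α = 0.05 measures ≈ 0.03–0.05 (λ = 5…500, 10⁴
replicates), reflecting the discreteness of the statistic.

## qPCR validation arithmetic

Relative expression is `2^-(Ct_target − Ct_U6)`; technical replicates
are averaged on the Ct scale (geometric averaging on the linear scale),
before exponentiation. Groups are compared per target with Welch's
unequal-variance t-test on per-sample relative expressions — the
unequal-variance form is the safer default where the original reports
only "t-test". Two degenerate constant groups give P = 1 (equal means)
or 0 (different means) rather than an undefined statistic. Concordance
with sequencing is sign agreement between the qPCR log2 ratio of group
means and the sequencing fold change; targets absent from the
sequencing table are reported as missing, not errors.

## The synthetic-data generator

The generator emulates the *structure* of a two-condition pooled
small-RNA experiment, not any particular instrument:

- *Catalog*: hairpins of 60–80 nt; mature arm 20–24 nt with the length
  law peaked at 22 nt (probabilities 0.06/0.18/0.45/0.19/0.12 for
  20…24, echoing the dominance of 22-mers among Dicer products); star
  arm = reverse complement of the mature arm with 1–3 planted
  substitutions on the opposite side of the loop. Contaminant reference
  sets (rRNA, tRNA, snRNA, snoRNA, repeat) are random sequences with
  class-specific read-length ranges chosen mostly outside 21–24 nt.
- *Abundance*: per-miRNA baseline weights are log-normal(0, 1.5),
  shared between the two libraries of a pair via a common abundance
  seed. σ = 1.5 puts the most abundant miRNA near 10–20% of miRNA
  reads, the dominance level visible in published two-library count
  tables; heavier tails would let a single hairpin's arm length set the
  whole library's length mode.
- *Mixture*: per read, contaminant with probability 0.05, random
  "unannotated" sequence (15–25 nt uniform over ACGT) with probability
  0.12, otherwise a miRNA arm — star arm with probability 0.1. These
  defaults echo the published composition of miRNA-enriched ovary
  libraries (miRNAs ≈ 80–95% of reads). Planted truth: selected miRNAs
  get a `2^±effect` multiplier in library A; library-specific miRNAs
  are forced to zero reads in one library.
- *Noise*: per-base substitution errors (default 0.001), 3' length
  jitter in −2…+2 nt, and an optional planted low-quality read
  fraction (quality strings are synthetic constants, high or low — the
  quality filter is exercised by an explicit knob, not an error model).
- *Truth bookkeeping*: every emitted read increments its source's
  count, so truth tables partition `n_reads` exactly.

Two properties make the truth *exact* rather than approximate. First,
arms are rejection-sampled at catalog generation so no arm is claimable
by another hairpin or a contaminant reference under the annotation
matching rules; second, "unannotated" random sequences are
rejection-sampled against the catalog and contaminant references. Under
zero noise the annotation stage therefore reproduces the truth table
read-for-read, which the test suite asserts as an equality, not a
tolerance.

Planted DE and library-specific miRNAs are drawn from miRNAs with
expected mature count ≥ 100 but holding ≤ 1% of baseline abundance:
count data are compositional, and perturbing a library-dominating
species would shift every other miRNA's relative abundance and blur the
planted null. The residual compositional shift from 20 planted effects
at ≤ 1% share each keeps null |log2FC| well below the significance
threshold of 1.

What the generator does **not** model — and hence what passing tests do
not establish about real data: position- and motif-dependent sequencer
error profiles, ligation bias, PCR duplication, isomiR families beyond
the ±2 nt jitter, true biological within-group variance, and genomic
multi-mapping (no genome exists in this design; annotation is purely
catalog-based).

## Problem sizes and runtime choices

The test suite and the acceptance script run library pairs of 10⁵ reads
over 200-hairpin catalogs — about two orders of magnitude below the
~10⁷-read libraries of production experiments, but large enough that
planted 4-fold effects on miRNAs with ≥ 100 expected reads separate
cleanly from sampling noise (observed sensitivity 100%, false-positive
rate 0% at these sizes). Null calibration uses 10⁴ replicates per
Poisson rate. The exact-test oracle grid spans counts up to 5000 and
the depth ratios 0.5, 1, 1.19 (the goat-ovary depth ratio 11.01/9.23)
and 2.

## Known limitations

- One count per condition: P-values quantify sampling, not biology.
- Tag-to-miRNA assignment is winner-takes-all; multi-mapping tags are
  not fractionally split.
- Contaminant matching requires full containment with ≤ 1 mismatch;
  fragments overhanging a reference end are not recognized.
- The star arm is modelled at the mature arm's length; real duplexes
  have 2-nt 3' overhangs and length asymmetry.
- `percent` implements fixed half-up rounding for report parity, which
  differs from banker's rounding used by Python's built-in `round`.
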
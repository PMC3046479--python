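# Methods

## The tagmentation model

A tagmentation library is produced by hyperactive Tn5 transposomes
attacking target DNA: each insertion event cuts the DNA and joins a
19 bp mosaic-end adaptor (`CTGTCTCTTATACACATCT`) to the 5' side of the
break. Two physical effects shape the statistics the package models:

**Insertion-sequence preference.** Native Tn5 weakly prefers the
palindromic 11 bp target `AGNTYWRANCT`. We model the preference as a
positional probability matrix built from an IUPAC motif mixed with
uniform background:

    p(position i, base b) = strength * uniform(allowed bases at i)
                          + (1 - strength) * 1/4,

with `strength` in [0, 1]; `strength = 0` is a bias-free enzyme. The
quantitative strength of the real enzyme is not established, so it is a
free parameter rather than a fitted constant. The motif window is
anchored with its 4th position (the T of `AGNTYWRANCT`) on the first
base of the inserted-adaptor junction, making the simulated bias profile
asymmetric around the read start, which matches the qualitative shape of
observed profiles; the anchor offset is configurable. Because the motif
is its own reverse complement but the anchor is not at the palindromic
centre, reverse-strand (fragment-end) contexts sit 2 bp out of register
with forward contexts under the shared-site convention below —
preference-recovery analyses therefore stack forward (fragment-start)
contexts.

**Steric hindrance.** The transposase homodimer's core acts on a 9 bp
region that is duplicated on insertion, and protects roughly 10
additional bases on either side. Adjacent insertion events on one
molecule are therefore at least `2 x (core + flank) = 38 bp` apart, a
hard floor on fragment length. `core_bp` and `flank_bp` are parameters
(defaults 9 and 10); changing them moves the floor accordingly. The
~10 bp helical-pitch ripple seen near the floor in real data is off by
default; setting `pitch_amplitude` > 0 thins arrivals just above the
floor by a cosine of the gap to the nearest accepted site (period
`pitch_period`, default 10.5 bp), reproducing the ripple.

### Insertion placement

Insertion sites on each simulated molecule arrive sequentially: a
candidate position is accepted with probability proportional to the
preference score of its local motif window (the product of the matrix
probabilities over the window), and is rejected when it falls within the
38 bp floor of a previously accepted site on the same molecule. The
implementation vectorises this exactly: the number of
preference-accepted arrivals is Binomial(attempts, mean score / max
score), their positions are i.i.d. with probability proportional to the
per-position score (computed once per genome), and the steric rejection
is applied to the arrival stream in order. This is distribution-
identical to per-candidate rejection sampling but runs in linear time
even for strongly concentrated preferences.

Two exposure controls exist:

* `attempts_per_molecule` — transposome exposure; the default is chosen
  so the expected number of preference-accepted arrivals is ~10 per
  38 bp of genome, i.e. the reaction runs to steric saturation, the
  regime of a completed tagmentation reaction (mean fragment ~50–140 bp,
  all fragments ≥ 38 bp).
* `target_sites_per_molecule` — keep drawing until this many sites are
  accepted; with many molecules and few sites each this is the *dilute*
  regime (abundant input DNA, moderate insertion density), where the
  site ensemble follows the preference distribution closely.

Fragments are the intervals between adjacent accepted sites on one
molecule; both abutting fragments share the insertion coordinate (the
real reaction duplicates the 9 bp core; we do not model the duplication,
which only offsets the two junctions by 9 bp). Optional `[size_min,
size_max]` bounds emulate size selection.

### Reads, duplicates, errors

Read 1 is the fragment's forward strand from its start; read 2 the
reverse complement from its end. When the insert is shorter than the
read, the read continues into the adaptor and is then padded with a
constant `A` (arbitrary, fixed for determinism). PCR duplication is a
single per-pair re-draw probability (`dup_rate`): with that probability
an emitted pair re-uses a previously chosen progenitor with fresh
errors. This one-parameter model is sufficient to exercise duplicate
removal and complexity curves; it is not a branching PCR process.
Sequencing error is i.i.d. per-base substitution (`error_rate`); no
indels, no quality-dependent error profile. Index reads are the 9 bp
barcode with the same substitution error.

## Fragmentation-site profiling

The fragmentation site is the genomic position of the first sequenced
base. Contexts of ±W (default 20) are stacked — as-is around forward
read starts, reverse-complemented around the 5' genomic base of reverse
reads — giving per-offset base counts, frequencies `p_wj`, and
information content

    IC(w) = log2(J) + Σ_j p_wj log2 p_wj,    J = 4,

with `0 log 0 = 0`; offsets with no data are reported as missing, not 0.
Background base frequencies are intentionally not subtracted, so IC is
on an absolute 0–2 bit scale. Summaries (max, mean) are taken over
±10 bp. Sites whose window overruns the sequence are skipped and
counted. Duplicate-marked and MAPQ-0 records are excluded by default so
each fragmentation event counts once.

The IUPAC consensus call per offset: a single base when its frequency
reaches `primary_threshold` (default 0.45) and the runner-up stays below
the two-base floor; a two-base code when the top two frequencies jointly
reach `pair_threshold` (default 0.65) and each exceeds uniform by at
least half of the pair threshold's excess over 0.5 (floor 0.325 at the
default); otherwise N. The runner-up condition on the single-base branch
matters: a two-base position generated at strength 0.9 has top frequency
0.475, which would otherwise be mistaken for a weakly fixed base.

### What recovery tests do and do not show

With strength 0.9, roughly half the insertion probability mass falls on
the genome's exact motif matches, which occur at only ~30 per Mb per
strand. Recovering the generating matrix to per-position L1 < 0.02
therefore needs thousands of such windows — the round-trip check uses a
96 Mb genome, 4,000 molecules and ~116,000 insertions in the dilute
regime. Conversely, at steric saturation most accepted sites are forced
onto non-preferred positions and the measured IC is far below the
single-event preference — which is why real saturated libraries show
maximum IC of only ~0.1–0.2 bits even though the enzyme has a genuine
target preference. Passing round-trip tests show the estimator and the
generator are mutually consistent; they do not calibrate the real
enzyme's strength.

## Coverage statistics

Depth counts aligned *read* bases ("the number of times each base was
sequenced"); a whole-fragment-span mode exists behind a flag. Reads of
short inserts are clipped at the fragment boundaries, since adaptor
bases do not align. Normalization divides by total mapped bases and
multiplies by a constant (default 1e9, matching libraries of about a
gigabase). The Poisson(λ) reference pmf — the expectation under no bias
of any kind — is tabulated with scipy to a cutoff leaving < 1e-9 tail
mass. G+C bias tables tile the genome in fixed bins (500 bp is apt for
bacterial genomes, 1–10 kb for larger ones); the trailing partial bin is
kept with its actual length. On-target accounting counts an aligned base
as on target when within 100 bp (inclusive) of a target interval, and a
target position as covered at depth ≥ 1.

The Poisson-overlay check simulates a bias-free library (uniform
fragment starts, 36 bp paired reads) at mean depth 12 and 24 on a 1 Mb
genome and requires total-variation distance < 0.02 between the depth
histogram and Poisson(λ). At these sizes the residual TV is ~0.005,
dominated by the spatial correlation of depth within a read length.

## Library QC

Duplicates are pairs with identical (reference, start of read 1, end of
read 2, orientation) — outer fragment coordinates, the same key used for
"unique start-point pairs" in complexity curves, so duplicate removal
followed by a complexity curve reproduces the 100%-unique diagonal
exactly. Complexity curves shuffle the pairs once under a seed and
consume them in 50,000-pair increments without replacement. The
expected-occupancy law `m(1 - (1 - 1/m)^n)` (with its exact variance)
serves as the closed-form oracle for sampling n pairs from m equally
likely progenitors.

Mapped insert size is `end2 - start1`; improperly oriented (negative)
sizes are counted separately and excluded. The mapping-independent
estimate aligns read 1 ungapped against the reverse complement of read 2
over all offsets with overlap ≥ 10 and ≤ 1 mismatch (defaults); the
qualifying offset with the fewest mismatches wins, ties to the larger
overlap. Tail alignment is ungapped because tagmentation introduces no
indels at junctions. Pairs with no qualifying offset are "no
read-through" (insert at least the read length). At 1% per-base error
the overlap stream has ~2% mismatch, so with a 2-mismatch cap about 90%
of truly read-through pairs are detected, and essentially every detected
size is exact — detection is conservative, not error-prone. Sizes below
25 bp are labelled probable PCR artifacts but kept in the histogram.

## Barcodes

Design is a randomized greedy search: the pool of all 4^9 nine-mers is
filtered by composition (no homopolymer run ≥ 3, GC ≤ 0.60, all four
bases present) and screening (neither the candidate nor its reverse
complement occurs in any adaptor/primer sequence, either orientation),
shuffled under the seed, and accumulated greedily subject to pairwise
Levenshtein distance ≥ 4; per-position base coverage is repaired by
targeted swaps, with full restarts on failure. A returned set has always
passed an independent re-validation of every constraint. With 96 random
composition-valid barcodes the per-position coverage constraint is
almost never binding, but the repair pass guarantees it.

Distances are Levenshtein throughout (the deconvolution rule is defined
in edits, and index reads can carry synthesis artefacts as well as
substitutions); the distance-0/1/2 classes reported by the demux summary
are edit classes. The margin rule — best barcode within 2 edits, runner-
up at least 2 further edits away, ties never assigned — combined with a
pairwise floor of 4 guarantees by the triangle inequality that every
single-substitution corruption is assigned to its true barcode and no
≤ 2-substitution corruption is ever assigned to a wrong one; both facts
are checked exhaustively.

## Numerical and interface choices

* Coordinates are 0-based half-open everywhere; SAM is converted at the
  boundary, BED is native. The simulator truth table is the canonical
  alignment source; a minimal SAM dialect (match/soft-clip CIGARs) is
  supported for real data.
* All randomness flows through `numpy.random.default_rng(seed)`; every
  seeded operation is byte-reproducible. Output data files contain no
  timestamps (sidecar metadata files do).
* Preference scores are computed in float32 (smallest possible window
  score ~1e-15 is comfortably representable); their cumulative sum for
  weighted sampling is accumulated in float64 so background-level
  weights are not lost to rounding.
* IC is clamped at 0 against negative round-off; uniform, one-hot and
  half-half columns evaluate to exactly 0, 2 and 1 bits in binary
  arithmetic.
* Problem sizes in the test suite (1–2 Mb genomes for coverage and floor
  checks, a 96 Mb genome for the strength-0.9 preference round trip,
  3,000-pair tail-alignment batches) are chosen as the smallest scales
  at which the statistical claims under test are expected to hold with
  clear margin.

## Known limitations

* No PCR amplification-efficiency GC bias, no quality-score error
  profiles, no indel errors, no mate-pair/long-insert libraries.
* The 9 bp target-site duplication is not modelled; both abutting
  fragments share one junction coordinate.
* Single-reference workflows: multi-contig references are read, but the
  analyses operate per reference sequence.
* Library complexity is plotted, not extrapolated — no Lander-Waterman
  or zero-truncated fits of total library size.
* The simulator's genomes are i.i.d.; real genomes have repeats,
  composition heterogeneity and mappability structure that these tests
  deliberately exclude, so passing them validates the statistics, not
  performance on any particular organism.
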
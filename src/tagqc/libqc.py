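"""Library complexity and insert-size QC.

Complexity — the number of molecules of distinct origin in a library —
is assessed by incremental random sampling of read-pairs without
replacement and counting uniquely occurring start-point pairs; a complex
library tracks the 100%-unique diagonal.  Duplicates are pairs sharing
identical outer mapping coordinates and orientation.

Insert sizes come in two flavours: mapping-based (end of read 2 minus
start of read 1) and mapping-independent, in which the tails of a read
pair are aligned to one another to detect adaptor read-through — the
only way to see inserts shorter than the read length, and the
measurement that exposes the steric-hindrance floor near 38 bp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simdata import MOSAIC_END, revcomp


def _pair_key(p):
    return (p.genome, p.start1, p.end2, p.strand1)


def dedup(pairs) -> tuple[list, int]:
    """Remove PCR duplicates: pairs with identical (genome, start1, end2,
    orientation).  The first occurrence is kept."""
    seen = set()
    unique = []
    dups = 0
    for p in pairs:
        k = _pair_key(p)
        if k in seen:
            dups += 1
        else:
            seen.add(k)
            unique.append(p)
    return unique, dups


def filter_short_inserts(pairs, read_len: int,
                         threshold: int | None = None) -> list:
    """Retain pairs whose insert size is at least ``threshold``.

    The default threshold is the read length (reads from shorter inserts
    run into the adaptor); the variant-calling recipe uses 90 bp.
    """
    t = read_len if threshold is None else threshold
    return [p for p in pairs if p.insert_size >= t]


@dataclass
class ComplexityCurve:
    """Cumulative sampled pairs vs cumulative distinct start-point pairs."""

    step: int
    totals: np.ndarray
    uniques: np.ndarray

    @property
    def unique_fraction(self) -> float:
        return float(self.uniques[-1] / self.totals[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sampled_pairs": self.totals,
                             "unique_pairs": self.uniques})

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def complexity_curve(pairs, step: int = 50_000, seed: int = 0) -> ComplexityCurve:
    """Sample read-pairs without replacement in ``step`` increments and
    record the cumulative number of unique start-point pairs."""
    if step <= 0:
        raise ValueError("step must be positive")
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no pairs supplied")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    first = np.zeros(len(pairs), dtype=bool)
    seen: set = set()
    for i, idx in enumerate(order):
        k = _pair_key(pairs[idx])
        if k not in seen:
            seen.add(k)
            first[i] = True
    cum_unique = np.cumsum(first)
    marks = list(range(step, len(pairs) + 1, step))
    if not marks or marks[-1] != len(pairs):
        marks.append(len(pairs))
    totals = np.asarray(marks, dtype=np.int64)
    return ComplexityCurve(step, totals, cum_unique[totals - 1])


@dataclass
class InsertSizeHistogram:
    """Insert-size counts with summary moments.

    ``source`` is 'mapped' (end2 - start1) or 'tail_aligned' (adaptor
    read-through detection).  ``n_excluded`` counts improperly oriented
    pairs (mapped mode) or pairs with no detectable read-through (tail
    mode), which are not part of the histogram.
    """

    counts: dict[int, int]
    source: str
    n_excluded: int = 0
    artifact_threshold: int | None = None

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @property
    def mean(self) -> float:
        if not self.counts:
            return float("nan")
        total = self.n
        return sum(k * c for k, c in self.counts.items()) / total

    @property
    def sd(self) -> float:
        if not self.counts:
            return float("nan")
        m = self.mean
        var = sum(c * (k - m) ** 2 for k, c in self.counts.items()) / self.n
        return var ** 0.5

    @property
    def n_artifact_labelled(self) -> int:
        """Pairs at sizes below the artifact threshold (labelled, not removed)."""
        if self.artifact_threshold is None:
            return 0
        return sum(c for k, c in self.counts.items()
                   if k < self.artifact_threshold)

    def to_frame(self) -> pd.DataFrame:
        sizes = sorted(self.counts)
        return pd.DataFrame({"insert_size": sizes,
                             "count": [self.counts[s] for s in sizes]})

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def insert_sizes_mapped(pairs) -> InsertSizeHistogram:
    """Insert-size histogram from mapped pairs: end2 - start1.

    Pairs with non-positive sizes (improper orientation) are counted
    separately and excluded.
    """
    counts: dict[int, int] = {}
    excluded = 0
    for p in pairs:
        size = p.insert_size
        if size < 0:
            excluded += 1
            continue
        counts[size] = counts.get(size, 0) + 1
    return InsertSizeHistogram(counts, "mapped", excluded)


def tail_align_insert(read1: str, read2: str, min_overlap: int = 10,
                      max_mismatch: int = 1) -> int | None:
    """Mapping-independent insert size of one pair by tail alignment.

    Scans ungapped offsets of read 1 against the reverse complement of
    read 2; an offset implying insert size ``f`` overlaps the two reads
    over their first ``f`` bases.  The qualifying offset with the fewest
    mismatches wins (ties go to the larger overlap).  Returns None when
    no offset qualifies — i.e. no detectable read-through, insert at
    least the read length.
    """
    if len(read1) != len(read2):
        raise ValueError("read lengths differ within a pair")
    R = len(read1)
    a = np.frombuffer(read1.encode(), dtype=np.uint8)
    b = np.frombuffer(revcomp(read2).encode(), dtype=np.uint8)
    best_f, best_mm = None, None
    for f in range(min_overlap, R):
        mm = int(np.count_nonzero(a[:f] != b[R - f:]))
        if mm <= max_mismatch and (best_mm is None or mm < best_mm
                                   or (mm == best_mm and f > best_f)):
            best_f, best_mm = f, mm
    return best_f


def insert_sizes_tail(reads1, reads2, adaptor: str = MOSAIC_END,
                      min_overlap: int = 10, max_mismatch: int = 1,
                      artifact_threshold: int = 25) -> InsertSizeHistogram:
    """Mapping-independent insert-size histogram by pairwise tail alignment.

    ``reads1``/``reads2`` are synchronized sequence lists (or (name, seq)
    tuples).  Pairs with no qualifying overlap are reported as "no
    read-through" via ``n_excluded``.  Sizes below ``artifact_threshold``
    are labelled as probable PCR artifacts but kept in the histogram.
    """
    seqs1 = [r[1] if isinstance(r, tuple) else r for r in reads1]
    seqs2 = [r[1] if isinstance(r, tuple) else r for r in reads2]
    if len(seqs1) != len(seqs2):
        raise ValueError("read lists differ in length")
    counts: dict[int, int] = {}
    no_rt = 0
    for r1, r2 in zip(seqs1, seqs2):
        f = tail_align_insert(r1, r2, min_overlap, max_mismatch)
        if f is None:
            no_rt += 1
        else:
            counts[f] = counts.get(f, 0) + 1
    return InsertSizeHistogram(counts, "tail_aligned", no_rt,
                               artifact_threshold=artifact_threshold)


def expected_unique(m: int, n: int) -> float:
    """Closed-form expected occupancy: distinct progenitors seen when
    sampling ``n`` pairs with replacement from ``m`` equally likely ones:
    ``m * (1 - (1 - 1/m)**n)``."""
    return m * (1.0 - (1.0 - 1.0 / m) ** n)


def expected_unique_sd(m: int, n: int) -> float:
    """Standard deviation of the occupancy count above."""
    q1 = (1.0 - 1.0 / m) ** n
    q2 = (1.0 - 2.0 / m) ** n
    var = m * q1 + m * (m - 1) * q2 - (m * q1) ** 2
    return max(var, 0.0) ** 0.5
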
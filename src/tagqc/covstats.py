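"""Coverage, GC-bias and on-target statistics for shotgun libraries.

Depth is the number of times each base of the genome was sequenced
(aligned read bases, not fragment spans, by default).  Coverage
histograms are compared against the Poisson distribution with matching
mean — the expectation if there were no bias of any kind — and coverage
is additionally summarized per fixed-size GC bin, the standard way to
expose amplification- or fragmentation-driven G+C bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simdata import GenomeSequence


@dataclass
class CoverageTrack:
    """Per-base sequencing depth over one reference sequence."""

    genome: str
    depth: np.ndarray

    def __post_init__(self):
        self.depth = np.asarray(self.depth)
        if self.depth.ndim != 1:
            raise ValueError("depth must be one-dimensional")
        if (self.depth < 0).any():
            raise ValueError("depth must be non-negative")

    @property
    def total_mapped_bases(self) -> int:
        return int(self.depth.sum())

    def __len__(self) -> int:
        return self.depth.size


def depth_from_alignments(alignments, genome_length: int,
                          exclude_duplicates: bool = True,
                          mode: str = "read",
                          genome_name: str = "") -> CoverageTrack:
    """Per-base depth from aligned read pairs.

    ``mode='read'`` (default) counts aligned read bases: each pair
    contributes its two read intervals, which requires ``read_len`` on
    the pairs.  ``mode='fragment'`` counts whole fragment spans instead.
    Duplicate-marked pairs are excluded by default.
    """
    if mode not in ("read", "fragment"):
        raise ValueError("mode must be 'read' or 'fragment'")
    starts, ends = [], []
    for p in alignments:
        if exclude_duplicates and p.is_duplicate:
            continue
        if p.start1 < 0 or p.end2 > genome_length:
            raise ValueError(
                f"alignment [{p.start1}, {p.end2}) outside genome of "
                f"length {genome_length}")
        if mode == "fragment":
            starts.append(p.start1)
            ends.append(p.end2)
        else:
            if p.read_len is None:
                raise ValueError("mode='read' requires read_len on pairs")
            rl = p.read_len
            starts.append(p.start1)
            ends.append(min(p.start1 + rl, p.end2))
            starts.append(max(p.end2 - rl, p.start1))
            ends.append(p.end2)
    diff = np.zeros(genome_length + 1, dtype=np.int64)
    if starts:
        np.add.at(diff, np.asarray(starts), 1)
        np.add.at(diff, np.asarray(ends), -1)
    return CoverageTrack(genome_name, np.cumsum(diff[:-1]))


def normalize_track(track: CoverageTrack, constant: float = 1e9) -> np.ndarray:
    """Depth rescaled by total mapped bases times a constant.

    ``value_i = depth_i / total_mapped_bases * constant``; the default
    constant 1e9 matches libraries of roughly a gigabase of mapped
    sequence, making normalized values comparable across libraries.
    """
    total = track.total_mapped_bases
    if total <= 0:
        raise ValueError("track has zero mapped bases")
    return track.depth / total * constant


def coverage_histogram(track: CoverageTrack) -> dict[int, float]:
    """Fraction of genome positions at each observed depth (sums to 1)."""
    values, counts = np.unique(track.depth, return_counts=True)
    n = track.depth.size
    return {int(v): c / n for v, c in zip(values, counts)}


@dataclass
class PoissonReference:
    """Poisson(λ) depth distribution: the no-bias expectation."""

    lam: float
    pmf: np.ndarray  # pmf[k] = P(depth == k), k = 0..cutoff

    @property
    def cutoff(self) -> int:
        return self.pmf.size - 1


def poisson_reference(lam: float, tail_eps: float = 1e-9) -> PoissonReference:
    """Poisson pmf tabulated to a cutoff leaving tail mass below ``tail_eps``."""
    if lam <= 0:
        raise ValueError("lam must be positive")
    cutoff = int(stats.poisson.isf(tail_eps, lam)) + 1
    while stats.poisson.sf(cutoff, lam) >= tail_eps:
        cutoff += 1
    k = np.arange(cutoff + 1)
    return PoissonReference(lam, stats.poisson.pmf(k, lam))


def total_variation(histogram: dict[int, float],
                    reference: PoissonReference) -> float:
    """Total-variation distance between a depth histogram and a Poisson
    reference: ``0.5 * sum_k |f_k - pmf_k|`` over the union support."""
    kmax = max(max(histogram, default=0), reference.cutoff)
    f = np.zeros(kmax + 1)
    for k, v in histogram.items():
        f[k] = v
    g = np.zeros(kmax + 1)
    g[:reference.pmf.size] = reference.pmf
    return 0.5 * float(np.abs(f - g).sum())


@dataclass
class GCBiasTable:
    """Mean depth per fixed-size GC bin tiling the reference."""

    table: pd.DataFrame  # columns: bin_start, bin_len, gc_fraction, mean_depth
    bin_size: int

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def gc_bias(track: CoverageTrack, genome: GenomeSequence,
            bin_size: int) -> GCBiasTable:
    """G+C fraction and mean depth in consecutive ``bin_size`` bp bins.

    Bins tile the genome left to right; a trailing partial bin is kept
    with its actual length.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    L = len(genome)
    if len(track) != L:
        raise ValueError("track length does not match genome length")
    is_gc = np.frombuffer(genome.seq.encode(), dtype=np.uint8)
    is_gc = (is_gc == ord("G")) | (is_gc == ord("C"))
    edges = np.arange(0, L + bin_size, bin_size)
    edges[-1] = min(edges[-1], L)
    if edges[-1] == edges[-2]:
        edges = edges[:-1]
    gc_cum = np.concatenate([[0], np.cumsum(is_gc)])
    d_cum = np.concatenate([[0], np.cumsum(track.depth, dtype=np.float64)])
    lens = np.diff(edges)
    rows = pd.DataFrame({
        "bin_start": edges[:-1],
        "bin_len": lens,
        "gc_fraction": (gc_cum[edges[1:]] - gc_cum[edges[:-1]]) / lens,
        "mean_depth": (d_cum[edges[1:]] - d_cum[edges[:-1]]) / lens,
    })
    return GCBiasTable(rows, bin_size)


def merge_intervals(intervals) -> list[tuple[int, int]]:
    """Merge possibly overlapping 0-based half-open intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    for s, e in ivs:
        if s >= e:
            raise ValueError(f"malformed interval [{s}, {e})")
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def on_target_stats(alignments, targets, slop: int = 100,
                    genome_length: int | None = None,
                    exclude_duplicates: bool = True) -> tuple[float, float]:
    """On-target fraction of aligned bases and fraction of target covered.

    An aligned base is on target when it lies within ``slop`` bp
    (inclusive) of a target interval.  A target position is covered when
    its depth is at least one.  Targets are merged before use.
    """
    alignments = list(alignments)
    merged = merge_intervals(targets)
    if genome_length is None:
        hi = max((p.end2 for p in alignments), default=0)
        genome_length = max(hi, merged[-1][1] if merged else 0) + slop
    # position weight 1 within slop of a target, via prefix sums
    near = np.zeros(genome_length + 1, dtype=np.int64)
    for s, e in merged:
        near[max(0, s - slop)] += 1
        near[min(genome_length, e + slop)] -= 1
    near_cum = np.concatenate([[0], np.cumsum(np.cumsum(near[:-1]) > 0)])

    total_bases = 0
    on_bases = 0
    for p in alignments:
        if exclude_duplicates and p.is_duplicate:
            continue
        if p.read_len is None:
            ivs = [(p.start1, p.end2)]
        else:
            ivs = [(p.start1, min(p.start1 + p.read_len, p.end2)),
                   (max(p.end2 - p.read_len, p.start1), p.end2)]
        for s, e in ivs:
            total_bases += e - s
            on_bases += int(near_cum[e] - near_cum[s])
    on_target_fraction = on_bases / total_bases if total_bases else 0.0

    track = depth_from_alignments(alignments, genome_length,
                                  exclude_duplicates=exclude_duplicates)
    target_positions = 0
    covered = 0
    for s, e in merged:
        target_positions += e - s
        covered += int((track.depth[s:e] >= 1).sum())
    covered_fraction = covered / target_positions if target_positions else 0.0
    return on_target_fraction, covered_fraction
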
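"""Fragmentation-site bias profiling.

The genomic position of the first sequenced base of each read (the
fragmentation site) carries the signature of how the library was
fragmented.  Stacking the reference context around every site — as-is
for forward-strand reads, reverse-complemented around the 5' genomic end
for reverse-strand reads — gives a positional weight matrix (PWM), whose
per-offset information content

    IC(w) = log2(J) + sum_j p_wj * log2(p_wj),   J = 4

quantifies the bias on a 0–2 bit scale (0 = no preference, 2 = fixed
base).  Background base frequencies are deliberately not factored in.

Offset convention: offset 0 is the first sequenced base; negative
offsets are upstream in read orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simdata import BASES, GenomeSequence, seq_to_codes

#: two-base IUPAC degeneracy codes keyed by unordered base pair
_PAIR_CODES = {frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
               frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M"}


@dataclass(frozen=True)
class AlignedReadPair:
    """Outer mapping coordinates of a properly oriented read pair.

    ``start1`` is the leftmost mapped position of read 1 and ``end2`` the
    exclusive end of read 2's mapping, so ``end2 - start1`` is the insert
    size.  ``strand1`` records read 1's orientation ('+' or '-').
    """

    genome: str
    start1: int
    end2: int
    strand1: str = "+"
    mapq: int = 60
    is_duplicate: bool = False
    read_len: int | None = None

    def __post_init__(self):
        if self.strand1 not in "+-":
            raise ValueError(f"strand1 must be '+' or '-', got {self.strand1!r}")

    @property
    def insert_size(self) -> int:
        return self.end2 - self.start1


def sites_from_pairs(pairs, exclude_duplicates: bool = True,
                     min_mapq: int = 1):
    """Fragmentation sites (position, strand) from aligned pairs.

    Each pair contributes two sites: read 1's start on the forward strand
    and read 2's 5' genomic base (``end2 - 1``) on the reverse strand.
    Duplicate-marked and sub-``min_mapq`` pairs are dropped by default so
    one fragmentation event is counted once.
    """
    sites = []
    for p in pairs:
        if exclude_duplicates and p.is_duplicate:
            continue
        if p.mapq < min_mapq:
            continue
        sites.append((p.start1, "+"))
        sites.append((p.end2 - 1, "-"))
    return sites


def sites_from_fragments(fragments, ends: str = "both"):
    """Fragmentation sites from simulator truth fragments.

    ``ends='start'`` stacks only forward (fragment-start) contexts, the
    orientation in which the simulator applied its insertion preference.
    """
    if ends not in ("both", "start", "end"):
        raise ValueError("ends must be 'both', 'start' or 'end'")
    sites = []
    for f in fragments:
        if ends in ("both", "start"):
            sites.append((f.start, "+"))
        if ends in ("both", "end"):
            sites.append((f.end - 1, "-"))
    return sites


@dataclass
class FragSiteProfile:
    """Stacked base counts around fragmentation sites.

    ``counts[i, j]`` is the tally of base ``BASES[j]`` at ``offsets[i]``.
    Sites whose window overruns the sequence are skipped and counted in
    ``n_skipped``.
    """

    offsets: np.ndarray
    counts: np.ndarray
    n_sites: int
    n_skipped: int = 0

    @property
    def half_window(self) -> int:
        return int(self.offsets.max())

    @property
    def freqs(self) -> np.ndarray:
        """Per-offset base frequencies p_wj (rows sum to 1; NaN if empty)."""
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, self.counts / totals, np.nan)

    def index_of(self, offset: int) -> int:
        idx = int(np.searchsorted(self.offsets, offset))
        if idx >= self.offsets.size or self.offsets[idx] != offset:
            raise ValueError(f"offset {offset} outside profile window")
        return idx

    def to_frame(self) -> pd.DataFrame:
        freqs = self.freqs
        ic = information_content(self)
        data = {"offset": self.offsets}
        for j, b in enumerate(BASES):
            data[f"count{b}"] = self.counts[:, j]
        for j, b in enumerate(BASES):
            data[f"p{b}"] = freqs[:, j]
        data["IC"] = ic
        return pd.DataFrame(data)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def collect_contexts(alignments, genome: GenomeSequence,
                     half_window: int = 20, exclude_duplicates: bool = True,
                     min_mapq: int = 1) -> FragSiteProfile:
    """Stack genomic context around fragmentation sites into a profile.

    ``alignments`` may be ``AlignedReadPair`` objects (both reads of each
    pair are stacked) or pre-extracted ``(position, strand)`` site tuples.
    Forward-strand sites contribute the window ``[pos - W, pos + W]``
    as-is; reverse-strand sites the reverse complement of the window
    around their 5' genomic base, so offset 0 is always the first
    sequenced base.
    """
    alignments = list(alignments)
    if not alignments:
        raise ValueError("no alignments supplied")
    if half_window < 1:
        raise ValueError("half_window must be >= 1")
    if isinstance(alignments[0], AlignedReadPair):
        sites = sites_from_pairs(alignments, exclude_duplicates, min_mapq)
    else:
        sites = alignments

    codes = seq_to_codes(genome.seq)
    L = codes.size
    W = half_window
    pos = np.fromiter((s[0] for s in sites), dtype=np.int64, count=len(sites))
    fwd = np.fromiter((s[1] == "+" for s in sites), dtype=bool, count=len(sites))
    in_bounds = (pos - W >= 0) & (pos + W < L)
    n_skipped = int((~in_bounds).sum())

    offs = np.arange(-W, W + 1)
    counts = np.zeros((2 * W + 1, 4), dtype=np.int64)
    p_fwd = pos[in_bounds & fwd]
    p_rev = pos[in_bounds & ~fwd]
    if p_fwd.size:
        win = codes[p_fwd[:, None] + offs[None, :]]
        for i in range(offs.size):
            counts[i] += np.bincount(win[:, i], minlength=4)
    if p_rev.size:
        # context base at offset k is the complement of the base at pos - k
        win = 3 - codes[p_rev[:, None] - offs[None, :]]
        for i in range(offs.size):
            counts[i] += np.bincount(win[:, i], minlength=4)
    return FragSiteProfile(offsets=offs, counts=counts,
                           n_sites=int(in_bounds.sum()), n_skipped=n_skipped)


def information_content(profile: FragSiteProfile) -> np.ndarray:
    """Per-offset information content in bits, on the 0–2 scale.

    Uses the convention 0*log2(0) = 0.  Offsets with no stacked bases are
    undefined and returned as NaN rather than 0.
    """
    freqs = profile.freqs
    with np.errstate(invalid="ignore", divide="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(np.where(freqs > 0, freqs, 1.0)), 0.0)
    ic = 2.0 + plogp.sum(axis=1)
    ic[np.isnan(freqs).any(axis=1)] = np.nan
    # guard against -eps from float round-off in the entropy sum
    return np.where(np.isnan(ic), np.nan, np.maximum(ic, 0.0))


def ic_summary(profile: FragSiteProfile, range_bp: int = 10) -> tuple[float, float]:
    """(max, mean) information content over offsets within ±``range_bp``."""
    if range_bp > profile.half_window:
        raise ValueError(f"range_bp {range_bp} exceeds profile half-window "
                         f"{profile.half_window}")
    ic = information_content(profile)
    sel = ic[np.abs(profile.offsets) <= range_bp]
    if np.isnan(sel).any():
        raise ValueError("information content undefined inside requested range")
    return float(sel.max()), float(sel.mean())


def consensus(profile: FragSiteProfile, primary_threshold: float = 0.45,
              pair_threshold: float = 0.65, offsets=None) -> str:
    """IUPAC consensus string of the profile.

    Per offset: a single base when its frequency reaches
    ``primary_threshold`` and the runner-up stays below the two-base
    floor; a two-base degeneracy code when the top two jointly reach
    ``pair_threshold`` and each exceeds uniform by at least half the
    pair threshold's excess over 0.5; otherwise N.
    """
    freqs = profile.freqs
    secondary_floor = 0.25 + (pair_threshold - 0.5) / 2.0
    if offsets is None:
        rows = range(len(profile.offsets))
    else:
        rows = [profile.index_of(o) for o in offsets]
    out = []
    for i in rows:
        f = freqs[i]
        if np.isnan(f).any():
            out.append("N")
            continue
        order = np.argsort(f)[::-1]
        f1, f2 = f[order[0]], f[order[1]]
        b1, b2 = BASES[order[0]], BASES[order[1]]
        if f1 >= primary_threshold and f2 < secondary_floor:
            out.append(b1)
        elif f1 + f2 >= pair_threshold and f2 >= secondary_floor:
            out.append(_PAIR_CODES[frozenset((b1, b2))])
        else:
            out.append("N")
    return "".join(out)
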
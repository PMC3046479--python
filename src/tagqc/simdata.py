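"""Synthetic tagmentation libraries with known ground truth.

Hyperactive Tn5 transposase fragments target DNA and joins a 19 bp
mosaic-end adaptor to the 5' side of each break in a single reaction
("tagmentation").  Two physical features dominate the statistics of the
resulting shotgun library:

* a weak, palindromic insertion-sequence preference (``AGNTYWRANCT``),
  modelled here as a positional probability matrix mixed with uniform
  background by a ``strength`` parameter in [0, 1];
* steric exclusion between adjacent transposase homodimers: the enzyme
  core acts on a 9 bp region (duplicated on insertion) and protects
  roughly 10 flanking bases on each side, so adjacent insertion events
  cannot sit closer than ``2 * (core + flank)`` ~ 38 bp, which puts a
  hard floor on the insert-size distribution.

This module simulates genomes, insertion events subject to both effects,
PCR duplication, sequencing error and adaptor read-through, and emits
paired reads, 9 bp index reads and a tab-separated truth table so that
every downstream QC computation can be exercised against known truth.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = "ACGT"

#: 19 bp hyperactive Tn5 mosaic-end adaptor appended to fragment ends;
#: appears inside reads whenever the insert is shorter than the read.
MOSAIC_END = "CTGTCTCTTATACACATCT"

#: Reported insertion preference of native Tn5.
TN5_MOTIF = "AGNTYWRANCT"

IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_CODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE_TABLE[ord(_b)] = _i
_BASE_BYTES = np.frombuffer(BASES.encode(), dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode an A/C/G/T string as uint8 codes 0..3."""
    codes = _CODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if codes.size and codes.max() == 255:
        bad = chr(int(np.frombuffer(seq.encode(), np.uint8)[codes == 255][0]))
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return codes


def codes_to_seq(codes: np.ndarray) -> str:
    return _BASE_BYTES[codes].tobytes().decode("ascii")


@dataclass(frozen=True)
class GenomeSequence:
    """A named reference sequence over the strict A/C/G/T alphabet."""

    name: str
    seq: str

    def __post_init__(self):
        if not self.seq:
            raise ValueError("genome sequence must be non-empty")
        seq_to_codes(self.seq)  # alphabet check

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def gc_content(self) -> float:
        return (self.seq.count("G") + self.seq.count("C")) / len(self.seq)


def simulate_genome(length: int, gc_content: float, seed: int) -> GenomeSequence:
    """I.i.d. random genome with P(G)=P(C)=gc/2 and P(A)=P(T)=(1-gc)/2."""
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    if not 0.0 <= gc_content <= 1.0:
        raise ValueError(f"gc_content must be in [0, 1], got {gc_content}")
    rng = np.random.default_rng(seed)
    at, gc = (1.0 - gc_content) / 2.0, gc_content / 2.0
    t1, t2, t3 = at, at + gc, at + 2 * gc  # cumulative bounds, order A,C,G,T
    u = rng.random(length)
    codes = (u >= t1).astype(np.uint8)
    codes += u >= t2
    codes += u >= t3
    return GenomeSequence(f"sim_gc{gc_content:g}_seed{seed}", codes_to_seq(codes))


@dataclass(frozen=True)
class InsertionPreference:
    """Positional base-probability model for the transposase insertion site.

    ``probs`` has one row per motif position (columns A, C, G, T, summing
    to 1).  ``anchor`` gives the row aligned with the first base of the
    inserted-adaptor junction (offset 0 of a fragmentation-site profile);
    the default 3 puts the 4th motif position (the T of AGNTYWRANCT) on
    the junction, so the bias profile is asymmetric around the read start.
    """

    probs: np.ndarray
    strength: float = 0.0
    anchor: int = 3

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4:
            raise ValueError("probs must be an (window_length, 4) array")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each motif position's probabilities must sum to 1")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("strength must be in [0, 1]")
        if not 0 <= self.anchor < p.shape[0]:
            raise ValueError("anchor must index a motif position")
        object.__setattr__(self, "probs", p)

    @property
    def window_length(self) -> int:
        return self.probs.shape[0]

    @classmethod
    def uniform(cls, window_length: int = 11, anchor: int = 3) -> "InsertionPreference":
        return cls(np.full((window_length, 4), 0.25), strength=0.0, anchor=anchor)


def iupac_to_preference(motif: str, strength: float,
                        anchor: int | None = None) -> InsertionPreference:
    """Mix a degenerate IUPAC motif with uniform background.

    Per position: ``strength * uniform-over-allowed + (1-strength) * 0.25``.
    The default anchor is position 4 of the motif (or its last position
    for shorter motifs).
    """
    if anchor is None:
        anchor = min(3, len(motif) - 1)
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must be in [0, 1]")
    rows = []
    for ch in motif.upper():
        allowed = IUPAC_CODES.get(ch)
        if allowed is None:
            raise ValueError(f"unknown IUPAC code {ch!r} in motif")
        row = np.full(4, (1.0 - strength) * 0.25)
        for b in allowed:
            row[BASES.index(b)] += strength / len(allowed)
        rows.append(row)
    return InsertionPreference(np.array(rows), strength=strength, anchor=anchor)


@dataclass(frozen=True)
class StericModel:
    """Footprint geometry of the transposase homodimer.

    The core acts on ``core_bp`` bases (duplicated on insertion) and
    protects ``flank_bp`` bases on either side, so adjacent insertion
    events are at least ``2 * (core_bp + flank_bp)`` bp apart.
    """

    core_bp: int = 9
    flank_bp: int = 10

    def __post_init__(self):
        if self.core_bp < 0 or self.flank_bp < 0:
            raise ValueError("core_bp and flank_bp must be non-negative")

    @property
    def min_spacing(self) -> int:
        return 2 * (self.core_bp + self.flank_bp)


def min_spacing(steric: StericModel) -> int:
    """Minimum distance between adjacent insertion events, in bp."""
    return steric.min_spacing


@dataclass(frozen=True)
class TagmentationModel:
    """All tunable parameters of a simulated tagmentation library."""

    preference: InsertionPreference = field(default_factory=InsertionPreference.uniform)
    steric: StericModel = field(default_factory=StericModel)
    size_min: int | None = None
    size_max: int | None = None
    dup_rate: float = 0.0
    error_rate: float = 0.0
    read_len: int = 36
    adaptor_seq: str = MOSAIC_END
    #: optional helical-pitch modulation of acceptance near the steric
    #: floor (DNA winds away from the bound transposase, so insertion is
    #: easier at whole-turn spacings); off by default
    pitch_amplitude: float = 0.0
    pitch_period: float = 10.5

    def __post_init__(self):
        if not 0.0 <= self.dup_rate < 1.0:
            raise ValueError("dup_rate must be in [0, 1)")
        if not 0.0 <= self.pitch_amplitude <= 1.0:
            raise ValueError("pitch_amplitude must be in [0, 1]")
        if self.pitch_period <= 0:
            raise ValueError("pitch_period must be positive")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if self.read_len < 1:
            raise ValueError("read_len must be >= 1")
        if self.size_min is not None and self.size_min < self.steric.min_spacing:
            raise ValueError(
                f"size_min {self.size_min} below steric floor "
                f"{self.steric.min_spacing}")
        seq_to_codes(self.adaptor_seq)


@dataclass(frozen=True)
class TruthFragment:
    """A simulated progenitor fragment between two adjacent insertion sites."""

    genome: str
    start: int
    end: int
    molecule_id: int = 0

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"need 0 <= start < end, got [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


def preference_scores(genome: GenomeSequence,
                      preference: InsertionPreference) -> np.ndarray:
    """Per-position insertion score: product of motif probabilities over
    the window anchored at each candidate junction.  Positions whose
    window overruns the sequence get score 0.
    """
    codes = seq_to_codes(genome.seq)
    L = codes.size
    W, a = preference.window_length, preference.anchor
    scores = np.zeros(L, dtype=np.float32)
    lo, hi = a, L - (W - a) + 1
    if hi <= lo:
        return scores
    n = hi - lo
    s = np.ones(n, dtype=np.float32)
    probs32 = preference.probs.astype(np.float32)
    for i in range(W):
        s *= probs32[i, codes[lo - a + i: lo - a + i + n]]
    scores[lo:hi] = s
    return scores


def _draw_weighted(rng, cum_weights, n: int) -> np.ndarray:
    """n i.i.d. positions with probability proportional to the score."""
    idx = np.searchsorted(cum_weights, rng.random(n), side="right")
    return np.minimum(idx, cum_weights.size - 1)


def _spacing_accept(accepted: list[int], q: int, spacing: int,
                    rng=None, amplitude: float = 0.0,
                    period: float = 10.5) -> bool:
    """Accept q unless within ``spacing`` of an accepted site; keep sorted.

    With ``amplitude`` > 0, arrivals just above the floor are further
    thinned by a cosine of the gap to the nearest accepted neighbour
    (period ~ the DNA helical pitch), producing the ~10 bp ripple seen
    at the short end of real insert-size distributions.
    """
    i = bisect.bisect_left(accepted, q)
    right = accepted[i] - q if i < len(accepted) else None
    left = q - accepted[i - 1] if i > 0 else None
    if (right is not None and right < spacing) or \
            (left is not None and left < spacing):
        return False
    if amplitude > 0.0:
        gap = min(g for g in (left, right) if g is not None) \
            if (left is not None or right is not None) else None
        if gap is not None and gap < spacing + 4 * period:
            p = (1.0 + amplitude
                 * math.cos(2.0 * math.pi * (gap - spacing) / period)) \
                / (1.0 + amplitude)
            if rng.random() >= p:
                return False
    accepted.insert(i, q)
    return True


def _place_sites_all(rng, cum_weights, accept_mean, spacing, n_molecules,
                     attempts, target, amplitude=0.0, period=10.5):
    """Sequential insertion with steric exclusion, all molecules at once.

    Arrivals are candidate insertions that already passed the preference
    test (uniform candidate accepted w.p. score/max-score, realised as a
    Binomial count plus score-weighted positions); each arrival is then
    rejected if it falls within ``spacing`` of an already-accepted site
    on its molecule.  Draws are batched across molecules so the cost is
    dominated by a handful of vectorized weighted draws.
    """
    sites: list[list[int]] = [[] for _ in range(n_molecules)]
    if attempts is not None:
        n_arr = rng.binomial(attempts, accept_mean, size=n_molecules)
        draws = _draw_weighted(rng, cum_weights, int(n_arr.sum()))
        pos = 0
        for m in range(n_molecules):
            acc = sites[m]
            for q in draws[pos:pos + n_arr[m]]:
                _spacing_accept(acc, int(q), spacing, rng, amplitude, period)
            pos += n_arr[m]
        return sites
    need = np.full(n_molecules, target, dtype=np.int64)
    for _ in range(40):
        active = np.nonzero(need > 0)[0]
        if active.size == 0:
            break
        per = need[active] + np.maximum(4, need[active] // 2)
        draws = _draw_weighted(rng, cum_weights, int(per.sum()))
        pos = 0
        progress = False
        for m, k in zip(active, per):
            acc = sites[m]
            for q in draws[pos:pos + k]:
                if need[m] and _spacing_accept(acc, int(q), spacing, rng,
                                               amplitude, period):
                    need[m] -= 1
                    progress = True
            pos += k
        if not progress:  # every active molecule is steric-saturated
            break
    return sites


def simulate_tagmentation(genome: GenomeSequence, model: TagmentationModel,
                          n_molecules: int = 1, seed: int = 0,
                          attempts_per_molecule: int | None = None,
                          target_sites_per_molecule: int | None = None,
                          ) -> list[TruthFragment]:
    """Simulate transposase insertion on ``n_molecules`` copies of a genome.

    Insertion sites are placed sequentially: each candidate position is
    accepted with probability proportional to the preference score of the
    local motif window and rejected when it falls within the steric
    minimum spacing of a previously accepted site on the same molecule.
    Fragments are the intervals between adjacent accepted sites; fragments
    outside ``[size_min, size_max]`` are discarded when bounds are set.

    ``attempts_per_molecule`` sets the transposome exposure (number of
    candidate insertions); the default is a near-saturating ``10 * L /
    min_spacing`` under a flat preference.  Alternatively
    ``target_sites_per_molecule`` keeps drawing candidates until that many
    sites are accepted (or placement stalls), which is the natural control
    for sub-saturating libraries.
    """
    ms = model.steric.min_spacing
    L = len(genome)
    if L <= ms:
        raise ValueError(f"genome length {L} must exceed minimum spacing {ms}")
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    rng = np.random.default_rng(seed)
    scores = preference_scores(genome, model.preference)
    # accumulate in float64 so even background-level weights stay resolvable
    cum_weights = np.cumsum(scores, dtype=np.float64)
    total = float(cum_weights[-1])
    if total <= 0:
        raise ValueError("insertion preference assigns zero weight everywhere")
    accept_mean = total / (float(scores.max()) * L)
    cum_weights /= total

    attempts = attempts_per_molecule
    if attempts is None and target_sites_per_molecule is None:
        # near-saturating exposure: enough candidates that the expected
        # number of preference-accepted arrivals is ~10 per spacing unit
        arrivals = 10 * max(L // max(ms, 1), 1)
        attempts = int(np.ceil(arrivals / accept_mean))

    all_sites = _place_sites_all(rng, cum_weights, accept_mean, ms,
                                 n_molecules, attempts,
                                 target_sites_per_molecule,
                                 model.pitch_amplitude, model.pitch_period)
    fragments: list[TruthFragment] = []
    for mol, sites in enumerate(all_sites):
        for s0, s1 in zip(sites, sites[1:]):
            fragments.append(TruthFragment(genome.name, int(s0), int(s1), mol))
    if model.size_min is not None:
        fragments = [f for f in fragments if f.length >= model.size_min]
    if model.size_max is not None:
        fragments = [f for f in fragments if f.length <= model.size_max]
    return fragments


def simulate_uniform_fragments(genome_length: int, n_fragments: int,
                               fragment_len: int, seed: int = 0,
                               genome_name: str = "sim") -> list[TruthFragment]:
    """Bias-free library: fixed-length fragments at uniform random starts.

    The marginal per-base depth of such a library is Binomial and, at
    genomic scale, indistinguishable from Poisson — the no-bias reference
    used for coverage-distribution overlays.
    """
    if fragment_len > genome_length:
        raise ValueError("fragment_len exceeds genome_length")
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, genome_length - fragment_len + 1, size=n_fragments)
    return [TruthFragment(genome_name, int(s), int(s) + fragment_len, i)
            for i, s in enumerate(starts)]


@dataclass
class SimulatedReads:
    """Paired reads, optional index reads, and the per-pair truth table."""

    reads1: list[tuple[str, str]]
    reads2: list[tuple[str, str]]
    index_reads: list[tuple[str, str]] | None
    truth: pd.DataFrame


def _read_through(frag_seq: str, read_len: int, adaptor: str) -> str:
    # short inserts run into the adaptor, then constant 'A' padding
    s = frag_seq if len(frag_seq) >= read_len else frag_seq + adaptor
    if len(s) < read_len:
        s += "A" * (read_len - len(s))
    return s[:read_len]


def _with_errors(seq: str, error_rate: float, rng) -> str:
    if error_rate <= 0.0:
        return seq
    codes = seq_to_codes(seq)
    hit = rng.random(codes.size) < error_rate
    n = int(hit.sum())
    if n:
        codes[hit] = (codes[hit] + rng.integers(1, 4, size=n)) % 4
    return codes_to_seq(codes)


def fragments_to_reads(fragments: list[TruthFragment], genome: GenomeSequence,
                       model: TagmentationModel, barcode: str | None = None,
                       seed: int = 0) -> SimulatedReads:
    """Emit paired FASTQ records (plus index reads) from truth fragments.

    Read 1 is the fragment's forward strand from its start; read 2 the
    reverse complement from its end.  Inserts shorter than the read length
    read through into the adaptor.  With probability ``dup_rate`` an
    emitted pair is a PCR duplicate: a previously chosen progenitor is
    re-emitted with fresh sequencing errors.  Index reads carry the
    barcode with i.i.d. substitution errors.
    """
    if barcode is not None:
        seq_to_codes(barcode)
    rng = np.random.default_rng(seed)
    rl, err = model.read_len, model.error_rate
    progenitors: list[TruthFragment] = []
    reads1, reads2, idx = [], [], []
    rows = []
    fresh = 0
    for k in range(len(fragments)):
        if progenitors and rng.random() < model.dup_rate:
            frag = progenitors[int(rng.integers(len(progenitors)))]
            dup = True
        else:
            frag = fragments[fresh]
            fresh += 1
            progenitors.append(frag)
            dup = False
        frag_seq = genome.seq[frag.start:frag.end]
        name = f"pair{k:07d}"
        reads1.append((name, _with_errors(
            _read_through(frag_seq, rl, model.adaptor_seq), err, rng)))
        reads2.append((name, _with_errors(
            _read_through(revcomp(frag_seq), rl, model.adaptor_seq), err, rng)))
        if barcode is not None:
            idx.append((name, _with_errors(barcode, err, rng)))
        rows.append((name, frag.genome, frag.start, frag.end,
                     frag.molecule_id, dup, barcode or ""))
    truth = pd.DataFrame(rows, columns=["read_id", "genome", "start", "end",
                                        "molecule_id", "is_duplicate", "barcode"])
    return SimulatedReads(reads1, reads2, idx if barcode is not None else None, truth)
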
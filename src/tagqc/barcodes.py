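"""Design and deconvolution of 9 bp sample-index barcodes.

A 96-plex index set is built so that every barcode: contains no
homopolymer run of three or more bases, has GC content of at most 60%,
contains each of the four bases at least once, screens negative against
the adaptor and primer sequences used in library construction, and sits
at Levenshtein distance at least four from every other member; across
the set, every base appears at least once at every position.

Deconvolution computes the Levenshtein edit distance between an index
read and every barcode and assigns the read when the best barcode is
within ``max_dist`` edits and the runner-up is at least ``margin``
further edits away.  With a minimum pairwise distance of four and the
default rule (2, 2), every single-error index read is still assigned to
its true barcode, by the triangle inequality.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .simdata import MOSAIC_END, revcomp, seq_to_codes

#: Full-length sequencing adaptors used alongside the mosaic end; the
#: default screen list for barcode design.
ADAPTOR_P5 = ("AATGATACGGCGACCACCGAGATCTACACGCCTCCCTCGCGCCATCAG"
              "AGATGTGTATAAGAGACAG")
ADAPTOR_P7 = ("CAAGCAGAAGACGGCATACGAGATCGGTCTGCCTTGCCAGCCCGCTCAG"
              "AGATGTGTATAAGAGACAG")
DEFAULT_SCREEN_SEQS = (MOSAIC_END, ADAPTOR_P5, ADAPTOR_P7)


def levenshtein(a: str, b: str) -> int:
    """Unit-cost Levenshtein edit distance (substitution/insertion/deletion)."""
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1,          # deletion
                           cur[j - 1] + 1,       # insertion
                           prev[j - 1] + (ca != cb)))  # substitution
        prev = cur
    return prev[-1]


@dataclass(frozen=True)
class BarcodeDesignSpec:
    """Constraint system for an index-barcode set."""

    n: int = 96
    length: int = 9
    min_edit: int = 4
    max_gc: float = 0.60
    max_run: int = 2
    require_all_bases_per_barcode: bool = True
    require_all_bases_per_position: bool = True
    screen_seqs: tuple[str, ...] = DEFAULT_SCREEN_SEQS

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.min_edit > self.length:
            raise ValueError("min_edit cannot exceed barcode length")
        if self.max_run < 1:
            raise ValueError("max_run must be >= 1")


def _longest_run(seq: str) -> int:
    best = run = 1
    for prev, cur in zip(seq, seq[1:]):
        run = run + 1 if cur == prev else 1
        best = max(best, run)
    return best


def passes_composition(seq: str, spec: BarcodeDesignSpec) -> tuple[bool, str]:
    """Check homopolymer-run, GC and base-representation constraints.

    Returns (ok, reason); reason is "" when the sequence passes.
    """
    seq_to_codes(seq)
    run = _longest_run(seq)
    if run > spec.max_run:
        return False, f"homopolymer run of {run}"
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    if gc > spec.max_gc + 1e-12:
        return False, f"GC fraction {gc:.3f} > {spec.max_gc}"
    if spec.require_all_bases_per_barcode and len(set(seq)) < 4:
        missing = sorted(set("ACGT") - set(seq))
        return False, f"missing base(s) {''.join(missing)}"
    return True, ""


def screen_against(seq: str, screen_seqs) -> bool:
    """True iff neither ``seq`` nor its reverse complement occurs as an
    exact substring of any screen sequence (either orientation)."""
    rc = revcomp(seq)
    for s in screen_seqs:
        for hay in (s, revcomp(s)):
            if seq in hay or rc in hay:
                return False
    return True


@dataclass
class BarcodeSet:
    """A designed (or user-supplied) index set plus its constraint spec."""

    barcodes: list[str]
    spec: BarcodeDesignSpec
    min_pairwise_edit: int | None = None

    def __len__(self) -> int:
        return len(self.barcodes)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for bc in self.barcodes:
                fh.write(bc + "\n")

    @classmethod
    def read(cls, path, spec: BarcodeDesignSpec | None = None) -> "BarcodeSet":
        with open(path) as fh:
            barcodes = [ln.strip().split("\t")[-1] for ln in fh
                        if ln.strip() and not ln.startswith("#")]
        return cls(barcodes, spec or BarcodeDesignSpec(n=len(barcodes)))


class InfeasibleDesignError(ValueError):
    """Raised when the design search cannot reach the requested set size;
    carries the best set found in ``best_set``."""

    def __init__(self, message: str, best_set: BarcodeSet):
        super().__init__(message)
        self.best_set = best_set


def _composition_pool(spec: BarcodeDesignSpec, max_candidates=None,
                      rng=None) -> list[str]:
    n_total = 4 ** spec.length
    if max_candidates is not None and max_candidates < n_total:
        # too many to enumerate: sample candidates at random
        rng = rng or np.random.default_rng(0)
        codes = rng.integers(0, 4, size=(max_candidates, spec.length))
        cands = {"".join("ACGT"[c] for c in row) for row in codes}
    else:
        cands = ("".join(t) for t in
                 itertools.product("ACGT", repeat=spec.length))
    return [s for s in cands
            if passes_composition(s, spec)[0]
            and screen_against(s, spec.screen_seqs)]


def _positional_coverage(barcodes: list[str], length: int) -> np.ndarray:
    cov = np.zeros((length, 4), dtype=np.int64)
    for bc in barcodes:
        for i, b in enumerate(bc):
            cov[i, "ACGT".index(b)] += 1
    return cov


def design_barcodes(spec: BarcodeDesignSpec | None = None, seed: int = 0,
                    max_candidates: int | None = None,
                    max_restarts: int = 8) -> BarcodeSet:
    """Randomized greedy search for a barcode set satisfying ``spec``.

    The composition- and screening-valid candidate pool is shuffled under
    ``seed`` and candidates are accepted greedily when at least
    ``min_edit`` from every accepted barcode.  Missing per-position base
    coverage is repaired by targeted swaps; the search restarts with a
    fresh shuffle up to ``max_restarts`` times.  The returned set has
    passed an independent full validation.
    """
    spec = spec or BarcodeDesignSpec()
    pool = _composition_pool(spec, max_candidates)
    if not pool:
        raise InfeasibleDesignError("no candidate passes composition and "
                                    "screening", BarcodeSet([], spec))
    ss = np.random.SeedSequence(seed)
    best: list[str] = []
    for child in ss.spawn(max_restarts):
        rng = np.random.default_rng(child)
        order = rng.permutation(len(pool))
        accepted: list[str] = []
        for idx in order:
            cand = pool[idx]
            if all(levenshtein(cand, bc) >= spec.min_edit for bc in accepted):
                accepted.append(cand)
                if len(accepted) >= spec.n:
                    break
        if spec.require_all_bases_per_position and len(accepted) >= spec.n:
            accepted = _repair_positional_coverage(accepted, pool, spec)
        if len(accepted) > len(best):
            best = accepted
        if len(accepted) >= spec.n:
            candidate = BarcodeSet(accepted[:spec.n], spec)
            report = validate_barcode_set(candidate, spec)
            if report.passed:
                candidate.min_pairwise_edit = report.min_pairwise_edit
                return candidate
    raise InfeasibleDesignError(
        f"could not assemble {spec.n} barcodes (best: {len(best)})",
        BarcodeSet(best, spec))


def _repair_positional_coverage(accepted, pool, spec):
    """Swap members so every base occurs at every position, never
    increasing the number of uncovered (position, base) cells."""
    cov = _positional_coverage(accepted, spec.length)
    for pos in range(spec.length):
        for j, base in enumerate("ACGT"):
            if cov[pos, j] > 0:
                continue
            taken = set(accepted)
            done = False
            for cand in pool:
                if done:
                    break
                if cand[pos] != base or cand in taken:
                    continue
                cand_cov = _positional_coverage([cand], spec.length)
                for k, old in enumerate(accepted):
                    new_cov = cov - _positional_coverage([old], spec.length) \
                        + cand_cov
                    if (new_cov == 0).sum() >= (cov == 0).sum():
                        continue
                    keep = accepted[:k] + accepted[k + 1:]
                    if all(levenshtein(cand, bc) >= spec.min_edit
                           for bc in keep):
                        accepted[k] = cand
                        cov = new_cov
                        done = True
                        break
    return accepted


@dataclass
class BarcodeValidationReport:
    """Independent re-check of every design constraint."""

    min_pairwise_edit: int
    max_gc: float
    max_run: int
    position_coverage: np.ndarray  # (length, 4) counts
    composition_failures: list[tuple[str, str]]
    screen_failures: list[str]
    n_barcodes: int
    spec: BarcodeDesignSpec

    @property
    def positional_coverage_ok(self) -> bool:
        if not self.spec.require_all_bases_per_position:
            return True
        return bool((self.position_coverage > 0).all())

    @property
    def passed(self) -> bool:
        return (self.n_barcodes >= 1
                and self.min_pairwise_edit >= self.spec.min_edit
                and self.max_gc <= self.spec.max_gc + 1e-12
                and self.max_run <= self.spec.max_run
                and not self.composition_failures
                and not self.screen_failures
                and self.positional_coverage_ok)


def validate_barcode_set(bset: BarcodeSet,
                         spec: BarcodeDesignSpec | None = None
                         ) -> BarcodeValidationReport:
    """Re-check a barcode set against its constraint spec from scratch."""
    spec = spec or bset.spec
    bcs = bset.barcodes
    comp_fail = []
    screen_fail = []
    for bc in bcs:
        ok, why = passes_composition(bc, spec)
        if not ok:
            comp_fail.append((bc, why))
        if not screen_against(bc, spec.screen_seqs):
            screen_fail.append(bc)
    min_edit = min((levenshtein(a, b)
                    for a, b in itertools.combinations(bcs, 2)),
                   default=spec.length)
    max_gc = max(((bc.count("G") + bc.count("C")) / len(bc) for bc in bcs),
                 default=0.0)
    max_run = max((_longest_run(bc) for bc in bcs), default=0)
    cov = _positional_coverage(bcs, spec.length) if bcs else \
        np.zeros((spec.length, 4), dtype=np.int64)
    return BarcodeValidationReport(min_edit, max_gc, max_run, cov,
                                   comp_fail, screen_fail, len(bcs), spec)


@dataclass(frozen=True)
class DemuxRule:
    """Distance/margin assignment rule for index deconvolution."""

    max_dist: int = 2
    margin: int = 2

    def __post_init__(self):
        if self.max_dist < 0 or self.margin < 0:
            raise ValueError("max_dist and margin must be non-negative")


def demux(index_read: str, bset: BarcodeSet,
          rule: DemuxRule = DemuxRule()) -> tuple[int, int] | None:
    """Assign one index read, or return None when ambiguous.

    Returns ``(barcode index, distance)`` when the closest barcode is
    within ``rule.max_dist`` edits and the runner-up is at least
    ``rule.margin`` further edits away; ties at the minimum are always
    unassigned.
    """
    if not bset.barcodes:
        raise ValueError("empty barcode set")
    # fast path: an exact match wins outright when the set's pairwise
    # floor already guarantees the margin
    if (bset.min_pairwise_edit is not None
            and bset.min_pairwise_edit >= rule.margin):
        try:
            return bset.barcodes.index(index_read), 0
        except ValueError:
            pass
    dists = [levenshtein(index_read, bc) for bc in bset.barcodes]
    order = np.argsort(dists, kind="stable")
    d_min = dists[order[0]]
    d_second = dists[order[1]] if len(dists) > 1 else d_min + rule.margin
    if d_min <= rule.max_dist and d_second >= d_min + rule.margin:
        return int(order[0]), d_min
    return None


@dataclass
class DemuxSummary:
    """Aggregate deconvolution outcome over a batch of index reads."""

    fraction_by_distance: dict[int, float]
    fraction_unassigned: float
    per_barcode_counts: np.ndarray
    n_reads: int

    @property
    def count_ratio(self) -> float:
        """Max/min per-barcode read count (inf when a barcode got none)."""
        lo = self.per_barcode_counts.min()
        return float(self.per_barcode_counts.max() / lo) if lo else float("inf")


def demux_summary(index_reads, bset: BarcodeSet,
                  rule: DemuxRule = DemuxRule()) -> DemuxSummary:
    """Demultiplex a batch of index reads and summarize the outcome."""
    counts = np.zeros(len(bset.barcodes), dtype=np.int64)
    by_dist = {d: 0 for d in range(rule.max_dist + 1)}
    unassigned = 0
    n = 0
    for read in index_reads:
        seq = read[1] if isinstance(read, tuple) else read
        n += 1
        hit = demux(seq, bset, rule)
        if hit is None:
            unassigned += 1
        else:
            idx, d = hit
            counts[idx] += 1
            by_dist[d] += 1
    if n == 0:
        raise ValueError("no index reads supplied")
    return DemuxSummary({d: c / n for d, c in by_dist.items()},
                        unassigned / n, counts, n)
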
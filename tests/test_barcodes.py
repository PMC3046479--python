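"""Barcode constraints, design search, validation and deconvolution."""

import itertools
from functools import lru_cache

import edlib
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tagqc.barcodes import (
    BarcodeDesignSpec,
    BarcodeSet,
    DemuxRule,
    InfeasibleDesignError,
    demux,
    demux_summary,
    design_barcodes,
    levenshtein,
    passes_composition,
    screen_against,
    validate_barcode_set,
)
from tagqc.simdata import _with_errors

DNA = st.text(alphabet="ACGT", min_size=0, max_size=12)


def _brute_levenshtein(a: str, b: str) -> int:
    """Exponential-time recursive definition, the textbook oracle."""
    @lru_cache(maxsize=None)
    def rec(i, j):
        if i == 0:
            return j
        if j == 0:
            return i
        return min(rec(i - 1, j) + 1, rec(i, j - 1) + 1,
                   rec(i - 1, j - 1) + (a[i - 1] != b[j - 1]))
    return rec(len(a), len(b))


class TestLevenshtein:
    @pytest.mark.parametrize("a,b,d", [
        ("ACGTACGTA", "ACGTACGTA", 0),
        ("ACGTACGTA", "ACGAACGTA", 1),
        ("", "ACG", 3),
        ("AC", "CA", 2),
        ("ACGT", "AGT", 1),
    ])
    def test_known_distances(self, a, b, d):
        assert levenshtein(a, b) == d

    def test_against_recursive_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(150):
            a = "".join(rng.choice(list("ACGT"), rng.integers(0, 7)))
            b = "".join(rng.choice(list("ACGT"), rng.integers(0, 7)))
            assert levenshtein(a, b) == _brute_levenshtein(a, b)

    @settings(derandomize=True, max_examples=150)
    @given(DNA, DNA)
    def test_against_edlib(self, a, b):
        if a and b:
            assert levenshtein(a, b) == edlib.align(a, b)["editDistance"]

    @settings(derandomize=True, max_examples=150)
    @given(DNA, DNA, DNA)
    def test_metric_properties(self, a, b, c):
        assert levenshtein(a, b) == levenshtein(b, a)
        assert (levenshtein(a, b) == 0) == (a == b)
        assert levenshtein(a, c) <= levenshtein(a, b) + levenshtein(b, c)


class TestComposition:
    def test_homopolymer_run_of_three_fails(self):
        ok, why = passes_composition("AAACGTCGT", BarcodeDesignSpec())
        assert not ok and "run" in why

    def test_valid_barcode_passes(self):
        ok, why = passes_composition("ACGTACGTA", BarcodeDesignSpec())
        assert ok and why == ""

    def test_high_gc_fails(self):
        ok, why = passes_composition("ACGCGCGCG", BarcodeDesignSpec())
        assert not ok and "GC" in why

    def test_missing_base_fails_when_required(self):
        ok, why = passes_composition("ACACACACT", BarcodeDesignSpec())
        assert not ok and "G" in why


class TestScreening:
    def test_substring_of_screen_sequence_fails(self):
        assert not screen_against("TACACATCT", ["CTGTCTCTTATACACATCT"])

    def test_empty_screen_list_passes(self):
        assert screen_against("ACGTACGTA", [])

    def test_reverse_complement_hit_fails(self):
        # revcomp("AGATGTGTA") = "TACACATCT", inside the mosaic end
        assert not screen_against("AGATGTGTA", ["CTGTCTCTTATACACATCT"])


class TestDesign:
    def test_default_spec_yields_96(self, designed_set):
        assert len(designed_set) >= 96

    def test_designed_set_validates(self, designed_set):
        report = validate_barcode_set(designed_set)
        assert report.passed
        assert report.min_pairwise_edit >= 4
        assert report.max_gc <= 0.60
        assert report.max_run <= 2
        assert report.positional_coverage_ok

    def test_infeasible_spec_rejected(self):
        with pytest.raises(ValueError):
            design_barcodes(BarcodeDesignSpec(n=2, length=3, min_edit=4))

    def test_overconstrained_search_reports_best_set(self):
        spec = BarcodeDesignSpec(n=200, length=4, min_edit=4, max_gc=1.0,
                                 max_run=4,
                                 require_all_bases_per_barcode=False,
                                 require_all_bases_per_position=False,
                                 screen_seqs=())
        with pytest.raises(InfeasibleDesignError) as exc:
            design_barcodes(spec, seed=1, max_restarts=2)
        assert len(exc.value.best_set) < 200

    def test_small_design_against_exhaustive_check(self):
        spec = BarcodeDesignSpec(n=4, length=4, min_edit=2, max_gc=1.0,
                                 max_run=4,
                                 require_all_bases_per_barcode=False,
                                 require_all_bases_per_position=False,
                                 screen_seqs=())
        bset = design_barcodes(spec, seed=2)
        assert len(bset) == 4
        for a, b in itertools.combinations(bset.barcodes, 2):
            assert levenshtein(a, b) >= 2
        # the full 4^4 pool must contain every returned member
        pool = {"".join(t) for t in itertools.product("ACGT", repeat=4)}
        assert set(bset.barcodes) <= pool


class TestValidator:
    def test_duplicated_barcode_fails(self, designed_set):
        corrupt = BarcodeSet(designed_set.barcodes[:-1]
                             + [designed_set.barcodes[0]],
                             designed_set.spec)
        report = validate_barcode_set(corrupt)
        assert report.min_pairwise_edit == 0 and not report.passed

    def test_corrupting_any_one_barcode_detected(self, designed_set):
        bad = "ACGCGCGCG"  # GC 7/9 violates composition
        corrupt = BarcodeSet(designed_set.barcodes[:-1] + [bad],
                             designed_set.spec)
        assert not validate_barcode_set(corrupt).passed

    def test_missing_base_at_position_fails_coverage(self):
        spec = BarcodeDesignSpec(n=2, length=4, min_edit=1, max_gc=1.0,
                                 max_run=4,
                                 require_all_bases_per_barcode=False,
                                 screen_seqs=())
        report = validate_barcode_set(BarcodeSet(["ACGT", "AGCT"], spec))
        assert not report.positional_coverage_ok


class TestDemux:
    def test_exact_member_assigned_at_zero(self, designed_set):
        hit = demux(designed_set.barcodes[5], designed_set)
        assert hit == (5, 0)

    def test_equidistant_tie_unassigned(self):
        spec = BarcodeDesignSpec(n=2, length=4, min_edit=2, max_gc=1.0,
                                 max_run=4,
                                 require_all_bases_per_barcode=False,
                                 require_all_bases_per_position=False,
                                 screen_seqs=())
        bset = BarcodeSet(["AAAA", "AACC"], spec)
        # "AAAC" is distance 1 from both members: margin violated
        assert demux("AAAC", bset, DemuxRule(2, 2)) is None

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            demux("ACGT", BarcodeSet([], BarcodeDesignSpec(n=1)))

    def test_two_substitution_reads_never_misassigned(self, designed_set):
        rng = np.random.default_rng(3)
        rule = DemuxRule(2, 2)
        for _ in range(400):
            i = int(rng.integers(96))
            bc = designed_set.barcodes[i]
            p, q = rng.choice(9, size=2, replace=False)
            read = list(bc)
            for pos in (int(p), int(q)):
                read[pos] = "ACGT"[(("ACGT".index(read[pos])
                                     + int(rng.integers(1, 4))) % 4)]
            hit = demux("".join(read), designed_set, rule)
            assert hit is None or hit[0] == i


class TestDemuxSummary:
    def test_error_free_reads_all_at_distance_zero(self, designed_set):
        reads = designed_set.barcodes * 3
        summary = demux_summary(reads, designed_set)
        assert summary.fraction_by_distance[0] == 1.0
        assert summary.fraction_unassigned == 0.0
        assert (summary.per_barcode_counts == 3).all()

    def test_fractions_sum_to_one(self, designed_set):
        rng = np.random.default_rng(4)
        reads = [_with_errors(designed_set.barcodes[int(rng.integers(96))],
                              0.02, rng) for _ in range(500)]
        s = demux_summary(reads, designed_set)
        total = sum(s.fraction_by_distance.values()) + s.fraction_unassigned
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_uniform_reads_give_uniform_counts(self, designed_set):
        rng = np.random.default_rng(5)
        n = 9_600
        reads = [designed_set.barcodes[int(i)]
                 for i in rng.integers(96, size=n)]
        s = demux_summary(reads, designed_set)
        lo, hi = stats.binom.interval(1 - 0.001 / 96, n, 1 / 96)
        assert s.per_barcode_counts.min() >= lo
        assert s.per_barcode_counts.max() <= hi

    def test_low_error_reads_rarely_unassigned(self, designed_set):
        rng = np.random.default_rng(6)
        reads = [_with_errors(designed_set.barcodes[int(rng.integers(96))],
                              0.005, rng) for _ in range(2_000)]
        s = demux_summary(reads, designed_set)
        assert s.fraction_unassigned < 0.01
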
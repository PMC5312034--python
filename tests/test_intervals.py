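"""Interval algebra: overlap predicates, sweep engine, TSS classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chipscape import (
    PeakSet,
    TSSIndex,
    TSSRecord,
    classify_peaks,
    compare_conditions,
    gap_overlap,
    intersect_sets,
    nearest_tss,
    overlaps,
)
from conftest import iv


def brute_force_pairs(a, b, min_overlap=1, max_gap=0):
    """All-pairs oracle for intersect_sets."""
    out = []
    for i, x in enumerate(a):
        for j, y in enumerate(b):
            if max_gap > 0:
                if gap_overlap(x, y, max_gap):
                    out.append((i, j))
            elif overlaps(x, y, min_overlap):
                out.append((i, j))
    return out


def random_peakset(rng, label, n, genome=100_000, width_max=400, chroms=("c1", "c2")):
    ivs = []
    for k in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, genome))
        width = int(rng.integers(1, width_max))
        ivs.append(iv(start, start + width, chrom=chrom, name=f"{label}{k}"))
    return PeakSet(label, ivs)


class TestOverlapPredicates:
    @pytest.mark.parametrize(
        "a,b,min_overlap,expected",
        [
            ((0, 100), (99, 200), 1, True),   # 1 bp shared at the boundary
            ((0, 100), (100, 200), 1, False),  # half-open adjacency
            ((0, 100), (95, 200), 10, False),  # 5 < 10
            ((0, 100), (50, 70), 20, True),    # containment, 20 bp
        ],
    )
    def test_overlaps_examples(self, a, b, min_overlap, expected):
        assert overlaps(iv(*a), iv(*b), min_overlap) is expected
        assert overlaps(iv(*b), iv(*a), min_overlap) is expected  # symmetric

    @pytest.mark.parametrize(
        "a,b,max_gap,expected",
        [
            ((0, 100), (250, 300), 200, True),   # gap 150
            ((0, 100), (301, 400), 200, False),  # gap 201
            ((0, 100), (50, 70), 0, True),       # overlapping
            ((0, 100), (100, 200), 0, True),     # adjacent: gap 0
        ],
    )
    def test_gap_overlap_examples(self, a, b, max_gap, expected):
        assert gap_overlap(iv(*a), iv(*b), max_gap) is expected
        assert gap_overlap(iv(*b), iv(*a), max_gap) is expected

    def test_different_chromosomes_never_overlap(self):
        assert not overlaps(iv(0, 100), iv(0, 100, chrom="chr2"))
        assert not gap_overlap(iv(0, 100), iv(0, 100, chrom="chr2"), 10**9)

    def test_argument_validation(self):
        with pytest.raises(ValueError):
            overlaps(iv(0, 10), iv(0, 10), min_overlap=0)
        with pytest.raises(ValueError):
            gap_overlap(iv(0, 10), iv(0, 10), max_gap=-1)

    @given(
        s1=st.integers(0, 500), w1=st.integers(1, 100),
        s2=st.integers(0, 500), w2=st.integers(1, 100),
    )
    @settings(max_examples=200, deadline=None)
    def test_gap_overlap_zero_equals_overlaps(self, s1, w1, s2, w2):
        # equivalence holds everywhere except book-ended intervals, whose
        # gap is exactly 0 and therefore within max_gap=0
        a, b = iv(s1, s1 + w1), iv(s2, s2 + w2)
        book_ended = a.end == b.start or b.end == a.start
        if book_ended:
            assert gap_overlap(a, b, 0)
        else:
            assert gap_overlap(a, b, 0) == overlaps(a, b, 1)


class TestIntersectSets:
    def test_boundary_pair(self):
        a = PeakSet("a", [iv(0, 100)])
        b = PeakSet("b", [iv(99, 200)])
        assert intersect_sets(a, b) == [(0, 0)]

    def test_far_apart_with_gap(self):
        a = PeakSet("a", [iv(0, 10)])
        b = PeakSet("b", [iv(500, 600)])
        assert intersect_sets(a, b, max_gap=200) == []

    @pytest.mark.parametrize("max_gap,min_overlap", [(0, 1), (0, 50), (200, 1)])
    def test_matches_all_pairs_oracle(self, max_gap, min_overlap):
        rng = np.random.default_rng(42 + max_gap + min_overlap)
        for _ in range(10):
            a = random_peakset(rng, "a", 200)
            b = random_peakset(rng, "b", 200)
            got = intersect_sets(a, b, min_overlap=min_overlap, max_gap=max_gap)
            want = brute_force_pairs(a, b, min_overlap=min_overlap, max_gap=max_gap)
            assert sorted(got) == sorted(want)


class TestNearestTss:
    def test_containment_gives_zero(self, tss_index):
        gene, dist = nearest_tss(iv(9_500, 9_700 + 400), tss_index)
        assert (gene, dist) == ("geneA", 0.0)

    def test_distance_from_peak_edge(self, tss_index):
        gene, dist = nearest_tss(iv(12_000, 12_400), tss_index)
        assert (gene, dist) == ("geneA", 2000.0)

    def test_containment_beats_proximity(self):
        index = TSSIndex(
            [
                TSSRecord("near", "chr1", 10_000, "+"),
                TSSRecord("inside", "chr1", 11_150, "+"),
            ]
        )
        assert nearest_tss(iv(11_000, 11_200), index) == ("inside", 0.0)

    def test_tie_breaks_lower_position_then_gene_id(self):
        index = TSSIndex(
            [
                TSSRecord("right", "chr1", 1_300, "+"),
                TSSRecord("left", "chr1", 700, "+"),
            ]
        )
        # peak [1000,1100): left dist 300, right dist 201 -> right wins
        assert nearest_tss(iv(1000, 1100), index) == ("right", 201.0)
        # peak [1000,1001): both TSS exactly 300 bp away -> lower position wins
        assert nearest_tss(iv(1000, 1001), index) == ("left", 300.0)
        index2 = TSSIndex(
            [
                TSSRecord("zzz", "chr1", 500, "+"),
                TSSRecord("aaa", "chr1", 500, "+"),
            ]
        )
        assert nearest_tss(iv(600, 700), index2) == ("aaa", 100.0)

    def test_missing_chromosome_gives_infinity(self, tss_index):
        gene, dist = nearest_tss(iv(0, 100, chrom="chrUn"), tss_index)
        assert gene is None and math.isinf(dist)


class TestClassifyPeaks:
    def test_examples(self, tss_index):
        peaks = PeakSet(
            "x",
            [iv(9_500, 9_700), iv(12_000, 12_400), iv(11_000, 11_200)],
        )
        cls = {(c.peak.start): c for c in classify_peaks(peaks, tss_index, 1000)}
        assert cls[9_500].klass == "tss_proximal"
        assert cls[9_500].distance_to_tss == 301.0
        assert cls[12_000].klass == "distal"
        assert cls[12_000].distance_to_tss == 2000.0
        # inclusive boundary: distance exactly 1000
        assert cls[11_000].klass == "tss_proximal"
        assert cls[11_000].distance_to_tss == 1000.0

    def test_partition_exhaustive_and_monotone_in_threshold(self, tss_index):
        rng = np.random.default_rng(0)
        peaks = random_peakset(rng, "p", 300, chroms=("chr1", "chr2", "chrUn"))
        prev_proximal = set()
        for threshold in (0, 100, 1000, 10_000, 100_000):
            cls = classify_peaks(peaks, tss_index, threshold)
            assert len(cls) == len(peaks)
            assert all(c.klass in ("tss_proximal", "distal") for c in cls)
            proximal = {i for i, c in enumerate(cls) if c.klass == "tss_proximal"}
            assert prev_proximal <= proximal  # never demoted as threshold grows
            prev_proximal = proximal

    def test_unannotated_chromosome_classified_distal(self, tss_index):
        cls = classify_peaks(PeakSet("x", [iv(0, 100, chrom="chrUn")]), tss_index)
        assert cls[0].klass == "distal"
        assert math.isinf(cls[0].distance_to_tss)
        assert cls[0].nearest_gene is None


class TestCompareConditions:
    def test_partition_and_shared_peak(self, tss_index):
        a = PeakSet("a", [iv(0, 100), iv(5_000, 5_200), iv(30_000, 30_100)])
        b = PeakSet("b", [iv(5_150, 5_400)])
        res = compare_conditions(a, b, tss_index)
        assert res.shared_a == [1]
        assert res.specific_a == [0, 2]
        assert len(res.shared_a) + len(res.specific_a) == len(a)

    def test_identity(self, tss_index):
        a = PeakSet("a", [iv(0, 100), iv(9_800, 10_300), iv(49_000, 51_000)])
        res = compare_conditions(a, a, tss_index)
        assert res.specific_a == [] and res.specific_b == []
        assert res.specific_genes_a == set() and res.specific_genes_b == set()
        assert res.shared_genes == {"geneA", "geneB"}

    def test_directions_induce_same_pair_set(self, tss_index):
        rng = np.random.default_rng(3)
        a = random_peakset(rng, "a", 150, chroms=("chr1",))
        b = random_peakset(rng, "b", 150, chroms=("chr1",))
        ab = compare_conditions(a, b, tss_index)
        ba = compare_conditions(b, a, tss_index)
        assert ab.shared_a == ba.shared_b
        assert ab.shared_b == ba.shared_a
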
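"""Interval algebra: coverage, distances, merging, controls, GC."""
import math

import numpy as np
import pytest
from scipy.stats import chisquare

from teacr.core import Acr, GenomicInterval, TeFeature
from teacr.intervals import (
    IntervalIndex,
    coverage_fraction,
    distance_bin,
    gc_content,
    is_te_derived,
    merge_intervals,
    nearest_distance,
    random_matched_regions,
    summit_covered,
    summit_te,
    te_class_rollup,
)


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


class TestCoverageFraction:
    @pytest.mark.parametrize(
        "subjects,expected",
        [
            ([(100, 200)], 1.0),                 # identical span
            ([(100, 150), (140, 180)], 0.8),     # union [100,180) = 80/100
            ([(300, 400)], 0.0),                 # disjoint
            ([], 0.0),
        ],
    )
    def test_worked_examples(self, subjects, expected):
        q = iv(100, 200)
        assert coverage_fraction(q, [iv(s, e) for s, e in subjects]) == pytest.approx(expected)

    def test_matches_per_bp_bitmap_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            qs = int(rng.integers(0, 5000))
            q = iv(qs, qs + int(rng.integers(1, 2000)))
            subs = []
            for _ in range(rng.integers(0, 8)):
                s = int(rng.integers(0, 9000))
                subs.append(iv(s, s + int(rng.integers(1, 1500))))
            bitmap = np.zeros(10_000, dtype=bool)
            for s in subs:
                bitmap[s.start : s.end] = True
            expected = bitmap[q.start : q.end].sum() / q.length
            assert coverage_fraction(q, subs) == pytest.approx(expected)


class TestTeDerived:
    def make(self, cov, length=100):
        acr = Acr(iv(0, length), "a")
        te = TeFeature(iv(0, max(1, int(cov * length))), "hAT")
        return acr, [te]

    def test_exactly_half_is_not_derived(self):
        acr, tes = self.make(0.5)
        assert not is_te_derived(acr, tes)

    def test_just_over_half_is_derived(self):
        acr, tes = self.make(0.51)
        assert is_te_derived(acr, tes)

    def test_no_overlap(self):
        acr = Acr(iv(0, 100), "a")
        assert not is_te_derived(acr, [TeFeature(iv(500, 600), "hAT")])


class TestSummit:
    def test_summit_inside_boundaries(self):
        te = [TeFeature(iv(100, 200), "hAT")]
        assert summit_covered(Acr(iv(140, 180), "a", summit_offset=10), te)  # 150
        # half-open: position 200 is outside, 100 is inside
        assert not summit_covered(Acr(iv(150, 250), "a", summit_offset=50), te)
        assert summit_covered(Acr(iv(50, 150), "a", summit_offset=50), te)

    def test_nested_tes_attribute_to_innermost(self):
        outer = TeFeature(iv(0, 1000), "Gypsy")
        inner = TeFeature(iv(400, 500), "SINE")
        acr = Acr(iv(420, 480), "a", summit_offset=30)
        assert summit_te(acr, [outer, inner]).superfamily == "SINE"

    def test_class_rollup_tie_goes_to_dna(self):
        acr = Acr(iv(0, 100), "a")
        tes = [TeFeature(iv(0, 40), "hAT"), TeFeature(iv(60, 100), "Gypsy")]
        assert te_class_rollup(acr, tes) == "DNA"
        assert te_class_rollup(acr, [tes[1]]) == "retrotransposon"


class TestNearestDistance:
    @pytest.mark.parametrize(
        "subject,expected,bin_label",
        [
            ((150, 300), 0, "0"),
            ((370, 400), 170, "1-170"),
            ((371, 400), 171, "171-500"),
            ((701, 800), 501, "501-1000"),
            ((1300, 1400), 1100, ">1000"),
        ],
    )
    def test_boundaries(self, subject, expected, bin_label):
        d = nearest_distance(iv(100, 200), [iv(*subject)])
        assert d == expected
        assert distance_bin(d) == bin_label

    def test_empty_chromosome_is_infinite(self):
        d = nearest_distance(iv(100, 200), [GenomicInterval("chr2", 0, 10)])
        assert math.isinf(d)
        assert distance_bin(d) == ">1000"

    def test_symmetric_for_singletons(self):
        a, b = iv(10, 50), iv(300, 320)
        assert nearest_distance(a, [b]) == nearest_distance(b, [a])


class TestMerge:
    def test_overlapping_merge(self):
        assert merge_intervals([iv(100, 200), iv(150, 250)]) == [iv(100, 250)]

    def test_abutting_do_not_merge(self):
        assert merge_intervals([iv(100, 200), iv(200, 300)]) == [iv(100, 200), iv(200, 300)]

    def test_identical_across_tissues_collapse(self):
        assert merge_intervals([iv(5, 50)] * 6) == [iv(5, 50)]

    def test_idempotent_and_disjoint(self):
        rng = np.random.default_rng(3)
        ivs = [
            GenomicInterval(f"chr{rng.integers(1, 3)}", s, s + int(rng.integers(1, 300)))
            for s in rng.integers(0, 5000, size=60)
        ]
        once = merge_intervals(ivs)
        assert merge_intervals(once) == once
        for a, b in zip(once, once[1:]):
            assert a.chrom != b.chrom or a.end <= b.start


class TestRandomRegions:
    SIZES = {"chr1": 100_000}

    def test_lengths_conserved_and_seeded(self):
        templates = [iv(0, 500), iv(10, 1300)]
        sets1 = random_matched_regions(templates, self.SIZES, 3, seed=5)
        sets2 = random_matched_regions(templates, self.SIZES, 3, seed=5)
        assert sets1 == sets2
        for regions in sets1:
            assert [r.length for r in regions] == [500, 1290]

    def test_uniform_start_distribution(self):
        templates = [iv(0, 10)] * 10_000
        (regions,) = random_matched_regions(templates, self.SIZES, 1, seed=1)
        starts = np.array([r.start for r in regions])
        counts, _ = np.histogram(starts, bins=20, range=(0, 100_000 - 10))
        assert chisquare(counts).pvalue > 0.01


class TestGcContent:
    @pytest.mark.parametrize(
        "seq,expected", [("GGCC", 1.0), ("ATGC", 0.5), ("ANGC", 2 / 3)]
    )
    def test_values(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_all_n_is_nan(self):
        assert math.isnan(gc_content("NNNN"))


class TestIntervalIndex:
    def test_matches_brute_force(self):
        rng = np.random.default_rng(9)
        subjects = [
            iv(int(s), int(s) + int(rng.integers(1, 400)))
            for s in rng.integers(0, 20_000, size=100)
        ]
        index = IntervalIndex(subjects)
        for _ in range(100):
            s = int(rng.integers(0, 20_000))
            q = iv(s, s + int(rng.integers(1, 500)))
            assert sorted(index.overlapping(q), key=lambda x: (x.start, x.end)) == sorted(
                [u for u in subjects if q.overlaps(u)], key=lambda x: (x.start, x.end)
            )
            assert index.nearest_gap(q) == nearest_distance(q, subjects)
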
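"""Interval engine: construction, merge/intersect semantics, oracle parity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from darkcov.intervals import (
    GenomicInterval,
    IntervalSet,
    count_source_overlaps,
    intersect,
    intersect_length,
    normalize,
)

from conftest import per_base_cover, random_intervals


def ivs(*spans, chrom="chr1"):
    return [GenomicInterval(chrom, s, e) for s, e in spans]


class TestGenomicInterval:
    @pytest.mark.parametrize(
        "chrom,start,end",
        [("", 0, 10), ("chr1", -1, 10), ("chr1", 10, 10), ("chr1", 20, 10)],
    )
    def test_invalid_rejected(self, chrom, start, end):
        with pytest.raises(ValueError):
            GenomicInterval(chrom, start, end)

    def test_half_open_overlap(self):
        a = GenomicInterval("chr1", 0, 10)
        assert not a.overlaps(GenomicInterval("chr1", 10, 20))
        assert a.overlaps(GenomicInterval("chr1", 9, 20))
        assert not a.overlaps(GenomicInterval("chr2", 0, 10))


class TestNormalize:
    def test_overlapping_merge(self):
        s = normalize(ivs((0, 10), (5, 15)))
        assert s.to_intervals() == ivs((0, 15))
        assert s.total_length == 15

    def test_touching_merge(self):
        s = normalize(ivs((0, 10), (10, 20)))
        assert s.to_intervals() == ivs((0, 20))
        assert s.total_length == 20

    def test_empty(self):
        s = normalize([])
        assert s.total_length == 0 and not s

    def test_total_length_matches_per_base_oracle(self):
        rng = np.random.default_rng(42)
        intervals = random_intervals(rng, 1000, ["chrT"], 10_000)
        cover = per_base_cover(intervals, {"chrT": 10_000})
        assert normalize(intervals).total_length == int(cover["chrT"].sum())


class TestIntersect:
    def test_simple(self):
        r = intersect(normalize(ivs((0, 10))), normalize(ivs((5, 15))))
        assert r.to_intervals() == ivs((5, 10))
        assert r.total_length == 5

    def test_disjoint_chromosomes(self):
        a = normalize(ivs((0, 10), chrom="chr1"))
        b = normalize(ivs((0, 10), chrom="chr2"))
        assert intersect(a, b).total_length == 0
        assert intersect_length(a, b) == 0

    def test_identities(self):
        rng = np.random.default_rng(0)
        a = normalize(random_intervals(rng, 50, ["chr1", "chr2"], 5000))
        empty = normalize([])
        assert intersect(a, a).to_intervals() == a.to_intervals()
        assert intersect(a, empty).total_length == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_per_base_oracle(self, seed):
        rng = np.random.default_rng(seed)
        chroms, L = ["chrA", "chrB"], 8000
        a_raw = random_intervals(rng, 80, chroms, L)
        b_raw = random_intervals(rng, 80, chroms, L)
        a, b = normalize(a_raw), normalize(b_raw)
        ca = per_base_cover(a_raw, {c: L for c in chroms})
        cb = per_base_cover(b_raw, {c: L for c in chroms})
        expected = int(sum((ca[c] & cb[c]).sum() for c in chroms))
        assert intersect_length(a, b) == expected
        assert intersect(a, b).total_length == expected
        # commutativity
        assert intersect_length(b, a) == expected

    def test_monotone_in_b(self):
        rng = np.random.default_rng(3)
        a = normalize(random_intervals(rng, 40, ["chr1"], 5000))
        b_raw = random_intervals(rng, 40, ["chr1"], 5000)
        lengths = []
        for i in range(1, len(b_raw) + 1):
            lengths.append(intersect_length(a, normalize(b_raw[:i])))
        assert lengths == sorted(lengths)
        assert lengths[-1] <= min(a.total_length, normalize(b_raw).total_length)


class TestCountSourceOverlaps:
    def test_abutting_records_count_separately(self):
        # two book-ended dark records both overlapping one locus
        source = ivs((100, 200), (200, 300))
        assert count_source_overlaps(source, GenomicInterval("chr1", 150, 250)) == 2

    def test_half_open_boundary(self):
        source = ivs((0, 100))
        assert count_source_overlaps(source, GenomicInterval("chr1", 100, 200)) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        source = random_intervals(rng, 60, ["chr1", "chr2"], 4000)
        query = random_intervals(rng, 1, ["chr1"], 4000)[0]
        expected = sum(
            1
            for s in source
            if s.chrom == query.chrom and s.start < query.end and query.start < s.end
        )
        assert count_source_overlaps(source, query) == expected


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    spans=st.lists(
        st.tuples(st.integers(0, 480), st.integers(1, 60)), min_size=0, max_size=30
    )
)
def test_normalize_invariants(spans):
    """Merged sets are sorted, disjoint with >= 1 bp gaps, length-consistent."""
    s = normalize([GenomicInterval("chr1", a, a + l) for a, l in spans])
    arr = s.arrays("chr1")
    assert (arr[:, 1] > arr[:, 0]).all()
    if arr.shape[0] > 1:
        assert (arr[1:, 0] > arr[:-1, 1]).all()  # strict gap: merged form
    assert s.total_length == int((arr[:, 1] - arr[:, 0]).sum())
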
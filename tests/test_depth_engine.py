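import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from covdepth.alignment_reader import ReadAlignment
from covdepth.depth_engine import DepthBlocks, RegionStats, accumulate_read, gene_stats, region_stats
from covdepth.errors import ValidationError
from covdepth.target_intervals import GeneModel, TargetRegion


def read(pos, cigar_ops, chrom="chr1"):
    return ReadAlignment(chrom, pos, 0, 60, tuple(cigar_ops))


def naive_depth(reads, chrom_length):
    """Per-test oracle: full array, plain CIGAR walk."""
    d = np.zeros(chrom_length, dtype=np.int64)
    for r in reads:
        cur = r.pos
        for op, n in r.cigar:
            if op in "M=X":
                for j in range(cur, min(cur + n, chrom_length)):
                    d[j] += 1
                cur += n
            elif op in "DN":
                cur += n
    return d


class TestAccumulateRead:
    def test_single_10m(self):
        d = DepthBlocks("chr1", 100)
        accumulate_read(d, read(0, [("M", 10)]))
        arr = d.to_array()
        assert arr[:10].tolist() == [1] * 10 and arr[10:].sum() == 0

    def test_insertion_consumes_no_reference(self):
        d = DepthBlocks("chr1", 100)
        accumulate_read(d, read(0, [("M", 5), ("I", 2), ("M", 5)]))
        arr = d.to_array()
        assert arr[:10].tolist() == [1] * 10 and arr[10:].sum() == 0

    def test_deletion_advances_without_depth(self):
        d = DepthBlocks("chr1", 100)
        accumulate_read(d, read(0, [("M", 3), ("D", 2), ("M", 3)]))
        assert d.to_array()[:10].tolist() == [1, 1, 1, 0, 0, 1, 1, 1, 0, 0]

    def test_block_boundary_split(self):
        # two-block toy, block_size=8, read spans the boundary
        d = DepthBlocks("chr1", 20, block_size=8)
        r = read(5, [("M", 12)])
        accumulate_read(d, r)
        assert np.array_equal(d.to_array(), naive_depth([r], 20))
        assert set(d.blocks) == {0, 1, 2}

    def test_softclip_hardclip_pad_ignored(self):
        d = DepthBlocks("chr1", 50)
        r = read(10, [("S", 5), ("M", 4), ("P", 1), ("H", 2)])
        accumulate_read(d, r)
        assert np.array_equal(d.to_array(), naive_depth([r], 50))

    def test_splice_gap(self):
        d = DepthBlocks("chr1", 200)
        r = read(0, [("M", 10), ("N", 50), ("M", 10)])
        accumulate_read(d, r)
        assert np.array_equal(d.to_array(), naive_depth([r], 200))

    def test_overflow_past_chrom_end_clipped(self, caplog):
        d = DepthBlocks("chr1", 10)
        with caplog.at_level("WARNING", logger="covdepth.depth_engine"):
            accumulate_read(d, read(7, [("M", 10)]))
        assert d.to_array().tolist() == [0] * 7 + [1, 1, 1]
        assert any("past chromosome end" in m for m in caplog.messages)

    def test_eq_and_x_ops_add_depth(self):
        d = DepthBlocks("chr1", 20)
        accumulate_read(d, read(0, [("=", 3), ("X", 2)]))
        assert d.to_array()[:6].tolist() == [1, 1, 1, 1, 1, 0]


class TestRegionStats:
    def test_arithmetic(self):
        d = DepthBlocks("chr1", 5)
        accumulate_read(d, read(2, [("M", 1)]))
        accumulate_read(d, read(3, [("M", 1)]))
        accumulate_read(d, read(3, [("M", 1)]))
        s = region_stats(d, TargetRegion("chr1", 0, 5))
        assert (s.covered_site, s.total_depth) == (2, 3)
        assert s.coverage_pct == pytest.approx(40.0)
        assert s.mean_depth == pytest.approx(0.6)

    def test_all_zero(self):
        d = DepthBlocks("chr1", 100)
        s = region_stats(d, TargetRegion("chr1", 0, 100))
        assert (s.covered_site, s.total_depth, s.coverage_pct, s.mean_depth) == (0, 0, 0.0, 0.0)

    def test_read_counts_where_bases_fall(self):
        # read starts outside the region but overlaps it
        d = DepthBlocks("chr1", 100)
        accumulate_read(d, read(5, [("M", 10)]))
        s = region_stats(d, TargetRegion("chr1", 10, 20))
        assert (s.covered_site, s.total_depth) == (5, 5)

    def test_out_of_bounds_fatal(self):
        d = DepthBlocks("chr1", 100)
        with pytest.raises(ValidationError):
            region_stats(d, TargetRegion("chr1", 50, 101))

    def test_wrong_chrom_fatal(self):
        d = DepthBlocks("chr1", 100)
        with pytest.raises(ValidationError):
            region_stats(d, TargetRegion("chr2", 0, 10))


class TestGeneStats:
    def test_merged_parts_uniform_depth(self):
        d = DepthBlocks("chr1", 100)
        for _ in range(2):
            accumulate_read(d, read(0, [("M", 40)]))
        g = GeneModel("g", "chr1", (TargetRegion("chr1", 0, 10, "g"),
                                    TargetRegion("chr1", 20, 30, "g")))
        s = gene_stats(d, g)
        assert (s.length, s.covered_site, s.total_depth) == (20, 20, 40)
        assert s.coverage_pct == pytest.approx(100.0)
        assert s.mean_depth == pytest.approx(2.0)

    def test_single_part_equals_region_stats(self):
        d = DepthBlocks("chr1", 100)
        accumulate_read(d, read(3, [("M", 20)]))
        part = TargetRegion("chr1", 5, 15, "g")
        g = GeneModel("g", "chr1", (part,))
        assert gene_stats(d, g) == region_stats(d, part)

    def test_zero_depth_gene(self):
        d = DepthBlocks("chr1", 100)
        g = GeneModel("g", "chr1", (TargetRegion("chr1", 0, 10, "g"),))
        s = gene_stats(d, g)
        assert (s.covered_site, s.total_depth) == (0, 0)


reads_st = st.lists(
    st.tuples(
        st.integers(0, 95),
        st.lists(
            st.tuples(st.sampled_from("MIDNSX="), st.integers(1, 10)),
            min_size=1, max_size=4,
        ),
    ),
    max_size=25,
)


class TestProperties:
    @given(reads_st, st.sampled_from([7, 64, 1 << 20]))
    @settings(max_examples=60, deadline=None)
    def test_blocked_equals_naive_any_block_size(self, specs, bs):
        rs = [read(pos, ops) for pos, ops in specs]
        d = DepthBlocks("chr1", 100, block_size=bs)
        for r in rs:
            accumulate_read(d, r)
        assert np.array_equal(d.to_array(), naive_depth(rs, 100))

    @given(reads_st)
    @settings(max_examples=40, deadline=None)
    def test_block_size_invariance(self, specs):
        rs = [read(pos, ops) for pos, ops in specs]
        outs = []
        for bs in (7, 64, 1 << 20):
            d = DepthBlocks("chr1", 100, block_size=bs)
            for r in rs:
                accumulate_read(d, r)
            outs.append(region_stats(d, TargetRegion("chr1", 0, 100)))
        assert outs[0] == outs[1] == outs[2]

    @given(reads_st, st.randoms())
    @settings(max_examples=30, deadline=None)
    def test_read_order_invariance(self, specs, rnd):
        rs = [read(pos, ops) for pos, ops in specs]
        shuffled = list(rs)
        rnd.shuffle(shuffled)
        d1, d2 = (DepthBlocks("chr1", 100, block_size=16) for _ in range(2))
        for r in rs:
            accumulate_read(d1, r)
        for r in shuffled:
            accumulate_read(d2, r)
        assert np.array_equal(d1.to_array(), d2.to_array())

    @given(reads_st, st.tuples(st.integers(0, 95), st.lists(
        st.tuples(st.sampled_from("MX="), st.integers(1, 10)), min_size=1, max_size=2)))
    @settings(max_examples=30, deadline=None)
    def test_monotonicity(self, specs, extra):
        rs = [read(pos, ops) for pos, ops in specs]
        d = DepthBlocks("chr1", 100)
        for r in rs:
            accumulate_read(d, r)
        before = region_stats(d, TargetRegion("chr1", 0, 100))
        accumulate_read(d, read(*extra))
        after = region_stats(d, TargetRegion("chr1", 0, 100))
        assert after.covered_site >= before.covered_site
        assert after.total_depth >= before.total_depth

    @given(reads_st, st.integers(1, 40))
    @settings(max_examples=40, deadline=None)
    def test_window_conservation(self, specs, w):
        rs = [read(pos, ops) for pos, ops in specs]
        d = DepthBlocks("chr1", 100, block_size=13)
        for r in rs:
            accumulate_read(d, r)
        whole = region_stats(d, TargetRegion("chr1", 0, 100))
        parts = [region_stats(d, TargetRegion("chr1", s, min(s + w, 100)))
                 for s in range(0, 100, w)]
        assert sum(p.total_depth for p in parts) == whole.total_depth
        assert sum(p.covered_site for p in parts) == whole.covered_site


def test_region_stats_invariants():
    s = RegionStats(length=10, covered_site=4, total_depth=12)
    assert s.coverage_pct == pytest.approx(100 * 4 / 10)
    assert s.mean_depth == pytest.approx(1.2)
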
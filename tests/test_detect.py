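import numpy as np
import pandas as pd
import pytest

from rtkit.coverage import CoverageTrack, region_fpkm
from rtkit.detect import (
    NRT,
    RT,
    UND,
    DetectorConfig,
    RtRatioRecord,
    build_rt_ratio_matrix,
    call_readthrough,
    classify_readin,
    consensus_rt_genes,
    filter_opposite_strand,
    rt_proportion,
    rt_ratio,
)
from conftest import make_gene

LIB, RL = 1_000_000, 100
# with this library/read length a uniform depth d gives window FPKM 10*d
DEPTH_PER_FPKM = 0.1


def track_with_tail(gene_end=5000, tail_len=2000, tail_fpkm=0.2, chrom_len=40_000,
                    body_depth=1.0, strand="+"):
    depth = np.zeros(chrom_len)
    if strand == "+":
        depth[:gene_end] = body_depth
        depth[gene_end:gene_end + tail_len] = tail_fpkm * DEPTH_PER_FPKM / 0.1 * 0.1
        depth[gene_end:gene_end + tail_len] = tail_fpkm * 0.1
    else:
        depth[gene_end:] = body_depth
        depth[gene_end - tail_len:gene_end] = tail_fpkm * 0.1
    return CoverageTrack({"chr1": depth}, LIB, RL)


class TestCallReadthrough:
    def test_four_windows_is_rt_at_min_length(self):
        track = track_with_tail(tail_len=2000, tail_fpkm=0.2)
        g = make_gene(exons=((0, 5000),))
        call = call_readthrough(track, g)
        assert call.status == RT
        assert (call.tail_start, call.tail_end) == (5000, 7000)

    def test_three_windows_is_nrt(self):
        track = track_with_tail(tail_len=1500, tail_fpkm=0.2)
        g = make_gene(exons=((0, 5000),))
        call = call_readthrough(track, g)
        assert call.status == NRT
        assert call.tail_length_bp == 1500

    def test_minus_strand_scans_leftward(self):
        track = track_with_tail(gene_end=20_000, tail_len=3000, tail_fpkm=0.5, strand="-")
        g = make_gene(strand="-", exons=((20_000, 25_000),))
        call = call_readthrough(track, g)
        assert call.status == RT
        assert (call.tail_start, call.tail_end) == (17_000, 20_000)

    def test_window_below_floor_stops_scan(self):
        track = track_with_tail(tail_len=5000, tail_fpkm=0.14)  # below 0.15 floor
        g = make_gene(exons=((0, 5000),))
        call = call_readthrough(track, g)
        assert call.status == NRT and call.tail_length_bp == 0

    def test_max_tail_cap(self):
        track = track_with_tail(tail_len=30_000, tail_fpkm=1.0)
        g = make_gene(exons=((0, 5000),))
        call = call_readthrough(track, g, DetectorConfig(max_tail_bp=10_000))
        assert call.tail_length_bp == 10_000

    def test_chromosome_edge_truncates(self):
        track = track_with_tail(gene_end=5000, tail_len=35_000, tail_fpkm=1.0)
        g = make_gene(exons=((0, 5000),))
        call = call_readthrough(track, g, DetectorConfig(max_tail_bp=100_000))
        assert call.tail_end == 40_000  # chromosome length

    def test_matches_brute_force_window_scan(self, rng):
        """Tail boundaries equal an independent per-window scan on random profiles."""
        cfg = DetectorConfig()
        for _ in range(60):
            depth = np.zeros(30_000)
            depth[:5000] = 1.0
            depth[5000:] = rng.uniform(0, 0.04, size=25_000)
            track = CoverageTrack({"chr1": depth.copy()}, LIB, RL)
            g = make_gene(exons=((0, 5000),))
            call = call_readthrough(track, g, cfg)
            # oracle: walk fixed windows, recompute FPKM independently
            pos = 5000
            while pos + cfg.window_bp <= 30_000 and (pos - 5000) < cfg.max_tail_bp:
                w = depth[pos:pos + cfg.window_bp]
                fpkm = (w.sum() / RL) / ((cfg.window_bp / 1000) * (LIB / 1e6))
                if fpkm < cfg.min_window_fpkm:
                    break
                pos += cfg.window_bp
            assert call.tail_end == pos

    def test_strand_mirror_symmetry(self, rng):
        """Reflecting the genome and flipping strand leaves the call invariant."""
        n = 20_000
        depth = np.zeros(n)
        depth[:4000] = 1.0
        depth[4000:4000 + 2700] = rng.uniform(0.1, 0.5, size=2700)
        plus_track = CoverageTrack({"chr1": depth.copy()}, LIB, RL)
        minus_track = CoverageTrack({"chr1": depth[::-1].copy()}, LIB, RL)
        g_plus = make_gene(strand="+", exons=((0, 4000),))
        g_minus = make_gene(strand="-", exons=((n - 4000, n),))
        c_plus = call_readthrough(plus_track, g_plus)
        c_minus = call_readthrough(minus_track, g_minus)
        assert c_plus.status == c_minus.status
        assert c_plus.tail_length_bp == c_minus.tail_length_bp
        assert c_minus.tail_start == n - c_plus.tail_end

    def test_monotone_in_coverage(self, rng):
        depth = np.zeros(20_000)
        depth[:4000] = 1.0
        depth[4000:9000] = rng.uniform(0, 0.04, size=5000)
        g = make_gene(exons=((0, 4000),))
        lo = call_readthrough(CoverageTrack({"chr1": depth.copy()}, LIB, RL), g)
        hi = call_readthrough(CoverageTrack({"chr1": depth * 4}, LIB, RL), g)
        assert hi.tail_length_bp >= lo.tail_length_bp

    def test_missing_chromosome_raises(self):
        track = CoverageTrack({"chr2": np.zeros(100)}, LIB, RL)
        with pytest.raises(KeyError):
            call_readthrough(track, make_gene(exons=((0, 50),)))


class TestOppositeStrandFilter:
    def _rt_call(self, tail=(5000, 8000)):
        track = track_with_tail(tail_len=tail[1] - tail[0], tail_fpkm=0.5)
        g = make_gene("host", exons=((0, 5000),))
        return g, call_readthrough(track, g)

    def test_one_bp_overlap_is_und(self):
        g, call = self._rt_call()
        antisense = make_gene("anti", strand="-", exons=((7999, 9000),))
        (out,) = filter_opposite_strand([call], [g, antisense])
        assert out.status == UND
        assert out.tail_end == 8000  # tail retained

    def test_adjacent_gene_not_flagged(self):
        g, call = self._rt_call()
        antisense = make_gene("anti", strand="-", exons=((8000, 9000),))
        (out,) = filter_opposite_strand([call], [g, antisense])
        assert out.status == RT

    def test_same_strand_overlap_untouched(self):
        g, call = self._rt_call()
        sense = make_gene("down", strand="+", exons=((7000, 9000),))
        (out,) = filter_opposite_strand([call], [g, sense])
        assert out.status == RT

    def test_matches_all_pairs_overlap_oracle(self, rng):
        for _ in range(30):
            genes, calls = [], []
            for i in range(10):
                start = int(rng.integers(0, 20_000))
                strand = "+" if rng.random() < 0.5 else "-"
                genes.append(make_gene(f"g{i}", strand=strand, exons=((start, start + 1000),)))
            for i in range(5):
                ts = int(rng.integers(0, 25_000))
                from rtkit.detect import ReadthroughCall
                calls.append(
                    ReadthroughCall(f"c{i}", "chr1", "+", ts, ts, ts + 2500, 1.0, RT)
                )
            out = filter_opposite_strand(calls, genes)
            for call, res in zip(calls, out):
                overlaps = any(
                    g.strand == "-" and g.start < call.tail_end and call.tail_start < g.end
                    for g in genes
                )
                assert (res.status == UND) == overlaps


class TestReadIn:
    def test_half_open_boundary(self):
        g, call = TestOppositeStrandFilter()._rt_call()
        downstream = make_gene("down", strand="+", exons=((8000, 9000),))
        assert classify_readin(call, [g, downstream]) is False

    def test_overlap_is_read_in(self):
        g, call = TestOppositeStrandFilter()._rt_call()
        downstream = make_gene("down", strand="+", exons=((7500, 9000),))
        assert classify_readin(call, [g, downstream]) is True

    def test_antisense_neighbor_ignored(self):
        g, call = TestOppositeStrandFilter()._rt_call()
        antisense = make_gene("anti", strand="-", exons=((7500, 9000),))
        assert classify_readin(call, [g, antisense]) is False

    def test_requires_rt_status(self):
        from rtkit.detect import ReadthroughCall
        call = ReadthroughCall("g", "chr1", "+", 100, 100, 100, 0.0, NRT)
        with pytest.raises(ValueError):
            classify_readin(call, [])


class TestRtRatio:
    @pytest.mark.parametrize("rt,gene,expected", [(5, 5, 0.5), (0, 7, 0.0), (3, 0, 1.0), (0, 0, 0.0)])
    def test_values(self, rt, gene, expected):
        assert rt_ratio(rt, gene) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            rt_ratio(-1, 2)


class TestRtRatioMatrix:
    def test_missing_tissue_is_zero(self):
        mat = build_rt_ratio_matrix(
            {"A": [RtRatioRecord("g1", 2.0, 3.0)], "B": []}
        )
        assert mat.loc["g1", "A"] == pytest.approx(0.4)
        assert mat.loc["g1", "B"] == 0.0

    def test_duplicate_gene_rejected(self):
        with pytest.raises(ValueError):
            build_rt_ratio_matrix({"A": [RtRatioRecord("g1", 1, 1), RtRatioRecord("g1", 1, 1)]})

    def test_matches_dict_oracle(self, rng):
        per_tissue = {}
        for t in "ABC":
            recs = [
                RtRatioRecord(f"g{i}", float(rng.uniform(0, 5)), float(rng.uniform(0, 5)))
                for i in rng.choice(20, size=8, replace=False)
            ]
            per_tissue[t] = recs
        mat = build_rt_ratio_matrix(per_tissue)
        lookup = {
            (r.gene_id, t): r.ratio for t, recs in per_tissue.items() for r in recs
        }
        for gid in mat.index:
            for t in mat.columns:
                assert mat.loc[gid, t] == pytest.approx(lookup.get((gid, t), 0.0))


class TestRtProportion:
    def test_single_sample(self):
        assert rt_proportion([(1.0, 3.0)]) == 0.25

    def test_all_zero_tails(self):
        assert rt_proportion([(0.0, 2.0)] * 5) == 0.0

    def test_matches_sorted_median_oracle(self, rng):
        pairs = [(float(rng.uniform(0, 2)), float(rng.uniform(0, 5))) for _ in range(11)]
        ratios = sorted(t / (t + g) if t + g > 0 else 0.0 for t, g in pairs)
        assert rt_proportion(pairs) == pytest.approx(ratios[5])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rt_proportion([])


def test_consensus_majority_rule():
    from rtkit.detect import ReadthroughCall
    def call(gid, status):
        return ReadthroughCall(gid, "chr1", "+", 0, 0, 3000, 1.0, status)
    by_sample = {
        "s1": [call("g1", RT), call("g2", RT)],
        "s2": [call("g1", RT), call("g2", NRT)],
        "s3": [call("g1", NRT), call("g2", NRT)],
    }
    assert consensus_rt_genes(by_sample, fraction=0.5) == {"g1"}
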
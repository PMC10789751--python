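import math

import numpy as np
import pytest

from rtkit.annotation import GenomeIndex
from rtkit.context import (
    build_flank_regions,
    chromosome_enrichment,
    count_genes_with_peak,
    distance_to_downstream_expressed,
    gene_density,
    spearman,
    state_fold_enrichment,
)
from rtkit.detect import ReadthroughCall
from conftest import make_gene


def _genes_on(chrom_counts, strand="+"):
    genes = []
    i = 0
    for chrom, n in chrom_counts.items():
        for _ in range(n):
            genes.append(make_gene(f"g{i}", chrom=chrom, strand=strand,
                                   exons=((i * 10, i * 10 + 5),)))
            i += 1
    return genes


def hypergeom_two_sided(g_on, g_off, b_on, b_off):
    """Exact two-sided Fisher p by enumerating the hypergeometric support."""
    n1, n2 = g_on + g_off, b_on + b_off
    k = g_on + b_on
    def pmf(x):
        return (math.comb(n1, x) * math.comb(n2, k - x)) / math.comb(n1 + n2, k)
    p_obs = pmf(g_on)
    return sum(pmf(x) for x in range(max(0, k - n2), min(n1, k) + 1)
               if pmf(x) <= p_obs * (1 + 1e-9))


class TestChromosomeEnrichment:
    def test_proportional_group_is_ns(self):
        genes = _genes_on({"chr1": 40, "chr2": 40})
        background = {g.gene_id for g in genes}
        group = {g.gene_id for g in genes[::4]}  # every 4th: proportional
        records = chromosome_enrichment(group, background, genes)
        assert all(r.direction == "ns" for r in records)

    def test_odds_ratio_and_exact_p(self):
        """2x2 table (8,2,10,80): OR = 32, p equals hypergeometric tail sum."""
        genes = _genes_on({"chr1": 18, "chr2": 82})
        ids = [g.gene_id for g in genes]
        group = set(ids[:8]) | set(ids[18:20])  # 8 on chr1, 2 on chr2
        background = set(ids)
        records = chromosome_enrichment(group, background, genes)
        r = next(x for x in records if x.chrom == "chr1")
        assert (r.n_group_on, r.n_group_off, r.n_bg_on, r.n_bg_off) == (8, 2, 10, 80)
        assert r.odds_ratio == pytest.approx(32.0)
        assert r.p == pytest.approx(hypergeom_two_sided(8, 2, 10, 80), rel=1e-6)

    def test_concentrated_group_detected(self, rng):
        genes = _genes_on({"chr1": 50, "chr2": 50, "chr3": 50})
        ids = [g.gene_id for g in genes]
        group = set(ids[:40])  # 40 of 50 on chr1
        records = chromosome_enrichment(group, set(ids), genes)
        by_chrom = {r.chrom: r for r in records}
        assert by_chrom["chr1"].direction == "enriched"
        assert by_chrom["chr2"].direction == "depleted"

    def test_random_tables_match_exact_oracle(self, rng):
        for _ in range(100):
            g_on, g_off = int(rng.integers(0, 15)), int(rng.integers(1, 15))
            b_on, b_off = int(rng.integers(0, 30)), int(rng.integers(1, 60))
            from scipy.stats import fisher_exact
            _, p = fisher_exact([[g_on, g_off], [b_on, b_off]])
            assert p == pytest.approx(hypergeom_two_sided(g_on, g_off, b_on, b_off), rel=1e-6)

    def test_group_outside_background_rejected(self):
        genes = _genes_on({"chr1": 3})
        with pytest.raises(ValueError):
            chromosome_enrichment({"gX"}, {"g0"}, genes)


class TestGeneDensity:
    def test_chromosome_density(self):
        genome = GenomeIndex({"chr1": 10_000_000})
        genes = _genes_on({"chr1": 10})
        (rec,) = gene_density(genes, genome, unit="chromosome")
        assert rec.density == pytest.approx(1e-6)

    def test_empty_chromosome_zero(self):
        genome = GenomeIndex({"chr1": 100, "chr2": 100})
        records = gene_density(_genes_on({"chr1": 2}), genome, unit="chromosome")
        assert {r.unit_id: r.n_expressed for r in records} == {"chr1": 2, "chr2": 0}

    def test_window_counts_match_brute_force_and_conserve(self, rng):
        genome = GenomeIndex({"chr1": 5_500_000})
        genes = []
        for i in range(200):
            s = int(rng.integers(0, 5_400_000))
            genes.append(make_gene(f"g{i}", exons=((s, s + 100),),
                                   strand="+" if rng.random() < 0.5 else "-"))
        records = gene_density(genes, genome, unit="window", window_bp=1_000_000)
        # conservation: window counts sum to the chromosome count
        assert sum(r.n_expressed for r in records) == 200
        # brute force assignment by 5' end
        for r in records:
            w_start = int(r.unit_id.split(":")[1])
            expected = sum(
                1 for g in genes
                if w_start <= (g.start if g.strand == "+" else g.end - 1) < w_start + r.length_bp
            )
            assert r.n_expressed == expected
        assert records[-1].length_bp == 500_000  # trailing short window


class TestDownstreamDistance:
    def test_plus_strand_gap(self):
        a = make_gene("a", exons=((0, 100),))
        b = make_gene("b", exons=((150, 300),))
        assert distance_to_downstream_expressed(a, [a, b]) == 50

    def test_antisense_only_neighbor_is_none(self):
        a = make_gene("a", exons=((0, 100),))
        b = make_gene("b", strand="-", exons=((150, 300),))
        assert distance_to_downstream_expressed(a, [a, b]) is None

    def test_minus_strand_looks_left(self):
        a = make_gene("a", strand="-", exons=((500, 600),))
        b = make_gene("b", strand="-", exons=((100, 400),))
        assert distance_to_downstream_expressed(a, [a, b]) == 100

    def test_overlapping_neighbor_ignored(self):
        a = make_gene("a", exons=((0, 100),))
        b = make_gene("b", exons=((50, 300),))
        assert distance_to_downstream_expressed(a, [a, b]) is None

    def test_matches_all_pairs_scan(self, rng):
        genes = []
        for i in range(40):
            s = int(rng.integers(0, 100_000))
            genes.append(make_gene(f"g{i}", exons=((s, s + int(rng.integers(50, 2000))),),
                                   strand="+" if rng.random() < 0.5 else "-"))
        for g in genes:
            t = g.end if g.strand == "+" else g.start
            candidates = []
            for o in genes:
                if o.gene_id == g.gene_id or o.strand != g.strand:
                    continue
                d = (o.start - t) if g.strand == "+" else (t - o.end)
                if d >= 1:
                    candidates.append(d)
            expected = min(candidates) if candidates else None
            assert distance_to_downstream_expressed(g, genes) == expected


class TestSpearman:
    def test_perfect_correlations(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert spearman(x, x)[0] == pytest.approx(1.0)
        assert spearman(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson(self, rng):
        from scipy.stats import pearsonr, rankdata
        x = rng.normal(size=50)
        y = rng.normal(size=50) + 0.4 * x
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(pearsonr(rankdata(x), rankdata(y))[0])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [1, 2])


def _call(gid, strand="+", tts=10_000, tail_len=3000, status="RT"):
    if strand == "+":
        ts, te = tts, tts + tail_len
    else:
        ts, te = tts - tail_len, tts
    if tail_len == 0:
        ts = te = tts
    return ReadthroughCall(gid, "chr1", strand, tts, ts, te, 1.0, status)


class TestFlankRegions:
    def test_short_tail_excluded_everywhere(self):
        regions = build_flank_regions([_call("g", tail_len=2400)])
        assert all("g" not in regions[c] for c in regions)

    def test_boundary_tail_included(self):
        regions = build_flank_regions([_call("g", tail_len=2500)])
        assert regions["TTSminus"]["g"] == ("chr1", 8000, 10_000)
        assert regions["TTSplus"]["g"] == ("chr1", 10_000, 12_000)
        assert regions["RTend"]["g"] == ("chr1", 10_500, 14_500)

    def test_minus_strand_mirrored(self):
        regions = build_flank_regions([_call("g", strand="-", tail_len=3000)])
        assert regions["TTSminus"]["g"] == ("chr1", 10_000, 12_000)
        assert regions["TTSplus"]["g"] == ("chr1", 8000, 10_000)
        assert regions["RTend"]["g"] == ("chr1", 5000, 9000)

    def test_nrt_gets_tts_windows_only(self):
        regions = build_flank_regions([_call("g", tail_len=0, status="NRT")])
        assert "g" in regions["TTSminus"] and "g" in regions["TTSplus"]
        assert "g" not in regions["RTend"]


class TestPeakCounts:
    def test_one_bp_touch_counts_and_multiplicity_does_not(self):
        regions = {"TTSplus": {"g": ("chr1", 100, 200)}}
        assert count_genes_with_peak(regions, [("chr1", 199, 300)]) == {"TTSplus": 1}
        assert count_genes_with_peak(regions, [("chr1", 200, 300)]) == {"TTSplus": 0}
        two = [("chr1", 110, 120), ("chr1", 150, 160)]
        assert count_genes_with_peak(regions, two) == {"TTSplus": 1}

    def test_matches_brute_force_overlap(self, rng):
        regions = {"X": {f"g{i}": ("chr1", int(s), int(s) + 500)
                         for i, s in enumerate(rng.integers(0, 50_000, 30))}}
        peaks = [("chr1", int(s), int(s) + 100) for s in rng.integers(0, 50_000, 40)]
        expected = sum(
            1 for _, (c, rs, re) in regions["X"].items()
            if any(ps < re and rs < pe for _, ps, pe in peaks)
        )
        assert count_genes_with_peak(regions, peaks)["X"] == expected


class TestStateFoldEnrichment:
    def test_region_inside_small_state(self):
        genome = GenomeIndex({"chr1": 1000})
        seg = [("chr1", 0, 100, "E1"), ("chr1", 100, 1000, "E2")]
        folds = state_fold_enrichment([("chr1", 10, 60)], seg, genome)
        assert folds["E1"] == pytest.approx(10.0)
        assert folds["E2"] == pytest.approx(0.0)

    def test_whole_genome_region_is_identity(self):
        genome = GenomeIndex({"chr1": 1000})
        seg = [("chr1", 0, 300, "A"), ("chr1", 300, 1000, "B")]
        folds = state_fold_enrichment([("chr1", 0, 1000)], seg, genome)
        assert folds == {"A": pytest.approx(1.0), "B": pytest.approx(1.0)}

    def test_overlapping_segmentation_rejected(self):
        genome = GenomeIndex({"chr1": 1000})
        with pytest.raises(ValueError, match="overlap"):
            state_fold_enrichment(
                [("chr1", 0, 10)], [("chr1", 0, 100, "A"), ("chr1", 50, 200, "B")], genome
            )

    def test_matches_per_base_oracle(self, rng):
        genome = GenomeIndex({"chr1": 5000})
        bounds = sorted(set([0, 5000] + [int(x) for x in rng.integers(1, 5000, 8)]))
        states = ["S" + str(int(rng.integers(0, 3))) for _ in range(len(bounds) - 1)]
        seg = [("chr1", a, b, s) for a, b, s in zip(bounds, bounds[1:], states)]
        regions = [("chr1", int(s), int(s) + 200) for s in rng.integers(0, 4800, 5)]
        folds = state_fold_enrichment(regions, seg, genome)
        state_of = np.empty(5000, dtype=object)
        for c, a, b, s in seg:
            state_of[a:b] = s
        in_region = np.zeros(5000, dtype=bool)
        overlap = {s: 0 for s in set(states)}
        region_bases = 0
        for _, a, b in regions:
            region_bases += b - a
            for i in range(a, b):
                overlap[state_of[i]] += 1
        for s in set(states):
            state_bases = int((state_of == s).sum())
            expected = (overlap[s] / region_bases) / (state_bases / 5000)
            assert folds[s] == pytest.approx(expected)
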
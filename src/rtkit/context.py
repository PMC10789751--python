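"""Genomic and epigenomic context of readthrough genes.

Chromosome-level Fisher enrichment of a gene group against the expressed
background, gene density per chromosome or per 1-Mb window, downstream
distance to the nearest same-strand expressed gene, TTS/tail flanking
region construction for epigenomic overlap, per-region peak counting and
chromatin-state fold enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .annotation import GeneModel, GenomeIndex, tts
from .detect import RT, ReadthroughCall
from .matching import bh_fdr


@dataclass
class ChromEnrichmentRecord:
    chrom: str
    n_group_on: int
    n_group_off: int
    n_bg_on: int
    n_bg_off: int
    odds_ratio: float
    p: float
    fdr: float
    direction: str  # enriched | depleted | ns


def chromosome_enrichment(
    group: set[str],
    background: set[str],
    genes: Sequence[GeneModel],
    fdr_threshold: float = 0.05,
    background_exclusive: bool = True,
) -> list[ChromEnrichmentRecord]:
    """Per-chromosome two-sided Fisher test of group membership, BH-corrected.

    By default the comparison set is the expressed background minus the
    group (exclusive complement); set ``background_exclusive=False`` to test
    against the full background.
    """
    if not background:
        raise ValueError("empty background")
    if not group <= background:
        raise ValueError("group must be a subset of the background")
    chrom_of = {g.gene_id: g.chrom for g in genes}
    bg = background - group if background_exclusive else background
    chroms = sorted({chrom_of[g] for g in background if g in chrom_of})
    tables = []
    for chrom in chroms:
        g_on = sum(1 for g in group if chrom_of.get(g) == chrom)
        g_off = len(group) - g_on
        b_on = sum(1 for g in bg if chrom_of.get(g) == chrom)
        b_off = len(bg) - b_on
        tables.append((chrom, g_on, g_off, b_on, b_off))
    ps, ors = [], []
    for _, g_on, g_off, b_on, b_off in tables:
        odds, p = stats.fisher_exact([[g_on, g_off], [b_on, b_off]], alternative="two-sided")
        ps.append(p)
        ors.append(odds)
    fdrs = bh_fdr(ps)
    records = []
    for (chrom, g_on, g_off, b_on, b_off), odds, p, q in zip(tables, ors, ps, fdrs):
        if q < fdr_threshold and odds > 1:
            direction = "enriched"
        elif q < fdr_threshold and odds < 1:
            direction = "depleted"
        else:
            direction = "ns"
        records.append(
            ChromEnrichmentRecord(chrom, g_on, g_off, b_on, b_off, float(odds), float(p), float(q), direction)
        )
    return records


@dataclass
class DensityRecord:
    unit_id: str
    n_expressed: int
    length_bp: int

    @property
    def density(self) -> float:
        return self.n_expressed / self.length_bp


def _five_prime(g: GeneModel) -> int:
    return g.start if g.strand == "+" else g.end - 1


def gene_density(
    expressed: Sequence[GeneModel],
    genome: GenomeIndex,
    unit: str = "chromosome",
    window_bp: int = 1_000_000,
) -> list[DensityRecord]:
    """Expressed-gene density per chromosome or per fixed-size window.

    A gene is assigned to the unit containing its 5' end; the last window of
    a chromosome may be shorter.
    """
    if unit not in ("chromosome", "window"):
        raise ValueError("unit must be 'chromosome' or 'window'")
    if unit == "chromosome":
        counts = {c: 0 for c in genome}
        for g in expressed:
            counts[g.chrom] += 1
        return [DensityRecord(c, counts[c], genome[c]) for c in sorted(genome)]
    records = []
    by_chrom: dict[str, list[int]] = {c: [] for c in genome}
    for g in expressed:
        by_chrom[g.chrom].append(_five_prime(g))
    for chrom in sorted(genome):
        length = genome[chrom]
        n_windows = (length + window_bp - 1) // window_bp
        counts = np.zeros(n_windows, dtype=int)
        for p in by_chrom[chrom]:
            counts[p // window_bp] += 1
        for w in range(n_windows):
            w_len = min(window_bp, length - w * window_bp)
            records.append(DensityRecord(f"{chrom}:{w * window_bp}", int(counts[w]), w_len))
    return records


def distance_to_downstream_expressed(
    gene: GeneModel, expressed: Iterable[GeneModel]
) -> int | None:
    """Gap to the nearest same-strand expressed gene strictly downstream.

    Overlapping and abutting neighbours are ignored; None when no such gene
    exists.
    """
    t = tts(gene)
    best: int | None = None
    for g in expressed:
        if g.gene_id == gene.gene_id or g.chrom != gene.chrom or g.strand != gene.strand:
            continue
        if gene.strand == "+":
            d = g.start - t
        else:
            d = t - g.end
        if d >= 1 and (best is None or d < best):
            best = d
    return best


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) and p-value."""
    if len(x) != len(y):
        raise ValueError("length mismatch")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


REGION_CLASSES = ("TTSminus", "TTSplus", "RTend")

RegionMap = dict[str, tuple[str, int, int]]  # gene_id -> (chrom, start, end)


def build_flank_regions(
    calls: Sequence[ReadthroughCall],
    window_bp: int = 2000,
    min_tail_bp_filter: int = 2500,
) -> dict[str, RegionMap]:
    """TTSminus / TTSplus / RT-end 2-kb windows per gene, strand-aware.

    RT genes with tails shorter than ``min_tail_bp_filter`` are excluded
    from all three classes; NRT genes contribute TTSminus and TTSplus only.
    """
    regions: dict[str, RegionMap] = {c: {} for c in REGION_CLASSES}
    for call in calls:
        if call.status == RT:
            if call.tail_length_bp < min_tail_bp_filter:
                continue
        elif call.status != "NRT":
            continue
        t = call.tts
        if call.strand == "+":
            minus = (call.chrom, max(0, t - window_bp), t)
            plus = (call.chrom, t, t + window_bp)
        else:
            minus = (call.chrom, t, t + window_bp)
            plus = (call.chrom, max(0, t - window_bp), t)
        regions["TTSminus"][call.gene_id] = minus
        regions["TTSplus"][call.gene_id] = plus
        if call.status == RT:
            end = call.tail_end if call.strand == "+" else call.tail_start
            regions["RTend"][call.gene_id] = (
                call.chrom, max(0, end - window_bp), end + window_bp,
            )
    return regions


def count_genes_with_peak(
    regions: Mapping[str, RegionMap], peaks: Sequence[tuple[str, int, int]]
) -> dict[str, int]:
    """Per region class, the number of genes with >=1 bp of peak overlap."""
    trees: dict[str, IntervalTree] = {}
    for chrom, s, e in peaks:
        trees.setdefault(chrom, IntervalTree()).addi(s, e)
    out = {}
    for cls, by_gene in regions.items():
        n = 0
        for chrom, s, e in by_gene.values():
            tree = trees.get(chrom)
            if tree is not None and tree.overlap(s, e):
                n += 1
        out[cls] = n
    return out


def state_fold_enrichment(
    regions: Sequence[tuple[str, int, int]],
    segmentation: Sequence[tuple[str, int, int, str]],
    genome: GenomeIndex,
) -> dict[str, float]:
    """Fold enrichment of each chromatin state within a region set.

    fold(state) = (region∩state / region) / (state / genome), computed on
    base counts. The segmentation must not contain overlapping records.
    """
    seg_by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    state_bases: dict[str, int] = {}
    for chrom, s, e, state in segmentation:
        seg_by_chrom.setdefault(chrom, []).append((s, e, state))
        state_bases[state] = state_bases.get(state, 0) + (e - s)
    for chrom, ivs in seg_by_chrom.items():
        ivs.sort()
        for (s1, e1, _), (s2, _, _) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping segmentation records on {chrom} at {s2}")

    genome_bases = genome.total_bp()
    region_bases = 0
    overlap: dict[str, int] = {state: 0 for state in state_bases}
    for chrom, rs, re_ in regions:
        region_bases += re_ - rs
        for s, e, state in seg_by_chrom.get(chrom, []):
            ov = min(e, re_) - max(s, rs)
            if ov > 0:
                overlap[state] += ov
    if region_bases == 0:
        raise ValueError("empty region set")
    folds = {}
    for state, bases in state_bases.items():
        expected = (region_bases / genome_bases) * (bases / genome_bases)
        observed = overlap[state] / genome_bases
        folds[state] = observed / expected if expected > 0 else 0.0
    return folds


def read_bed_intervals(path) -> list[tuple[str, int, int]]:
    """BED/narrowPeak: first three columns."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


def read_segmentation(path) -> list[tuple[str, int, int, str]]:
    """4-column BED: chrom, start, end, state label."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            parts = line.rstrip("\n").split("\t")
            out.append((parts[0], int(parts[1]), int(parts[2]), parts[3]))
    return out
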
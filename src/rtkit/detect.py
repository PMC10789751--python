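"""Readthrough (DoG) detection by rolling-window coverage scanning.

Starting at a gene's TTS, consecutive non-overlapping windows (default
500 bp) are evaluated in the downstream direction; a window passes while
its FPKM stays at or above the coverage floor (default 0.15 FPKM). The
tail is the span of passing windows; a gene is RT when the tail reaches
the minimum length (default 2000 bp), otherwise NRT. In unstranded data a
tail overlapping an opposite-strand gene is unresolvable and the call is
downgraded to UND. A tail invading a downstream same-strand expressed gene
is flagged as read-in.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import GeneModel, tts
from .coverage import CoverageTrack, region_fpkm

RT, NRT, UND = "RT", "NRT", "UND"


@dataclass
class DetectorConfig:
    window_bp: int = 500
    min_tail_bp: int = 2000
    min_window_fpkm: float = 0.15
    max_tail_bp: int = 100_000

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if self.min_tail_bp < self.window_bp:
            raise ValueError("min_tail_bp must be >= window_bp")
        if self.min_window_fpkm <= 0:
            raise ValueError("min_window_fpkm must be positive")


@dataclass
class ReadthroughCall:
    gene_id: str
    chrom: str
    strand: str
    tts: int
    tail_start: int  # == tail_end when no tail
    tail_end: int
    tail_fpkm: float
    status: str
    read_in: bool = False

    @property
    def tail_length_bp(self) -> int:
        return self.tail_end - self.tail_start

    @property
    def has_tail(self) -> bool:
        return self.tail_end > self.tail_start


def call_readthrough(
    track: CoverageTrack, gene: GeneModel, config: DetectorConfig | None = None
) -> ReadthroughCall:
    """Scan downstream of the TTS and call RT/NRT for one gene in one sample.

    Windows are consecutive and non-overlapping; scanning stops at the first
    window below the FPKM floor, at ``max_tail_bp``, or at the chromosome
    edge (the final window may be truncated there).
    """
    config = config or DetectorConfig()
    if gene.chrom not in track.depth:
        raise KeyError(f"chromosome {gene.chrom} absent from track {track.sample_id!r}")
    chrom_len = len(track.depth[gene.chrom])
    t = tts(gene)
    step = 1 if gene.strand == "+" else -1
    pos = t
    passed_bp = 0
    while passed_bp < config.max_tail_bp:
        w = min(config.window_bp, config.max_tail_bp - passed_bp)
        if step > 0:
            ws, we = pos, min(pos + w, chrom_len)
        else:
            ws, we = max(pos - w, 0), pos
        if we <= ws:
            break
        if region_fpkm(track, gene.chrom, ws, we) < config.min_window_fpkm:
            break
        passed_bp += we - ws
        pos = we if step > 0 else ws
        if we - ws < w:  # hit the chromosome edge
            break
    tail_start, tail_end = (t, pos) if step > 0 else (pos, t)
    fpkm = (
        region_fpkm(track, gene.chrom, tail_start, tail_end)
        if tail_end > tail_start
        else 0.0
    )
    status = RT if (tail_end - tail_start) >= config.min_tail_bp else NRT
    return ReadthroughCall(
        gene_id=gene.gene_id, chrom=gene.chrom, strand=gene.strand, tts=t,
        tail_start=tail_start, tail_end=tail_end, tail_fpkm=fpkm, status=status,
    )


def _strand_trees(genes: Iterable[GeneModel]) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for g in genes:
        trees.setdefault((g.chrom, g.strand), IntervalTree()).addi(g.start, g.end, g.gene_id)
    return trees


def filter_opposite_strand(
    calls: Sequence[ReadthroughCall], genes: Sequence[GeneModel]
) -> list[ReadthroughCall]:
    """Downgrade RT calls whose tail overlaps any opposite-strand gene to UND.

    The tail interval is retained for inspection; NRT calls are untouched.
    """
    trees = _strand_trees(genes)
    out = []
    for call in calls:
        if call.status == RT and call.has_tail:
            other = "-" if call.strand == "+" else "+"
            tree = trees.get((call.chrom, other))
            if tree is not None and tree.overlap(call.tail_start, call.tail_end):
                call = replace(call, status=UND)
        out.append(call)
    return out


def classify_readin(
    call: ReadthroughCall, expressed_genes: Sequence[GeneModel]
) -> bool:
    """True iff an RT tail overlaps a same-strand expressed gene downstream."""
    if call.status != RT:
        raise ValueError("read-in classification applies to RT calls only")
    for g in expressed_genes:
        if g.gene_id == call.gene_id or g.chrom != call.chrom or g.strand != call.strand:
            continue
        if g.start < call.tail_end and call.tail_start < g.end:
            return True
    return False


def rt_ratio(rt_levels: float, gene_levels: float) -> float:
    """Readthrough burden: rt / (rt + gene); 0 when both are 0."""
    if rt_levels < 0 or gene_levels < 0:
        raise ValueError("levels must be non-negative")
    denom = rt_levels + gene_levels
    return rt_levels / denom if denom > 0 else 0.0


@dataclass
class RtRatioRecord:
    gene_id: str
    rt_levels: float  # median tail FPKM across samples
    gene_levels: float  # median gene-body FPKM across samples

    @property
    def ratio(self) -> float:
        return rt_ratio(self.rt_levels, self.gene_levels)


def build_rt_ratio_matrix(
    per_tissue: Mapping[str, Sequence[RtRatioRecord]]
) -> pd.DataFrame:
    """Gene x tissue RT-ratio matrix over the union of RT genes.

    A gene absent from a tissue gets ratio 0 there.
    """
    tissues = sorted(per_tissue)
    all_genes: set[str] = set()
    cols: dict[str, dict[str, float]] = {}
    for tissue in tissues:
        col: dict[str, float] = {}
        for rec in per_tissue[tissue]:
            if rec.gene_id in col:
                raise ValueError(f"duplicate gene {rec.gene_id} in tissue {tissue}")
            col[rec.gene_id] = rec.ratio
        cols[tissue] = col
        all_genes.update(col)
    index = sorted(all_genes)
    mat = pd.DataFrame(0.0, index=index, columns=tissues)
    for tissue, col in cols.items():
        for gid, r in col.items():
            mat.at[gid, tissue] = r
    return mat


def rt_proportion(pairs: Sequence[tuple[float, float]]) -> float:
    """Median across samples of tail/(tail+gene) FPKM for one gene."""
    if not pairs:
        raise ValueError("no samples")
    return float(np.median([rt_ratio(t, g) for t, g in pairs]))


def consensus_rt_genes(
    calls_by_sample: Mapping[str, Sequence[ReadthroughCall]], fraction: float = 0.5
) -> set[str]:
    """Genes called RT in more than ``fraction`` of a tissue's samples."""
    n = len(calls_by_sample)
    counts: dict[str, int] = {}
    for calls in calls_by_sample.values():
        for c in calls:
            if c.status == RT:
                counts[c.gene_id] = counts.get(c.gene_id, 0) + 1
    return {g for g, k in counts.items() if k / n > fraction}


def calls_to_frame(calls: Sequence[ReadthroughCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "chrom": [c.chrom for c in calls],
            "strand": [c.strand for c in calls],
            "tail_start": [c.tail_start for c in calls],
            "tail_end": [c.tail_end for c in calls],
            "tail_fpkm": [c.tail_fpkm for c in calls],
            "status": [c.status for c in calls],
            "read_in": [c.read_in for c in calls],
        }
    )
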
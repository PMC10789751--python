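"""Coverage tracks, FPKM quantification and the expressed-gene filter.

Coverage is per-base read depth per chromosome. Read counts are estimated
from depth as sum(depth)/read_length, so FPKM keeps its usual meaning
without needing alignments:

    FPKM = (sum(depth)/read_length) / ((length/1000) * (library_size/1e6))

Expressed genes are those with FPKM above a threshold (strictly greater)
in at least a given fraction of the samples of one tissue.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, GenomeIndex, merged_exonic_intervals


class CoverageError(ValueError):
    pass


@dataclass
class CoverageTrack:
    """Dense per-base depth per chromosome plus normalisation constants."""

    depth: dict[str, np.ndarray]
    library_size: int
    read_length: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise CoverageError("library_size must be positive")
        if self.read_length <= 0:
            raise CoverageError("read_length must be positive")
        for chrom, arr in self.depth.items():
            if np.any(arr < 0):
                raise CoverageError(f"negative depth on {chrom}")


@dataclass
class ExpressionFilterConfig:
    """FPKM > fpkm_threshold in >= sample_fraction of a tissue's samples."""

    fpkm_threshold: float = 1.0
    sample_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.fpkm_threshold <= 0 or not 0 < self.sample_fraction <= 1:
            raise ValueError("thresholds must be positive (fraction in (0,1])")


def read_bedgraph(
    path: str | Path,
    genome: GenomeIndex,
    library_size: int,
    read_length: int,
    sample_id: str = "",
) -> CoverageTrack:
    """Load a bedGraph into a dense track; absent positions have depth 0.

    Overlapping records, out-of-bounds intervals and negative values are
    rejected.
    """
    depth = {chrom: np.zeros(length, dtype=np.float64) for chrom, length in genome.items()}
    seen: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise CoverageError(f"{path}:{i}: expected 4 bedGraph columns")
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if chrom not in depth:
                raise CoverageError(f"{path}:{i}: unknown chromosome {chrom}")
            if start < 0 or end > len(depth[chrom]) or start >= end:
                raise CoverageError(f"{path}:{i}: interval out of bounds")
            if value < 0:
                raise CoverageError(f"{path}:{i}: negative value")
            seen.setdefault(chrom, []).append((start, end))
            depth[chrom][start:end] = value
    for chrom, ivs in seen.items():
        ivs.sort()
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise CoverageError(f"overlapping bedGraph records on {chrom} at {s2}")
    return CoverageTrack(depth, library_size, read_length, sample_id)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Run-length encode a dense track; zero runs are omitted."""
    with open(path, "w") as fh:
        for chrom in sorted(track.depth):
            arr = track.depth[chrom]
            if len(arr) == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def region_fpkm(track: CoverageTrack, chrom: str, start: int, end: int) -> float:
    """FPKM of one genomic interval from summed depth."""
    if end <= start:
        raise CoverageError(f"zero-length interval [{start},{end})")
    if chrom not in track.depth:
        raise CoverageError(f"chromosome {chrom} absent from track")
    reads = float(track.depth[chrom][start:end].sum()) / track.read_length
    return reads / (((end - start) / 1000.0) * (track.library_size / 1e6))


def regions_fpkm(track: CoverageTrack, chrom: str, intervals: Sequence[tuple[int, int]]) -> float:
    """FPKM over a union of disjoint intervals (summed depth, summed length)."""
    total_len = sum(e - s for s, e in intervals)
    if total_len == 0:
        raise CoverageError("zero total length")
    total = sum(float(track.depth[chrom][s:e].sum()) for s, e in intervals)
    reads = total / track.read_length
    return reads / ((total_len / 1000.0) * (track.library_size / 1e6))


def gene_fpkm(track: CoverageTrack, gene: GeneModel) -> float:
    """Exonic FPKM: depth summed over the merged exon union."""
    return regions_fpkm(track, gene.chrom, merged_exonic_intervals(gene))


def expression_matrix(
    tracks: Sequence[CoverageTrack], genes: Sequence[GeneModel]
) -> pd.DataFrame:
    """Gene x sample FPKM table from coverage tracks."""
    data = {
        t.sample_id: [gene_fpkm(t, g) for g in genes] for t in tracks
    }
    return pd.DataFrame(data, index=[g.gene_id for g in genes])


def classify_expressed(
    matrix: pd.DataFrame, config: ExpressionFilterConfig | None = None
) -> set[str]:
    """Expressed genes within one tissue's sample set.

    A gene qualifies iff the fraction of samples with FPKM strictly above
    the threshold is at least ``sample_fraction``.
    """
    config = config or ExpressionFilterConfig()
    if matrix.shape[1] == 0:
        raise ValueError("empty sample set")
    if (matrix.values < 0).any():
        raise ValueError("negative FPKM in expression matrix")
    frac = (matrix.values > config.fpkm_threshold).mean(axis=1)
    return set(matrix.index[frac >= config.sample_fraction])


def classify_expressed_by_tissue(
    matrix: pd.DataFrame,
    tissue_of_sample: Mapping[str, str],
    config: ExpressionFilterConfig | None = None,
) -> dict[str, set[str]]:
    """Apply the expressed-gene filter per tissue."""
    out: dict[str, set[str]] = {}
    tissues = sorted(set(tissue_of_sample.values()))
    for tissue in tissues:
        cols = [s for s in matrix.columns if tissue_of_sample[s] == tissue]
        out[tissue] = classify_expressed(matrix[cols], config)
    return out
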
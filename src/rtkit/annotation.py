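"""Gene annotation models and interval derivations.

Genes are modelled at the locus level: one :class:`GeneModel` per gene id,
holding every isoform's exon chain. All internal coordinates are 0-based
half-open (BED convention); GTF input/output converts at the boundary.
The merged exonic structure, the intron table (exon complement within the
gene span, masked by exons of *any* annotated gene) and the transcription
termination site (TTS, the downstream-facing span boundary) derived here
anchor every downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pyranges as pr

Interval = tuple[int, int]

_STRANDS = ("+", "-")


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


def _merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of half-open intervals, merged and sorted. Touching intervals merge."""
    ivs = sorted(intervals)
    merged: list[Interval] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def _subtract_intervals(base: Sequence[Interval], masks: Sequence[Interval]) -> list[Interval]:
    """Set difference base \\ masks over half-open intervals (both sorted, disjoint)."""
    out: list[Interval] = []
    mi = 0
    for s, e in base:
        cur = s
        while mi < len(masks) and masks[mi][1] <= cur:
            mi += 1
        j = mi
        while j < len(masks) and masks[j][0] < e:
            ms, me = masks[j]
            if ms > cur:
                out.append((cur, ms))
            cur = max(cur, me)
            if me >= e:
                break
            j += 1
        if cur < e:
            out.append((cur, e))
    return out


@dataclass(frozen=True)
class GeneModel:
    """A gene locus with strand, span and per-isoform exon chains."""

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    start: int
    end: int
    biotype: str
    isoforms: tuple[tuple[Interval, ...], ...]

    def __post_init__(self) -> None:
        if self.strand not in _STRANDS:
            raise AnnotationError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        if not self.start < self.end:
            raise AnnotationError(f"{self.gene_id}: empty span [{self.start},{self.end})")
        for iso in self.isoforms:
            prev_end = None
            for s, e in iso:
                if not s < e:
                    raise AnnotationError(f"{self.gene_id}: empty exon [{s},{e})")
                if s < self.start or e > self.end:
                    raise AnnotationError(
                        f"{self.gene_id}: exon [{s},{e}) outside gene span "
                        f"[{self.start},{self.end})"
                    )
                if prev_end is not None and s < prev_end:
                    raise AnnotationError(f"{self.gene_id}: overlapping/unsorted exons in isoform")
                prev_end = e

    @property
    def span(self) -> Interval:
        return (self.start, self.end)


@dataclass(frozen=True)
class IntronRecord:
    """One intron of a gene, ordinal-indexed in transcription order."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    index_from_start: int
    index_from_end: int

    @property
    def length_bp(self) -> int:
        return self.end - self.start


class GenomeIndex:
    """chrom -> length mapping with positive-length validation."""

    def __init__(self, lengths: Mapping[str, int]):
        for chrom, n in lengths.items():
            if n <= 0:
                raise AnnotationError(f"chromosome {chrom} has non-positive length {n}")
        self._lengths = dict(lengths)

    def __getitem__(self, chrom: str) -> int:
        return self._lengths[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def __iter__(self):
        return iter(self._lengths)

    def items(self):
        return self._lengths.items()

    def total_bp(self) -> int:
        return sum(self._lengths.values())

    @classmethod
    def from_file(cls, path: str | Path) -> "GenomeIndex":
        lengths: dict[str, int] = {}
        for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 2:
                raise AnnotationError(f"{path}:{i}: expected two columns")
            lengths[parts[0]] = int(parts[1])
        return cls(lengths)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(f"{c}\t{n}\n" for c, n in sorted(self._lengths.items()))
        )


def _validate_gtf_lines(path: str | Path) -> None:
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise AnnotationError(f"{path}:{i}: expected 9 tab-separated fields")
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError as exc:
                raise AnnotationError(f"{path}:{i}: non-integer coordinates") from exc
            if end < start:
                raise AnnotationError(f"{path}:{i}: end < start ({end} < {start})")


def parse_gtf(path: str | Path) -> list[GeneModel]:
    """Parse an Ensembl-dialect GTF into GeneModels.

    GTF 1-based closed coordinates are converted to 0-based half-open.
    Isoforms are grouped by ``transcript_id``; the gene span comes from the
    ``gene`` feature when present, otherwise from the union of its exons.
    Output is ordered by (chrom, start, gene_id).
    """
    _validate_gtf_lines(path)
    df = pr.read_gtf(str(path)).df
    if df.empty:
        return []
    if "gene_biotype" not in df.columns:
        df["gene_biotype"] = "other"
    if "gene_name" not in df.columns:
        df["gene_name"] = df["gene_id"]

    genes: list[GeneModel] = []
    for gene_id, gdf in df.groupby("gene_id", sort=False):
        gene_rows = gdf[gdf.Feature == "gene"]
        exon_rows = gdf[gdf.Feature == "exon"]
        if len(exon_rows) == 0:
            raise AnnotationError(f"gene {gene_id}: no exon features")
        chrom = str(gdf.Chromosome.iloc[0])
        strand = str(gdf.Strand.iloc[0])
        if len(gene_rows):
            start = int(gene_rows.Start.iloc[0])
            end = int(gene_rows.End.iloc[0])
            name = str(gene_rows.gene_name.iloc[0])
            biotype = str(gene_rows.gene_biotype.iloc[0])
        else:
            start = int(exon_rows.Start.min())
            end = int(exon_rows.End.max())
            name = str(gdf.gene_name.dropna().iloc[0]) if gdf.gene_name.notna().any() else gene_id
            bios = gdf.gene_biotype.dropna()
            biotype = str(bios.iloc[0]) if len(bios) else "other"
        isoforms = []
        for _, tdf in exon_rows.groupby("transcript_id", sort=True):
            exons = tuple(
                sorted((int(s), int(e)) for s, e in zip(tdf.Start, tdf.End))
            )
            isoforms.append(exons)
        genes.append(
            GeneModel(
                gene_id=str(gene_id),
                gene_name=name,
                chrom=chrom,
                strand=strand,
                start=start,
                end=end,
                biotype=biotype if biotype and biotype != "nan" else "other",
                isoforms=tuple(isoforms),
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def write_gtf(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write GeneModels as Ensembl-dialect GTF (1-based closed)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = (
                f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}"; '
                f'gene_biotype "{g.biotype}";'
            )
            fh.write(
                f"{g.chrom}\trtkit\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for ti, iso in enumerate(g.isoforms, start=1):
                tid = f"{g.gene_id}.t{ti}"
                tattrs = attrs + f' transcript_id "{tid}";'
                fh.write(
                    f"{g.chrom}\trtkit\ttranscript\t{iso[0][0] + 1}\t{iso[-1][1]}\t.\t"
                    f"{g.strand}\t.\t{tattrs}\n"
                )
                for s, e in iso:
                    fh.write(
                        f"{g.chrom}\trtkit\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{tattrs}\n"
                    )


def write_bed12(genes: Sequence[GeneModel], path: str | Path) -> None:
    """One BED12 line per isoform; gene metadata packed into the name field."""
    with open(path, "w") as fh:
        for g in genes:
            for iso in g.isoforms:
                iso_start, iso_end = iso[0][0], iso[-1][1]
                name = f"{g.gene_id}|{g.gene_name}|{g.biotype}|{g.start}|{g.end}"
                sizes = ",".join(str(e - s) for s, e in iso)
                starts = ",".join(str(s - iso_start) for s, e in iso)
                fh.write(
                    f"{g.chrom}\t{iso_start}\t{iso_end}\t{name}\t0\t{g.strand}\t"
                    f"{iso_start}\t{iso_end}\t0\t{len(iso)}\t{sizes}\t{starts}\n"
                )


def read_bed12(path: str | Path) -> list[GeneModel]:
    by_gene: dict[str, dict] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 12:
            raise AnnotationError(f"{path}:{i}: expected 12 BED columns")
        chrom, iso_start = parts[0], int(parts[1])
        gene_id, gene_name, biotype, gstart, gend = parts[3].split("|")
        sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
        offsets = [int(x) for x in parts[11].rstrip(",").split(",")]
        exons = tuple(
            (iso_start + off, iso_start + off + sz) for off, sz in zip(offsets, sizes)
        )
        rec = by_gene.setdefault(
            gene_id,
            dict(
                gene_id=gene_id, gene_name=gene_name, chrom=chrom, strand=parts[5],
                start=int(gstart), end=int(gend), biotype=biotype, isoforms=[],
            ),
        )
        rec["isoforms"].append(exons)
    genes = [
        GeneModel(**{**rec, "isoforms": tuple(rec["isoforms"])}) for rec in by_gene.values()
    ]
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def merged_exonic_intervals(gene: GeneModel) -> list[Interval]:
    """Union of all exons over all isoforms, merged and sorted."""
    return _merge_intervals(ex for iso in gene.isoforms for ex in iso)


def tts(gene: GeneModel) -> int:
    """Transcription termination site: the downstream-facing span boundary."""
    return gene.end if gene.strand == "+" else gene.start


def build_intron_table(genes: Sequence[GeneModel]) -> list[IntronRecord]:
    """Derive introns as the exon complement within each gene span.

    A gene's candidate introns are the gaps between its merged exons; any
    sub-interval overlapping an exon of *any* annotated gene (either strand,
    e.g. a nested gene) is then removed. Surviving pieces are indexed in
    transcription order (strand-aware) from both ends.
    """
    exons_by_chrom: dict[str, list[Interval]] = {}
    for g in genes:
        exons_by_chrom.setdefault(g.chrom, []).extend(
            ex for iso in g.isoforms for ex in iso
        )
    merged_by_chrom = {c: _merge_intervals(ivs) for c, ivs in exons_by_chrom.items()}

    records: list[IntronRecord] = []
    for g in genes:
        pieces = _subtract_intervals([g.span], merged_by_chrom[g.chrom])
        pieces = [p for p in pieces if p[1] - p[0] >= 1]
        if not pieces:
            continue
        n = len(pieces)
        ordered = pieces if g.strand == "+" else pieces[::-1]
        for i, (s, e) in enumerate(ordered, start=1):
            records.append(
                IntronRecord(
                    gene_id=g.gene_id, chrom=g.chrom, strand=g.strand,
                    start=s, end=e, index_from_start=i, index_from_end=n - i + 1,
                )
            )
    return records


def write_intron_bed(introns: Sequence[IntronRecord], path: str | Path) -> None:
    """BED6 plus index_from_start / index_from_end columns."""
    with open(path, "w") as fh:
        for r in introns:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene_id}\t0\t{r.strand}\t"
                f"{r.index_from_start}\t{r.index_from_end}\n"
            )
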
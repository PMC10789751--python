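"""Synthetic genomes, annotations and coverage with planted ground truth.

Every pipeline stage is testable without external data: the generator
emits multi-gene annotations on both strands, per-sample coverage tracks
with readthrough tails of known length and window-level FPKM planted
downstream of a configurable fraction of genes, planted intron retention,
genome sequence with controllable hexamer composition and exact planted
miRNA seed-site counts, peak sets with group-dependent presence rates and
expression matrices with known detection fractions. A machine-readable
truth table accompanies every dataset.

Coverage is emitted as depth plateaus rather than simulated reads: the
detector consumes per-base depth, so read-level realism adds nothing the
tests could observe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import (
    GeneModel,
    GenomeIndex,
    IntronRecord,
    build_intron_table,
    merged_exonic_intervals,
    tts,
    write_gtf,
)
from .coverage import CoverageTrack, write_bedgraph


@dataclass
class SimulationConfig:
    """Study conditions for the default synthetic panel.

    Tail lengths follow the observed range of readthrough transcripts in
    human tissues (2-60 kb, average ~5 kb, log-normal shaped); window
    coverages sit safely above the 0.15 FPKM detection floor so planted
    status is unambiguous. Library size and read length give FPKM = 10 x
    depth for a uniform plateau, which keeps planted FPKMs exact.
    """

    rng_seed: int = 0
    n_chromosomes: int = 2
    n_genes: int = 500
    strand_minus_fraction: float = 0.5
    mean_introns: float = 4.0
    exon_length_range: tuple[int, int] = (150, 400)
    intron_length_range: tuple[int, int] = (500, 2000)
    rt_fraction: float = 0.3
    antisense_fraction: float = 0.1  # of RT genes, given an antisense gene in the tail
    tail_length_range: tuple[int, int] = (2000, 60000)
    tail_length_distribution: str = "lognormal"  # or "uniform" over the range
    tail_length_log_mean: float = np.log(5000.0)
    tail_length_log_sd: float = 0.5
    tail_fpkm_range: tuple[float, float] = (0.3, 1.0)
    retention_baseline: float = 0.05
    rt_last_intron_retention: float = 1.0  # multiplier on RT genes' last introns
    gene_fpkm_range: tuple[float, float] = (2.0, 50.0)
    expression_log_sd: float = 0.1  # per-sample lognormal jitter on exonic depth
    gc_content: float = 0.5
    n_samples: int = 3
    library_size: int = 1_000_000
    read_length: int = 100
    noise_depth: float = 0.001  # Poisson depth floor per base
    intergenic_gap_range: tuple[int, int] = (4000, 8000)
    chrom_length_bp: int | None = None  # None: sized to fit the layout

    def __post_init__(self) -> None:
        for frac in (self.strand_minus_fraction, self.rt_fraction, self.antisense_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.n_genes < 1 or self.n_chromosomes < 1 or self.n_samples < 1:
            raise ValueError("counts must be positive")


STATUS_RT, STATUS_NRT, STATUS_UND, STATUS_ANTISENSE = "RT", "NRT", "UND", "ANTISENSE"


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genes: list[GeneModel]
    genome: GenomeIndex
    truth: pd.DataFrame  # indexed by gene_id

    def planted_status(self, gene_id: str) -> str:
        return self.truth.at[gene_id, "status"]


def fpkm_to_depth(fpkm: float, library_size: int, read_length: int) -> float:
    """Uniform per-base depth producing the given FPKM over any interval."""
    return fpkm * read_length * (library_size / 1e6) / 1000.0


def _gene_structure(rng: np.random.Generator, cfg: SimulationConfig, start: int):
    p = 1.0 / (1.0 + cfg.mean_introns)
    n_introns = int(rng.geometric(p) - 1)
    exons = []
    pos = start
    for i in range(n_introns + 1):
        ex_len = int(rng.integers(*cfg.exon_length_range, endpoint=True))
        exons.append((pos, pos + ex_len))
        pos += ex_len
        if i < n_introns:
            pos += int(rng.integers(*cfg.intron_length_range, endpoint=True))
    return exons, pos  # pos == gene end


def _draw_tail_length(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    lo, hi = cfg.tail_length_range
    if cfg.tail_length_distribution == "uniform":
        return int(rng.integers(lo, hi, endpoint=True))
    length = rng.lognormal(cfg.tail_length_log_mean, cfg.tail_length_log_sd)
    return int(np.clip(length, lo, hi))


def generate_annotation(config: SimulationConfig) -> SyntheticDataset:
    """Lay out non-overlapping genes with planted readthrough ground truth.

    RT genes receive a planted tail (length, window FPKM); a configurable
    fraction of them additionally get an antisense gene placed inside the
    tail, which makes their true final classification UND (the unstranded
    caller cannot resolve them). Layout reserves each planted tail plus a
    noise margin so neighbouring coverage never bleeds across genes.
    """
    cfg = config
    rng = np.random.default_rng(cfg.rng_seed)
    n = cfg.n_genes
    is_minus = rng.random(n) < cfg.strand_minus_fraction
    is_rt = rng.random(n) < cfg.rt_fraction
    has_antisense = np.logical_and(is_rt, rng.random(n) < cfg.antisense_fraction)

    genes: list[GeneModel] = []
    rows: list[dict] = []
    cursors = {f"chr{i + 1}": 0 for i in range(cfg.n_chromosomes)}
    chrom_names = sorted(cursors)

    for gi in range(n):
        chrom = chrom_names[gi % cfg.n_chromosomes]
        cursor = cursors[chrom]
        strand = "-" if is_minus[gi] else "+"
        gene_id = f"G{gi:04d}"
        tail_len = _draw_tail_length(rng, cfg) if is_rt[gi] else 0
        tail_fpkm = float(rng.uniform(*cfg.tail_fpkm_range)) if is_rt[gi] else 0.0
        gap = int(rng.integers(*cfg.intergenic_gap_range, endpoint=True))

        # reserve upstream space for leftward tails of minus-strand genes
        pre = gap + (tail_len if strand == "-" else 0)
        g_start = cursor + pre
        exons, g_end = _gene_structure(rng, cfg, g_start)
        genes.append(
            GeneModel(
                gene_id=gene_id, gene_name=gene_id, chrom=chrom, strand=strand,
                start=g_start, end=g_end, biotype="protein_coding",
                isoforms=(tuple(exons),),
            )
        )
        status = STATUS_NRT
        anti_partner = ""
        if is_rt[gi]:
            status = STATUS_UND if has_antisense[gi] else STATUS_RT
        if strand == "+":
            tail_start, tail_end = g_end, g_end + tail_len
            cursor = tail_end + gap
        else:
            tail_start, tail_end = g_start - tail_len, g_start
            cursor = g_end + gap
        if has_antisense[gi] and tail_len >= 3000:
            a_id = f"{gene_id}a"
            a_strand = "-" if strand == "+" else "+"
            mid = (tail_start + tail_end) // 2
            a_start = max(tail_start + 200, mid - 600)
            a_end = min(tail_end - 200, a_start + 1200)
            genes.append(
                GeneModel(
                    gene_id=a_id, gene_name=a_id, chrom=chrom, strand=a_strand,
                    start=a_start, end=a_end, biotype="lncRNA",
                    isoforms=(((a_start, a_end),),),
                )
            )
            anti_partner = a_id
            rows.append(
                dict(
                    gene_id=a_id, status=STATUS_ANTISENSE, tail_length_bp=0,
                    tail_window_fpkm=0.0, base_fpkm=float(rng.uniform(*cfg.gene_fpkm_range)),
                    retention_multiplier=1.0, antisense_partner=gene_id,
                )
            )
        elif has_antisense[gi]:
            status = STATUS_RT  # tail too short to host an antisense gene
        rows.append(
            dict(
                gene_id=gene_id, status=status, tail_length_bp=tail_len,
                tail_window_fpkm=tail_fpkm, base_fpkm=float(rng.uniform(*cfg.gene_fpkm_range)),
                retention_multiplier=(
                    cfg.rt_last_intron_retention if status in (STATUS_RT, STATUS_UND) else 1.0
                ),
                antisense_partner=anti_partner,
            )
        )
        cursors[chrom] = cursor

    lengths = {}
    for chrom in chrom_names:
        needed = cursors[chrom] + 10_000
        if cfg.chrom_length_bp is not None:
            if needed > cfg.chrom_length_bp:
                raise ValueError(
                    f"{chrom}: layout needs {needed} bp but chrom_length_bp="
                    f"{cfg.chrom_length_bp}"
                )
            lengths[chrom] = cfg.chrom_length_bp
        else:
            lengths[chrom] = needed
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    truth = pd.DataFrame(rows).set_index("gene_id")
    return SyntheticDataset(cfg, genes, GenomeIndex(lengths), truth)


def generate_coverage(dataset: SyntheticDataset, n_samples: int | None = None) -> list[CoverageTrack]:
    """Per-sample depth tracks realising the planted truth.

    Exonic depth follows each gene's base FPKM with per-sample log-normal
    jitter; introns carry exonic depth x retention baseline (x the planted
    multiplier on RT genes' last introns); planted tails are flat plateaus
    at the depth matching the planted window FPKM; a Poisson noise floor
    covers the rest of the genome.
    """
    cfg = dataset.config
    n_samples = n_samples or cfg.n_samples
    rng = np.random.default_rng(cfg.rng_seed + 1)
    truth = dataset.truth
    introns_by_gene: dict[str, list[IntronRecord]] = {}
    for r in build_intron_table(dataset.genes):
        introns_by_gene.setdefault(r.gene_id, []).append(r)

    tracks = []
    for si in range(n_samples):
        depth = {
            chrom: rng.poisson(cfg.noise_depth, size=length).astype(np.float64)
            for chrom, length in dataset.genome.items()
        }
        for g in dataset.genes:
            row = truth.loc[g.gene_id]
            base_depth = fpkm_to_depth(row.base_fpkm, cfg.library_size, cfg.read_length)
            sample_depth = base_depth * rng.lognormal(0.0, cfg.expression_log_sd)
            for s, e in merged_exonic_intervals(g):
                depth[g.chrom][s:e] += sample_depth
            for intron in introns_by_gene.get(g.gene_id, []):
                mult = row.retention_multiplier if intron.index_from_end == 1 else 1.0
                depth[g.chrom][intron.start:intron.end] += (
                    sample_depth * cfg.retention_baseline * mult
                )
            if row.tail_length_bp > 0:
                t = tts(g)
                if g.strand == "+":
                    ts, te = t, t + int(row.tail_length_bp)
                else:
                    ts, te = t - int(row.tail_length_bp), t
                depth[g.chrom][ts:te] += fpkm_to_depth(
                    row.tail_window_fpkm, cfg.library_size, cfg.read_length
                )
        tracks.append(
            CoverageTrack(depth, cfg.library_size, cfg.read_length, sample_id=f"s{si + 1}")
        )
    return tracks


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class HexamerBias:
    """Scale one k-mer's occurrence count inside TTS +/- flank of given genes."""

    kmer: str
    gene_ids: set[str]
    scale: float
    flank_bp: int = 500


def _find_occurrences(seq: bytearray, pattern: bytes, start: int, end: int) -> list[int]:
    hay = bytes(seq[start:end])
    out = []
    i = hay.find(pattern)
    while i != -1:
        out.append(start + i)
        i = hay.find(pattern, i + 1)
    return out


_DNA_COMPLEMENT = bytes.maketrans(b"ACGT", b"TGCA")


def _apply_hexamer_bias(
    seq: bytearray,
    bias: HexamerBias,
    region: tuple[int, int],
    rng: np.random.Generator,
    strand: str = "+",
) -> None:
    # the k-mer is defined on the gene's sense strand: for minus-strand genes
    # its genomic footprint is the reverse complement
    pattern = bias.kmer.encode()
    if strand == "-":
        pattern = pattern.translate(_DNA_COMPLEMENT)[::-1]
    s, e = region
    occ = _find_occurrences(seq, pattern, s, e)
    # per-region integer target: regions with a single occurrence deplete fully
    # under scale 0.5, so the realized group-level depletion is at least the
    # nominal scale (deterministic, unlike stochastic thinning)
    target = int(round(len(occ) * bias.scale))
    for _ in range(200):
        occ = _find_occurrences(seq, pattern, s, e)
        if len(occ) == target:
            return
        if len(occ) > target:
            pos = occ[int(rng.integers(len(occ)))]
            off = int(rng.integers(len(pattern)))
            old = seq[pos + off]
            choices = [b for b in _BASES if b != old]
            seq[pos + off] = int(choices[int(rng.integers(len(choices)))])
        else:
            pos = int(rng.integers(s, e - len(pattern)))
            seq[pos:pos + len(pattern)] = pattern
    raise RuntimeError(f"could not reach target count for {bias.kmer}")


@dataclass
class SeedPlant:
    """Plant an exact number of 8-mer seed sites inside one genomic interval."""

    chrom: str
    start: int
    end: int
    pattern: str  # DNA 8-mer
    count: int


def _apply_seed_plant(seq: bytearray, plant: SeedPlant, rng: np.random.Generator) -> None:
    pattern = plant.pattern.encode()
    k = len(pattern)
    s, e = plant.start, plant.end
    if (e - s) < plant.count * (k + 2):
        raise ValueError("interval too short for requested seed sites")
    slots = np.linspace(s, e - k, plant.count).astype(int)
    for pos in slots:
        seq[pos:pos + k] = pattern
    for _ in range(200):
        occ = _find_occurrences(seq, pattern, s, e)
        if len(occ) == plant.count:
            return
        if len(occ) > plant.count:  # spurious collision created a site
            extra = [p for p in occ if p not in set(slots)]
            pos = extra[int(rng.integers(len(extra)))]
            off = int(rng.integers(k))
            old = seq[pos + off]
            choices = [b for b in _BASES if b != old]
            seq[pos + off] = int(choices[int(rng.integers(len(choices)))])
        else:  # overlapping slots destroyed one; re-stamp them all
            for pos in slots:
                seq[pos:pos + k] = pattern
    raise RuntimeError("could not stabilise planted seed-site count")


def generate_genome_sequence(
    dataset: SyntheticDataset,
    hexamer_biases: Sequence[HexamerBias] = (),
    seed_plants: Sequence[SeedPlant] = (),
) -> dict[str, str]:
    """I.i.d. genome sequence with optional composition edits.

    Hexamer biases rescale a k-mer's occurrence count inside TTS flanks of
    the given genes; seed plants insert an exact number of pattern copies
    into an interval (verified by rescanning, so spurious junction motifs
    cannot corrupt the truth).
    """
    cfg = dataset.config
    rng = np.random.default_rng(cfg.rng_seed + 2)
    gc = cfg.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    chroms: dict[str, bytearray] = {}
    for chrom, length in dataset.genome.items():
        draw = rng.choice(_BASES, size=length, p=probs)
        chroms[chrom] = bytearray(draw.tobytes())
    gene_by_id = {g.gene_id: g for g in dataset.genes}
    for bias in hexamer_biases:
        for gid in sorted(bias.gene_ids):
            g = gene_by_id[gid]
            t = tts(g)
            region = (
                max(0, t - bias.flank_bp),
                min(dataset.genome[g.chrom], t + bias.flank_bp),
            )
            _apply_hexamer_bias(chroms[g.chrom], bias, region, rng, strand=g.strand)
    for plant in seed_plants:
        _apply_seed_plant(chroms[plant.chrom], plant, rng)
    return {chrom: seq.decode() for chrom, seq in chroms.items()}


def generate_peaks(
    regions: Mapping[str, tuple[str, int, int]],
    group_of: Mapping[str, str],
    presence_prob: Mapping[str, float],
    rng_seed: int = 0,
    peak_length: int = 200,
) -> tuple[list[tuple[str, int, int]], dict[str, bool]]:
    """Place one peak inside each gene's region with its group's probability."""
    rng = np.random.default_rng(rng_seed)
    peaks = []
    truth: dict[str, bool] = {}
    for gene_id in sorted(regions):
        chrom, s, e = regions[gene_id]
        prob = presence_prob[group_of[gene_id]]
        hit = bool(rng.random() < prob)
        truth[gene_id] = hit
        if hit:
            length = min(peak_length, e - s)
            start = int(rng.integers(s, e - length + 1))
            peaks.append((chrom, start, start + length))
    return peaks, truth


def generate_expression_matrix(
    n_genes: int,
    n_samples: int,
    detection_fractions: Sequence[float] | None = None,
    rng_seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """FPKM matrix where each gene clears FPKM > 1 in a known sample fraction."""
    if n_samples < 4:
        raise ValueError("need at least 4 samples")
    rng = np.random.default_rng(rng_seed)
    if detection_fractions is None:
        detection_fractions = rng.random(n_genes)
    gene_ids = [f"G{i:04d}" for i in range(n_genes)]
    mat = np.empty((n_genes, n_samples))
    truth: dict[str, float] = {}
    for i, frac in enumerate(detection_fractions):
        k = int(round(frac * n_samples))
        hot = rng.choice(n_samples, size=k, replace=False)
        row = rng.uniform(0.0, 0.9, size=n_samples)
        row[hot] = rng.uniform(1.5, 30.0, size=k)
        mat[i] = row
        truth[gene_ids[i]] = k / n_samples
    df = pd.DataFrame(mat, index=gene_ids, columns=[f"s{j + 1}" for j in range(n_samples)])
    return df, truth


def write_dataset(
    dataset: SyntheticDataset,
    outdir: str | Path,
    tracks: Sequence[CoverageTrack] | None = None,
    genome_seq: Mapping[str, str] | None = None,
) -> dict[str, Path]:
    """Emit GTF, chrom.sizes, truth TSV and optional bedGraphs / FASTA."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["annotation"] = outdir / "annotation.gtf"
    write_gtf(dataset.genes, paths["annotation"])
    paths["chrom_sizes"] = outdir / "genome.chrom.sizes"
    dataset.genome.to_file(paths["chrom_sizes"])
    paths["truth"] = outdir / "truth.tsv"
    dataset.truth.to_csv(paths["truth"], sep="\t")
    if tracks is not None:
        for t in tracks:
            p = outdir / f"coverage_{t.sample_id}.bedgraph"
            write_bedgraph(t, p)
            paths[f"coverage_{t.sample_id}"] = p
    if genome_seq is not None:
        p = outdir / "genome.fa"
        with open(p, "w") as fh:
            for chrom in sorted(genome_seq):
                fh.write(f">{chrom}\n")
                seq = genome_seq[chrom]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")
        paths["genome"] = p
    return paths
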
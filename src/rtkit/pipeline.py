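"""End-to-end orchestration: configuration, stage ordering, manifests.

The pipeline runs quantification -> detection -> classification ->
requested downstream analyses on a sample sheet, writes every result as
TSV/BED under an output directory, and records a manifest with SHA-256
checksums so reruns under the same configuration and seed are verifiably
identical. Logging goes to standard error; results only to files.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import annotation as ann
from . import context as ctx
from . import coverage as cov
from . import detect as det
from . import introns as intr
from . import kmers as km
from . import sponge as sp
from .matching import MatchingConfig, bh_fdr, mann_whitney_cohen


class ConfigError(ValueError):
    pass


class DataError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Flat configuration; defaults are the published analysis parameters."""

    annotation: str = ""
    chrom_sizes: str = ""
    samples: str = ""  # TSV: sample_id, tissue, path, library_size, read_length[, age]
    genome_fasta: str = ""
    mirna_fasta: str = ""
    peaks: str = ""
    out_dir: str = "rtk_out"
    rng_seed: int = 0
    # detector
    window_bp: int = 500
    min_tail_bp: int = 2000
    min_window_fpkm: float = 0.15
    max_tail_bp: int = 100_000
    consensus_fraction: float = 0.5
    # expressed-gene filter
    fpkm_threshold: float = 1.0
    sample_fraction: float = 0.25
    # epigenomic regions
    flank_window_bp: int = 2000
    min_tail_bp_filter: int = 2500
    # hexamer volcano
    kmer_k: int = 6
    kmer_flank_bp: int = 500
    kmer_n_subsample: int = 500
    kmer_n_permutations: int = 1000
    kmer_p_threshold: float = 0.001
    kmer_score_threshold: float = 0.58
    # miRNA sponges
    sponge_threshold: int = 20
    # aging comparison
    young_max_age: int = 40
    old_min_age: int = 60

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Flat ``key = value`` text format; unknown keys are rejected."""
        known = {f.name: f.type for f in fields(cls)}
        kwargs: dict = {}
        for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{i}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in known:
                raise ConfigError(f"{path}:{i}: unknown key {key!r}")
            default = getattr(cls, key, None)
            if isinstance(default, bool):
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                kwargs[key] = int(value)
            elif isinstance(default, float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def detector(self) -> det.DetectorConfig:
        return det.DetectorConfig(
            self.window_bp, self.min_tail_bp, self.min_window_fpkm, self.max_tail_bp
        )

    def expression_filter(self) -> cov.ExpressionFilterConfig:
        return cov.ExpressionFilterConfig(self.fpkm_threshold, self.sample_fraction)

    def config_hash(self) -> str:
        # out_dir does not affect results and must not perturb output headers
        payload = json.dumps(
            {f.name: getattr(self, f.name) for f in fields(self) if f.name != "out_dir"},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _log(msg: str) -> None:
    print(f"[rtk] {msg}", file=sys.stderr)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "tissue", "path", "library_size", "read_length"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"sample sheet missing columns: {sorted(missing)}")
    return df


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# rtkit 0.1.0 config={config.config_hash()}\n")
        df.to_csv(fh, sep="\t", index=index)


def rt_proportion_table(
    calls_by_sample: Mapping[str, Sequence[det.ReadthroughCall]],
    gene_fpkm_by_sample: Mapping[str, Mapping[str, float]],
) -> pd.DataFrame:
    """Per-gene per-sample readthrough proportion tail/(tail+gene)."""
    samples = sorted(calls_by_sample)
    genes = sorted({c.gene_id for calls in calls_by_sample.values() for c in calls})
    mat = pd.DataFrame(np.nan, index=genes, columns=samples)
    for sample, calls in calls_by_sample.items():
        fpkms = gene_fpkm_by_sample[sample]
        for c in calls:
            mat.at[c.gene_id, sample] = det.rt_ratio(c.tail_fpkm, fpkms[c.gene_id])
    return mat


def compare_groups(
    proportions: pd.DataFrame,
    group_of_sample: Mapping[str, str],
    group_a: str,
    group_b: str,
    fdr_threshold: float = 0.05,
    epsilon: float = 1e-6,
) -> pd.DataFrame:
    """Per-gene Mann-Whitney of readthrough proportion between two groups.

    Direction comes from the fold change of group medians (pseudocount
    epsilon guards zero baselines); significance from BH FDR.
    """
    a_cols = [s for s in proportions.columns if group_of_sample[s] == group_a]
    b_cols = [s for s in proportions.columns if group_of_sample[s] == group_b]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise DataError("each group needs at least 2 samples")
    rows = []
    for gene, row in proportions.iterrows():
        a = row[a_cols].dropna().values
        b = row[b_cols].dropna().values
        if len(a) < 2 or len(b) < 2:
            continue
        cmp = mann_whitney_cohen(a, b)
        fc = (np.median(a) + epsilon) / (np.median(b) + epsilon)
        rows.append(dict(gene_id=gene, p=cmp.p_value, cohen_d=cmp.cohen_d, fold_change=fc))
    if not rows:
        raise DataError("no genes with enough samples in both groups")
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p"].values)
    out["significant"] = out["fdr"] < fdr_threshold
    out["direction"] = np.where(out["fold_change"] > 1, "up", "down")
    out.loc[~out["significant"], "direction"] = "ns"
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run quantify -> detect -> classify -> downstream analyses.

    Returns the manifest (also written to ``out_dir/manifest.json``); every
    stage failure raises with the stage name.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    current_stage = ""

    def stage(name):
        nonlocal current_stage
        current_stage = name
        _log(f"stage: {name}")

    try:
        stage("load-annotation")
        if not config.annotation or not Path(config.annotation).exists():
            raise ConfigError(f"annotation path missing: {config.annotation!r}")
        genes = ann.parse_gtf(config.annotation)
        genome = ann.GenomeIndex.from_file(config.chrom_sizes)
        gene_by_id = {g.gene_id: g for g in genes}

        stage("load-coverage")
        sheet = read_sample_sheet(config.samples)
        tracks: dict[str, cov.CoverageTrack] = {}
        tissue_of = {}
        for _, row in sheet.iterrows():
            tracks[row.sample_id] = cov.read_bedgraph(
                row.path, genome, int(row.library_size), int(row.read_length),
                sample_id=row.sample_id,
            )
            tissue_of[row.sample_id] = row.tissue

        stage("quantify")
        matrix = cov.expression_matrix(list(tracks.values()), genes)
        p = out_dir / "expression_matrix.tsv"
        _write_tsv(matrix, p, config, index=True)
        outputs["expression_matrix"] = p
        expressed_by_tissue = cov.classify_expressed_by_tissue(
            matrix, tissue_of, config.expression_filter()
        )

        stage("detect")
        detector = config.detector()
        calls_by_sample: dict[str, list[det.ReadthroughCall]] = {}
        for sample_id, track in tracks.items():
            expressed = expressed_by_tissue[tissue_of[sample_id]]
            calls = [
                det.call_readthrough(track, gene_by_id[g], detector)
                for g in sorted(expressed)
            ]
            calls = det.filter_opposite_strand(calls, genes)
            expressed_models = [gene_by_id[g] for g in sorted(expressed)]
            for i, c in enumerate(calls):
                if c.status == det.RT:
                    calls[i].read_in = det.classify_readin(c, expressed_models)
            calls_by_sample[sample_id] = calls
            p = out_dir / f"calls_{sample_id}.tsv"
            _write_tsv(det.calls_to_frame(calls), p, config)
            outputs[f"calls_{sample_id}"] = p

        stage("ratio")
        per_tissue_records: dict[str, list[det.RtRatioRecord]] = {}
        for tissue in sorted(set(tissue_of.values())):
            t_samples = [s for s in tracks if tissue_of[s] == tissue]
            rt_genes = det.consensus_rt_genes(
                {s: calls_by_sample[s] for s in t_samples}, config.consensus_fraction
            )
            records = []
            for gid in sorted(rt_genes):
                tail_fpkms, body_fpkms = [], []
                for s in t_samples:
                    call = next(c for c in calls_by_sample[s] if c.gene_id == gid)
                    tail_fpkms.append(call.tail_fpkm if call.status == det.RT else 0.0)
                    body_fpkms.append(float(matrix.at[gid, s]))
                records.append(
                    det.RtRatioRecord(gid, float(np.median(tail_fpkms)), float(np.median(body_fpkms)))
                )
            per_tissue_records[tissue] = records
        ratio_matrix = det.build_rt_ratio_matrix(per_tissue_records)
        p = out_dir / "rt_ratio_matrix.tsv"
        _write_tsv(ratio_matrix, p, config, index=True)
        outputs["rt_ratio_matrix"] = p

        stage("introns")
        table = ann.build_intron_table(genes)
        p = out_dir / "intron_table.bed"
        ann.write_intron_bed(table, p)
        outputs["intron_table"] = p
        labeled = intr.select_terminal_introns(table)
        rpkm_frames = [
            intr.intron_rpkm_table(track, labeled) for track in tracks.values()
        ]
        rpkm_all = pd.concat([f for f in rpkm_frames if not f.empty], ignore_index=True) \
            if any(not f.empty for f in rpkm_frames) else pd.DataFrame()
        p = out_dir / "intron_rpkm.tsv"
        _write_tsv(rpkm_all, p, config)
        outputs["intron_rpkm"] = p

        if config.genome_fasta:
            stage("kmer")
            from pyfaidx import Fasta

            genome_seq = Fasta(config.genome_fasta)
            tissue0 = sorted(set(tissue_of.values()))[0]
            t_samples = [s for s in tracks if tissue_of[s] == tissue0]
            rt_genes = det.consensus_rt_genes(
                {s: calls_by_sample[s] for s in t_samples}, config.consensus_fraction
            )
            nrt_genes = {
                g for g in expressed_by_tissue[tissue0]
                if all(
                    next(c for c in calls_by_sample[s] if c.gene_id == g).status == det.NRT
                    for s in t_samples
                )
            }
            n_sub = min(config.kmer_n_subsample, len(rt_genes), len(nrt_genes))
            if n_sub >= 2:
                rt_seqs = {
                    g: km.extract_tts_flank(gene_by_id[g], genome_seq, config.kmer_flank_bp).sequence
                    for g in sorted(rt_genes)
                }
                nrt_seqs = {
                    g: km.extract_tts_flank(gene_by_id[g], genome_seq, config.kmer_flank_bp).sequence
                    for g in sorted(nrt_genes)
                }
                rt_expr = {g: float(matrix.loc[g, t_samples].median()) for g in rt_seqs}
                nrt_expr = {g: float(matrix.loc[g, t_samples].median()) for g in nrt_seqs}
                records = km.kmer_permutation_test(
                    rt_seqs, nrt_seqs, rt_expr, nrt_expr,
                    MatchingConfig(n_sub, config.kmer_n_permutations, config.rng_seed),
                    km.VolcanoConfig(
                        config.kmer_k, config.kmer_flank_bp,
                        config.kmer_p_threshold, config.kmer_score_threshold,
                    ),
                )
                kdf = pd.DataFrame(
                    [(r.kmer, r.score, r.p_value, r.fdr, r.call) for r in records],
                    columns=["kmer", "score", "p", "fdr", "call"],
                )
                p = out_dir / "kmer_enrichment.tsv"
                _write_tsv(kdf, p, config)
                outputs["kmer_enrichment"] = p

        if config.mirna_fasta and config.genome_fasta:
            stage("mirna")
            from pyfaidx import Fasta

            genome_seq = Fasta(config.genome_fasta)
            mirnas = sp.read_mirna_fasta(config.mirna_fasta)
            tail_regions: dict[str, str] = {}
            for sample_id, calls in sorted(calls_by_sample.items()):
                for c in calls:
                    if c.status == det.RT and c.gene_id not in tail_regions:
                        seq = str(genome_seq[c.chrom][c.tail_start:c.tail_end]).upper()
                        if c.strand == "-":
                            seq = km.reverse_complement(seq)
                        tail_regions[c.gene_id] = seq
            results = sp.scan_regions(tail_regions, mirnas)
            counts = {(r.region_id, r.mirna_id): r.count for r in results}
            sponges = sp.classify_sponges(counts, config.sponge_threshold)
            sdf = pd.DataFrame(
                [(s.gene_id, s.mirna_id, s.site_count) for s in sponges],
                columns=["gene_id", "mirna_id", "site_count"],
            )
            p = out_dir / "sponge_calls.tsv"
            _write_tsv(sdf, p, config)
            outputs["sponge_calls"] = p
            rdf = pd.DataFrame(
                [(r.region_id, r.mirna_id, r.region_length_bp, r.count, r.density) for r in results],
                columns=["gene_id", "mirna_id", "region_length_bp", "count", "density"],
            )
            p = out_dir / "seed_matches.tsv"
            _write_tsv(rdf, p, config)
            outputs["seed_matches"] = p

        if "age" in sheet.columns:
            stage("compare-age")
            fpkm_by_sample = {
                s: {g: float(matrix.at[g, s]) for g in matrix.index} for s in tracks
            }
            proportions = rt_proportion_table(calls_by_sample, fpkm_by_sample)
            group_of = {}
            for _, row in sheet.iterrows():
                if row.age < config.young_max_age:
                    group_of[row.sample_id] = "young"
                elif row.age > config.old_min_age:
                    group_of[row.sample_id] = "old"
                else:
                    group_of[row.sample_id] = "mid"
            if (
                sum(1 for v in group_of.values() if v == "old") >= 2
                and sum(1 for v in group_of.values() if v == "young") >= 2
            ):
                cols = [s for s in proportions.columns if group_of[s] in ("old", "young")]
                result = compare_groups(proportions[cols], group_of, "old", "young")
                p = out_dir / "age_comparison.tsv"
                _write_tsv(result, p, config)
                outputs["age_comparison"] = p

    except (ConfigError, DataError):
        raise
    except Exception as exc:  # annotate failures with the failing stage
        raise DataError(f"stage {current_stage!r} failed: {exc}") from exc

    stage("manifest")
    manifest = {
        "config_hash": config.config_hash(),
        "rng_seed": config.rng_seed,
        "outputs": {
            name: {"path": str(path), "sha256": _sha256(path)}
            for name, path in sorted(outputs.items())
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
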
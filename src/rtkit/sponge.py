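"""miRNA seed-match scanning and sponge classification on readthrough tails.

The seed of a mature miRNA is nucleotides 2-9 (1-based); its reverse
complement, transcribed to DNA, is the exact 8-mer matched on the target's
sense strand. RT tails carrying at least 20 sites for one miRNA are called
putative sponges. Tail-vs-last-exon comparisons average site counts and
per-bp densities per gene before testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

from .matching import GroupComparison, mann_whitney_cohen

_RNA = set("ACGU")


@dataclass(frozen=True)
class MatureMirna:
    mirna_id: str
    sequence: str  # RNA alphabet; T tolerated on input and read as U

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        if set(seq) - _RNA:
            raise ValueError(f"{self.mirna_id}: invalid alphabet")
        if len(seq) < 9:
            raise ValueError(f"{self.mirna_id}: sequence shorter than 9 nt has no seed")
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class SeedPattern:
    mirna_id: str
    pattern: str  # 8-nt DNA string matched on the target sense strand


@dataclass
class SeedMatchResult:
    mirna_id: str
    region_id: str
    region_length_bp: int
    count: int

    @property
    def density(self) -> float:
        return self.count / self.region_length_bp if self.region_length_bp else 0.0


@dataclass
class SpongeCall:
    gene_id: str
    mirna_id: str
    site_count: int
    threshold: int


def read_mirna_fasta(path: str | Path) -> list[MatureMirna]:
    return [
        MatureMirna(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]


def seed_pattern(mirna: MatureMirna) -> SeedPattern:
    """Positions 2-9 of the mature sequence, reverse-complemented, as DNA."""
    seed_rna = mirna.sequence[1:9]
    dna = str(Seq(seed_rna.replace("U", "T")).reverse_complement())
    return SeedPattern(mirna.mirna_id, dna)


def scan_seed_matches(sequence: str, pattern: SeedPattern) -> int:
    """Count of (possibly overlapping) exact pattern occurrences."""
    seq = sequence.upper()
    pat = pattern.pattern
    count = 0
    i = seq.find(pat)
    while i != -1:
        count += 1
        i = seq.find(pat, i + 1)
    return count


def scan_regions(
    regions: Mapping[str, str], mirnas: Sequence[MatureMirna]
) -> list[SeedMatchResult]:
    """Seed-match counts for every (region, miRNA) combination."""
    patterns = [seed_pattern(m) for m in mirnas]
    out = []
    for region_id, seq in regions.items():
        for pat in patterns:
            out.append(
                SeedMatchResult(
                    pat.mirna_id, region_id, len(seq), scan_seed_matches(seq, pat)
                )
            )
    return out


def classify_sponges(
    tail_counts: Mapping[tuple[str, str], int], threshold: int = 20
) -> list[SpongeCall]:
    """(gene, miRNA) pairs whose tail carries at least ``threshold`` sites."""
    calls = [
        SpongeCall(gene, mirna, count, threshold)
        for (gene, mirna), count in sorted(tail_counts.items())
        if count >= threshold
    ]
    return calls


def compare_tail_vs_last_exon(
    tail_results: Sequence[SeedMatchResult],
    exon_results: Sequence[SeedMatchResult],
) -> tuple[GroupComparison, GroupComparison]:
    """Tail-vs-last-exon comparison of per-gene mean site counts and densities.

    Counts/densities are averaged per gene (region_id) across miRNAs before
    testing; every gene must be quantified in both regions.
    """
    def per_gene(results):
        counts: dict[str, list[float]] = {}
        dens: dict[str, list[float]] = {}
        for r in results:
            counts.setdefault(r.region_id, []).append(r.count)
            dens.setdefault(r.region_id, []).append(r.density)
        return (
            {g: float(np.mean(v)) for g, v in counts.items()},
            {g: float(np.mean(v)) for g, v in dens.items()},
        )

    tail_counts, tail_dens = per_gene(tail_results)
    exon_counts, exon_dens = per_gene(exon_results)
    if set(tail_counts) != set(exon_counts):
        raise ValueError("every gene needs both a tail and a last-exon quantification")
    genes = sorted(tail_counts)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    count_cmp = mann_whitney_cohen(
        [tail_counts[g] for g in genes], [exon_counts[g] for g in genes]
    )
    density_cmp = mann_whitney_cohen(
        [tail_dens[g] for g in genes], [exon_dens[g] for g in genes]
    )
    return count_cmp, density_cmp
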
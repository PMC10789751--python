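"""Hexamer enrichment around transcription termination sites.

TTS-flanking sequences (default +/-500 bp, sense-strand oriented) are
compared between RT and NRT genes: per k-mer, the enrichment score is

    score = log2((count_RT + c) / (count_NRT + c))

with counts pooled over expression-matched subsamples (pseudocount c
guards zero counts), and significance comes from a Welch t-test between
the per-permutation count distributions of the two groups, BH-corrected.
Volcano calls require both the FDR and the |score| threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter
from itertools import product
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .annotation import GeneModel, tts
from .matching import MatchingConfig, bh_fdr, expression_matched_subsamples

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class FlankSequence:
    gene_id: str
    chrom: str
    start: int
    end: int
    sequence: str  # sense-strand oriented: position 0 is 5'-most


@dataclass
class VolcanoConfig:
    k: int = 6
    flank_bp: int = 500
    p_threshold: float = 0.001
    score_threshold: float = 0.58
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.p_threshold <= 0 or self.score_threshold <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class KmerEnrichmentRecord:
    kmer: str
    score: float
    p_value: float
    fdr: float
    call: str  # enriched | depleted | ns


def extract_tts_flank(gene: GeneModel, genome: Mapping[str, str], flank_bp: int = 500) -> FlankSequence:
    """Fetch [TTS-flank, TTS+flank), reverse-complemented for minus-strand genes.

    ``genome`` is any chrom -> sequence mapping (e.g. a pyfaidx.Fasta). The
    window is truncated at chromosome edges.
    """
    if gene.chrom not in genome:
        raise KeyError(f"chromosome {gene.chrom} missing from genome")
    chrom_seq = genome[gene.chrom]
    t = tts(gene)
    start = max(0, t - flank_bp)
    end = min(len(chrom_seq), t + flank_bp)
    seq = str(chrom_seq[start:end]).upper()
    seq = "".join(c if c in "ACGT" else "N" for c in seq)
    if gene.strand == "-":
        seq = reverse_complement(seq)
    return FlankSequence(gene.gene_id, gene.chrom, start, end, seq)


def _encode(seq: str) -> np.ndarray:
    codes = np.full(len(seq), -1, dtype=np.int64)
    for base, code in _BASE_CODE.items():
        idx = np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)
        codes[idx] = code
    return codes


def kmer_count_vector(seq: str, k: int) -> np.ndarray:
    """Counts of all 4^k k-mers (lexicographic index); N-containing windows skipped."""
    n_kmers = 4**k
    counts = np.zeros(n_kmers, dtype=np.int64)
    if len(seq) < k:
        return counts
    codes = _encode(seq.upper())
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = np.all(win >= 0, axis=1)
    if not valid.any():
        return counts
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    idx = win[valid] @ weights
    np.add.at(counts, idx, 1)
    return counts


def all_kmers(k: int) -> list[str]:
    return ["".join(p) for p in product("ACGT", repeat=k)]


def count_kmers(sequences: Sequence[str], k: int) -> Counter:
    """Overlapping k-mer counts summed over sequences; absent k-mers read as 0."""
    if k < 1:
        raise ValueError("k must be >= 1")
    total = np.zeros(4**k, dtype=np.int64)
    for seq in sequences:
        total += kmer_count_vector(seq, k)
    names = all_kmers(k)
    return Counter({names[i]: int(c) for i, c in enumerate(total) if c > 0})


def kmer_score(count_rt: float, count_nrt: float, pseudocount: float = 1.0) -> float:
    """log2 ratio of group occurrence counts with a pseudocount guard."""
    if count_rt < 0 or count_nrt < 0:
        raise ValueError("counts must be non-negative")
    return float(np.log2((count_rt + pseudocount) / (count_nrt + pseudocount)))


def kmer_permutation_test(
    rt_seqs: Mapping[str, str],
    nrt_seqs: Mapping[str, str],
    rt_expr: Mapping[str, float],
    nrt_expr: Mapping[str, float],
    matching: MatchingConfig,
    config: VolcanoConfig | None = None,
) -> list[KmerEnrichmentRecord]:
    """Per-k-mer enrichment over expression-matched subsamples.

    Per permutation, group counts are the summed k-mer counts of the matched
    gene flanks. Scores come from counts pooled over all permutations;
    significance from a two-sided Welch t-test between the per-permutation
    count vectors, BH-corrected. Records are ordered by k-mer.
    """
    config = config or VolcanoConfig()
    if matching.n_permutations < 2:
        raise ValueError("need at least 2 permutations for the t-test")
    missing = (set(rt_expr) - set(rt_seqs)) | (set(nrt_expr) - set(nrt_seqs))
    if missing:
        raise KeyError(f"genes without flank sequence: {sorted(missing)[:5]}")
    subsamples = expression_matched_subsamples(rt_expr, nrt_expr, matching)

    vec_cache: dict[str, np.ndarray] = {}

    def vec(gene: str, seqs: Mapping[str, str]) -> np.ndarray:
        if gene not in vec_cache:
            vec_cache[gene] = kmer_count_vector(seqs[gene], config.k)
        return vec_cache[gene]

    n_kmers = 4**config.k
    rt_mat = np.zeros((matching.n_permutations, n_kmers), dtype=np.float64)
    nrt_mat = np.zeros_like(rt_mat)
    for i, sub in enumerate(subsamples):
        for rt_g, nrt_g, _, _ in sub.pairs:
            rt_mat[i] += vec(rt_g, rt_seqs)
            nrt_mat[i] += vec(nrt_g, nrt_seqs)

    tot_rt = rt_mat.sum(axis=0)
    tot_nrt = nrt_mat.sum(axis=0)
    scores = np.log2((tot_rt + config.pseudocount) / (tot_nrt + config.pseudocount))
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(rt_mat, nrt_mat, axis=0, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)
    fdr = bh_fdr(p)

    names = all_kmers(config.k)
    records = []
    for i, kmer in enumerate(names):
        if fdr[i] <= config.p_threshold and scores[i] >= config.score_threshold:
            call = "enriched"
        elif fdr[i] <= config.p_threshold and scores[i] <= -config.score_threshold:
            call = "depleted"
        else:
            call = "ns"
        records.append(
            KmerEnrichmentRecord(kmer, float(scores[i]), float(p[i]), float(fdr[i]), call)
        )
    return records
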
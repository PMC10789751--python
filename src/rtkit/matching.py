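"""Expression-matched subsampling and group-comparison statistics.

RT and NRT gene groups differ in size and expression; every group
comparison in the pipeline therefore runs on repeated equal-sized
subsamples in which each randomly drawn RT gene is paired with its
nearest-neighbour expression partner among the unused NRT genes
(without replacement within a subsample). Matching distance is
|log2(x+1) difference| by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class MatchingConfig:
    n_per_subsample: int
    n_permutations: int = 1000
    rng_seed: int = 0
    expression_scale: str = "log2"  # or "linear"

    def __post_init__(self) -> None:
        if self.n_per_subsample < 1 or self.n_permutations < 1:
            raise ValueError("subsample size and permutation count must be >= 1")
        if self.expression_scale not in ("log2", "linear"):
            raise ValueError("expression_scale must be 'log2' or 'linear'")


@dataclass
class MatchedSubsample:
    permutation_index: int
    pairs: list[tuple[str, str, float, float]]  # (rt_gene, nrt_gene, rt_expr, nrt_expr)

    @property
    def rt_genes(self) -> list[str]:
        return [p[0] for p in self.pairs]

    @property
    def nrt_genes(self) -> list[str]:
        return [p[1] for p in self.pairs]


def expression_matched_subsamples(
    rt: Mapping[str, float], nrt: Mapping[str, float], config: MatchingConfig
) -> list[MatchedSubsample]:
    """Seeded nearest-neighbour expression matching, repeated per permutation.

    Per permutation: draw ``n_per_subsample`` RT genes uniformly without
    replacement; greedily pair each with the unused NRT gene minimising the
    absolute expression difference (ties broken by lexicographic gene id).
    NRT partners are consumed within a subsample and reset across
    permutations.
    """
    if not rt or not nrt:
        raise ValueError("both gene pools must be non-empty")
    n = config.n_per_subsample
    if n > len(rt) or n > len(nrt):
        raise ValueError(
            f"n_per_subsample={n} exceeds pool sizes (RT={len(rt)}, NRT={len(nrt)})"
        )
    rt_ids = sorted(rt)
    nrt_ids = sorted(nrt)  # lexicographic order => argmin ties pick smallest id
    rt_raw = np.array([rt[g] for g in rt_ids], dtype=float)
    nrt_raw = np.array([nrt[g] for g in nrt_ids], dtype=float)
    if not (np.all(np.isfinite(rt_raw)) and np.all(np.isfinite(nrt_raw))):
        raise ValueError("expressions must be finite")
    if config.expression_scale == "log2":
        rt_val = np.log2(rt_raw + 1.0)
        nrt_val = np.log2(nrt_raw + 1.0)
    else:
        rt_val, nrt_val = rt_raw, nrt_raw

    rng = np.random.default_rng(config.rng_seed)
    out: list[MatchedSubsample] = []
    for p in range(config.n_permutations):
        chosen = rng.choice(len(rt_ids), size=n, replace=False)
        used = np.zeros(len(nrt_ids), dtype=bool)
        pairs: list[tuple[str, str, float, float]] = []
        for i in chosen:
            d = np.abs(nrt_val - rt_val[i])
            d[used] = np.inf
            j = int(np.argmin(d))
            used[j] = True
            pairs.append((rt_ids[i], nrt_ids[j], float(rt_raw[i]), float(nrt_raw[j])))
        out.append(MatchedSubsample(permutation_index=p, pairs=pairs))
    return out


@dataclass
class GroupComparison:
    statistic: float  # Mann-Whitney U (group a vs b)
    p_value: float
    cohen_d: float
    n_a: int
    n_b: int


def cohen_d(a: Sequence[float], b: Sequence[float]) -> float:
    """Cohen's d with pooled (n-1)-weighted standard deviation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    va = a.var(ddof=1) if na > 1 else 0.0
    vb = b.var(ddof=1) if nb > 1 else 0.0
    pooled = np.sqrt(((na - 1) * va + (nb - 1) * vb) / max(na + nb - 2, 1))
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


def mann_whitney_cohen(a: Sequence[float], b: Sequence[float]) -> GroupComparison:
    """Two-sided Mann-Whitney U plus Cohen's d.

    Exact null distribution for small tie-free samples (both n <= 20),
    otherwise the tie-corrected normal approximation. Two identical
    constant groups give p = 1, d = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return GroupComparison(len(a) * len(b) / 2.0, 1.0, 0.0, len(a), len(b))
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(len(a), len(b)) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(min(res.pvalue, 1.0))
    return GroupComparison(float(res.statistic), p, cohen_d(a, b), len(a), len(b))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def aggregate_permutations(
    per_permutation: Sequence[Mapping[str, float]]
) -> dict[str, tuple[float, float]]:
    """Mean and sample SD per group across permutation summaries."""
    if len(per_permutation) < 2:
        raise ValueError("need at least 2 permutations to aggregate")
    keys = set(per_permutation[0])
    for d in per_permutation[1:]:
        if set(d) != keys:
            raise ValueError("group keys differ across permutations")
    out = {}
    for k in sorted(keys):
        vals = np.array([d[k] for d in per_permutation], dtype=float)
        out[k] = (float(vals.mean()), float(vals.std(ddof=1)))
    return out
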
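# Methods

## Coordinate and coverage model

All internal coordinates are 0-based half-open (BED convention); GTF I/O
converts at the boundary. Coverage is per-base depth per chromosome plus two
normalisation constants (library size in uniquely mapped reads, read length in
bp). Read counts over a region are estimated as `sum(depth)/read_length`, so
FPKM retains its usual semantics without alignments:

    FPKM(region) = (sum(depth)/read_length) / ((len/1000) · (lib/1e6)).

Gene-level FPKM is exonic: depth summed over the merged exon union of all
isoforms. Intron read counts round half-up.

## Readthrough detection

The caller scans consecutive, non-overlapping 500 bp windows downstream of the
TTS (rightward for `+`, leftward for `-`). A window passes at FPKM ≥ 0.15; the
scan stops at the first failing window, at 100 kb, or at the chromosome edge
(where the final window may be truncated). The tail ends at the last passing
window — no sub-window refinement — so recovered tail length is within one
window of truth, and a gene is RT at tail ≥ 2000 bp. Defaults (500 / 2000 /
0.15) are the published detection parameters; the 100 kb cap bounds the scan
well above the longest tails observed in human tissues (~60 kb).

Design choices where the procedure was genuinely open:

- **Windows are non-overlapping with step = window size.** "Rolling window"
  admits overlapping steps; non-overlapping matches the screening-interval
  behaviour of the reference caller and makes tail length a multiple of the
  window.
- **The UND filter tests against all annotated opposite-strand genes**, not
  only expressed ones — conservative for unstranded libraries. The tail is
  retained on UND calls for inspection.
- **Scanning does not stop at a downstream same-strand expressed gene**; the
  read-in flag reports that overlap instead.
- **Per-tissue aggregation**: a gene is RT in a tissue when called RT in more
  than half of the tissue's samples (configurable fraction).
- **TTS is the downstream-facing boundary of the gene-level span** (union over
  isoforms), not of a dominant isoform.

`RTratio = rt/(rt+gene)` with 0 at 0/0; the RT-ratio matrix over tissues fills
genes absent from a tissue with 0. The per-sample *RT proportion* is the
median across samples of tail/(tail+gene) FPKM; whether the published
"proportion" is this ratio or a read-count-based variant is ambiguous — the
ratio semantics is used throughout.

## Expression-matched subsampling

Nearest-neighbour matching on |log2(x+1) difference| (expression is roughly
log-normal; linear distance over-weights high expressors), RT genes drawn
uniformly without replacement per permutation, NRT partners consumed without
replacement within a permutation and reset across permutations, ties broken by
lexicographic gene id. Fully deterministic given the seed.

Two practical constraints matter:

- **The subsample must be well below the partner pool size.** As
  n_per_subsample approaches |NRT|, matching degenerates into using the whole
  pool and cannot equalise expression; the test panels keep the subsample at
  or below half the smaller pool.
- **Permutation resampling does not erase fixed-set differences.** All
  permutations draw from the same two finite gene sets, so test statistics
  computed across permutations (e.g. the per-k-mer Welch t) are
  anticonservative with respect to the gene-sampling null: any composition
  difference between the fixed sets is "confirmed" by resampling. Downstream
  calls therefore always combine the p-value with an effect-size gate (the
  0.58 score threshold for hexamers, Cohen's d > 0.3 for retention), and the
  calibration claims below are about call rates, not raw p-values.

Mann-Whitney U is two-sided with the exact null for tie-free samples of at
most 20, the tie-corrected normal approximation otherwise; two identical
constant groups give p = 1, d = 0. Cohen's d uses the pooled (n−1)-weighted
SD. Multiple testing uses Benjamini-Hochberg throughout.

## Hexamer enrichment

Flanks are TTS±500 bp, sense-strand oriented (minus-strand genes
reverse-complemented), with non-ACGT symbols read as N and N-containing
windows skipped. Per k-mer, the score is `log2((c_RT+1)/(c_NRT+1))` with
counts pooled over all matched subsamples (a pseudocount of 1 guards the
ratio, which the bare formula leaves undefined at zero counts; pooled counts
were preferred over per-permutation means as the closer reading of "number of
occurrences between the two groups"). Significance is a two-sided Welch t-test
between the per-permutation count vectors (the unequal-variance form is the
safer default where only "Student's t" is specified), BH-corrected; a volcano
call requires FDR ≤ 0.001 and |score| ≥ 0.58 together.

## Intron retention

The intron table is the exon complement within each gene span, with any piece
overlapping an exon of *any* annotated gene (either strand) removed — nested
or overlapping loci therefore punch holes in host introns. Pieces are indexed
in transcription order from both ends; only the first two and last two
introns are quantified, and an intron may carry two position labels in genes
with fewer than four introns (a 2-intron gene's last intron is also its
second). Retention per intron per sample is
`RPKM = (reads+1)/((len/1000)·(total/1e6))`, strictly positive by the
pseudocount. RT-vs-NRT comparisons pool matched per-gene values across
permutations and flag a position at p < 0.05 and d > 0.3.

Because of the label overlap, a genuine last-intron effect propagates into the
'first' and 'second' classes through 1–2-intron genes. Position-specific
claims are therefore only identifiable on genes with at least four introns,
and the recovery panels restrict the compared pools accordingly.

## Genomic and epigenomic context

Chromosome enrichment is a per-chromosome two-sided Fisher test of group
membership against the expressed background (exclusive of the group by
default; inclusive available), BH-corrected at FDR < 0.05 with direction from
the odds ratio. Gene density assigns each gene to the chromosome or 1-Mb
window containing its 5' end (avoids double counting; the last window of a
chromosome may be shorter). Downstream distance is the gap from the TTS to the
nearest strictly-downstream same-strand expressed gene; overlapping or
abutting neighbours yield no distance. Flank regions are 2-kb windows upstream
(TTSminus) and downstream (TTSplus) of the TTS and ±2 kb around the tail end
(RTend); RT genes with tails under 2500 bp are excluded from all three classes
to limit region overlap. Peak counting is "≥1 bp overlap, once per gene per
class"; state fold enrichment is
`(region∩state / region) / (state / genome)` on base counts over a
non-overlapping segmentation.

## miRNA sponges

The seed is mature positions 2–9 (the library convention of
extract-then-reverse-complement), matched as an exact DNA 8-mer on the
target's sense strand with overlapping occurrences counted; no G:U wobble or
7-mer variants. A tail with ≥ 20 sites for one miRNA is a putative sponge
("at least 20" adopted where a figure caption says "more than"; threshold
configurable). Tail-vs-last-exon comparisons average counts and per-bp
densities per gene across miRNAs before the Mann-Whitney/Cohen's d test; the
last exon is the 3'-most exon of the merged gene model.

## Synthetic data

The generator emits what the detector and statistics consume, nothing more:

- **Layout**: non-overlapping genes on both strands across a configurable
  number of chromosomes, geometric intron counts (default mean 4), uniform
  exon (150–400 bp) and intron (500–2000 bp) lengths, intergenic gaps of
  4–8 kb plus reserved space for planted tails so coverage never bleeds
  between neighbours. Chromosome lengths are sized to the layout unless fixed.
- **Planted truth**: a configurable fraction of genes (default 0.3) get tails
  with log-normal lengths (median ~5 kb, clipped to 2–60 kb, the observed
  range in human tissues; a uniform option serves threshold-recovery panels)
  and uniform window FPKM (default 0.3–1.0, safely above the 0.15 floor). A
  fraction of RT genes receive an antisense gene inside the tail; their true
  final classification is UND.
- **Coverage**: depth plateaus, not simulated reads — the detector consumes
  per-base depth, so read-level realism adds nothing testable. Exonic depth
  follows each gene's base FPKM (uniform 2–50) with per-sample log-normal
  jitter (σ = 0.1); introns carry exonic depth × retention baseline (0.05),
  times a planted multiplier on RT genes' last introns; a Poisson noise floor
  (mean depth 0.001) covers the rest. With the default library (10^6 reads,
  100 bp), FPKM = 10 × depth, keeping planted window FPKMs exact.
- **Sequence**: i.i.d. nucleotides at configurable GC. Hexamer biases rescale
  a k-mer's occurrences inside TTS flanks of chosen genes *on the sense
  strand* (reverse complement in genome coordinates for minus-strand genes);
  per-region integer targets mean single-occurrence regions deplete fully, so
  realized group-level depletion is at least the nominal scale. Seed-site
  planting stamps the pattern and rescans until the interval contains exactly
  the requested count, so junction artefacts cannot corrupt the truth.
- **Peaks / expression**: one peak per region with a group-dependent
  probability; expression matrices realise per-gene detection fractions
  exactly (k of n samples above FPKM 1).

What the synthetic panels do *not* emulate: overlapping gene models in the
coverage simulation, positional coverage bias, expression covariance between
genes, isoform switching, and stranded-library signal. Passing tests
demonstrate that the implementation recovers planted parameters under the
stated noise model — not that the thresholds are optimal for real tissue data.

## Problem sizes used in tests and the acceptance script

Panels are sized for single-CPU runs while keeping every estimate comfortably
powered: detector threshold panel 250 genes (tails 100 bp–10 kb, coverage
0.01–1.0 FPKM); end-to-end panel 500 genes × 3 samples; null calibration 800
independent matched comparisons; hexamer panels 800/1600 (null) and 250/350
(planted depletion) genes at 200 permutations with subsamples of 500 and 150;
retention panel 400 genes (mean 8 introns) × 3 samples at 200 permutations;
aging comparison 150 genes × 40 samples with a 3× shift planted in 50 genes.
The full suite runs in ~10 s and the acceptance script in ~10 s.

## Numerical notes and degenerate inputs

Ratios at 0/0 return 0 (`rt_ratio`, empty tails). Constant rows z-score to
zeros; identical groups compare at p = 1, d = 0. Interval arithmetic treats
touching intervals as non-overlapping (half-open convention) except interval
*merging*, where touching pieces fuse. bedGraph input rejects overlapping
records rather than guessing a combination rule. The k-mer counter skips any
window containing a non-ACGT symbol. Fold changes of proportions use an
epsilon of 1e-6 on group medians to handle zero baselines. All randomness
flows from explicit seeds; identical seeds give byte-identical outputs, and
the pipeline manifest records SHA-256 checksums of every file it writes.

## Known limitations

- Unstranded coverage cannot distinguish a readthrough tail from antisense
  transcription; the UND class under-counts true readthrough by design.
- The permutation t-test inherits the pseudo-replication caveat above;
  interpret hexamer FDRs only jointly with the score gate.
- FPKM from depth assumes uniform read length and ignores multi-mapping
  structure; no TPM or isoform-aware quantification.
- Seed matching is exact 8-mer only — no affinity model, conservation filter
  or miRNA expression integration.
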
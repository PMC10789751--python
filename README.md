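# rtkit

Transcription readthrough (TRT) analysis from coverage tracks: detection of
downstream-of-gene (DoG) transcripts, RT/NRT/UND gene classification, and the
statistics that characterise readthrough genes — expression-matched group
comparisons, hexamer enrichment at termination sites, intron retention,
genomic/epigenomic context, and miRNA-sponge prediction.

## Who this is for

RNA polymerase II sometimes continues past a gene's transcription termination
site (TTS), producing an extended downstream transcript (a readthrough tail,
or DoG). `rtkit` is for transcriptomics researchers who want to quantify this
phenomenon in bulk or single-cell RNA-seq coverage without re-running a full
alignment stack: the inputs are a gene annotation (GTF), per-sample bedGraph
coverage with library metadata, and optionally a genome FASTA, peak/state BED
files and mature miRNA sequences.

## The method

**Detection.** Starting at each expressed gene's TTS, consecutive
non-overlapping windows of 500 bp are scanned in the downstream direction. A
window passes while its coverage stays at or above 0.15 FPKM, where

```
FPKM = (sum(depth)/read_length) / ((length/1000) · (library_size/1e6)).
```

The tail is the span of passing windows (capped at 100 kb); a gene is **RT**
when the tail reaches 2000 bp, otherwise **NRT**. In unstranded libraries a
tail overlapping an opposite-strand gene cannot be attributed to either locus,
so the call is downgraded to **UND**; a tail invading a downstream same-strand
expressed gene is flagged as *read-in*. Expressed genes are those with
FPKM > 1 in at least 25% of a tissue's samples.

**Readthrough burden.** Per gene, `RTratio = RTlevels / (RTlevels +
GeneLevels)` from the median tail and gene-body FPKM across samples; the
per-sample version (median of tail/(tail+gene)) is the *RT proportion* used
for group comparisons (e.g. young < 40 vs old > 60 years, Mann-Whitney with
Benjamini-Hochberg FDR and fold-change direction).

**Group statistics.** RT and NRT genes differ in expression, so every
comparison runs on repeated equal-sized expression-matched subsamples:
randomly drawn RT genes paired with their nearest-neighbour NRT gene on
log2(FPKM+1), partners consumed without replacement. On top of that sit the
hexamer volcano (per 6-mer `score = log2(#6mer in RT / #6mer in NRT)` in
TTS±500 bp flanks, Welch t over the per-permutation count distributions,
thresholds FDR ≤ 0.001 and |score| ≥ 0.58), terminal intron retention
(`RPKM = (reads+1)/((length/1000)·(total/1e6))` on each gene's first two and
last two introns, flag at p < 0.05 and Cohen's d > 0.3), chromosome Fisher
enrichment, gene-density correlations, peak/state overlap of TTS±2 kb and
tail-end regions (RT tails ≥ 2500 bp only), and miRNA seed scanning
(positions 2–9 reverse-complemented, exact 8-mer matches; an RT tail with
≥ 20 sites for one miRNA is a putative sponge).

Every stage is exercised end-to-end by a synthetic-data generator that plants
readthrough tails of known length and coverage, antisense neighbours, intron
retention, sequence composition biases and exact seed-site counts, emitting a
machine-readable truth table.

## Worked example

```python
from rtkit.simulate import SimulationConfig, generate_annotation, generate_coverage
from rtkit import detect as det
from collections import Counter

cfg = SimulationConfig(n_genes=60, rng_seed=7, n_samples=1)
ds = generate_annotation(cfg)            # genes + planted truth table
(track,) = generate_coverage(ds, n_samples=1)

calls = [det.call_readthrough(track, g) for g in ds.genes]
calls = det.filter_opposite_strand(calls, ds.genes)
print(Counter(c.status for c in calls))

rt = [c for c in calls if c.status == "RT"]
c = rt[0]
print(c.gene_id, c.tail_start, c.tail_end, round(c.tail_fpkm, 3))
print(round(det.rt_ratio(c.tail_fpkm, 20.0), 3))
```

prints

```
Counter({'NRT': 44, 'RT': 14, 'UND': 4})
G0014 137038 146038 0.934
0.045
```

i.e. of 62 genes (60 plus 2 planted antisense neighbours), 14 are called RT;
the 4 planted antisense-overlap cases are correctly downgraded to UND. Gene
`G0014` carries a 9 kb tail at 0.93 FPKM; against a gene body at 20 FPKM that
is a readthrough ratio of 0.045 — about 4.5% of the locus signal comes from
the tail.

The same run from a shell:

```
rtk simulate --seed 7 --n-genes 60 --out sim/
rtk detect --annotation sim/annotation.gtf --chrom-sizes sim/genome.chrom.sizes \
    --coverage sim/coverage_s1.bedgraph --library-size 1000000 --read-length 100 \
    --out calls.tsv
```

`rtk all --config pipeline.cfg` runs quantification, detection,
classification, RT-ratio matrix, intron retention and (when a genome/miRNA
FASTA is configured) the hexamer and sponge analyses, writing a checksummed
manifest for reproducibility.

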
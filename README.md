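# apa-rhythm

Reusable pipeline for transcriptome-wide poly(A)-site (PAS) analysis of
circadian/ultradian rhythmicity and sleep-pressure response from 3'-tag
sequencing data, exercised end-to-end on ground-truthed synthetic data.

Stages:

1. **simulate** — synthetic gene models (GTF), tag alignments (BED6), FASTQ
   reads and NB count matrices with planted cosinor rhythms (24 h / 12 h),
   sleep-deprivation effects and 5' T-rich read artifacts, all linked to a
   truth table.
2. **preprocess** — FASTQ quality filter (Phred ≥ 10 for ≥ 50% of bases),
   5' T / T-rich trimming, ≥ 16 bp retention.
3. **call-pas** — cleavage-site extraction from BED/SAM, single-linkage
   clustering of sites within 25 nt into PACs, library-size-adaptive
   retention (≥ 3 samples with ≥ 3 reads below 1.7M reads/library, ≥ 4 reads
   at or above), mitochondrial removal, normalization to reads per 10^7.
4. **annotate** — PAC-to-gene assignment with six region categories
   (internal exon / intron / 3'UTR-internal / 3'UTR-terminal / 3'UTR-distal /
   intergenic) and per-gene APA statistics.
5. **rhythm** — three detectors (cosinor harmonic regression, single-frequency
   Lomb–Scargle, exact-null Kendall-tau cosine matching) combined per trial
   by Fisher's method; five replicate-slotted trials (Latin-square rotation
   or seeded random); consensus requires p < 0.05 in all five trials; 5-h
   sliding phase windows.
6. **diffexp** — sleep-deprivation recovery contrasts (R0 vs ZT6, R2 vs ZT8,
   R4 vs ZT10, R8 vs ZT14): design-protected PC1 nuisance removal, NB Wald
   tests with trended dispersion shrinkage, Cauchy-prior LFC shrinkage, BH
   and empirical-null local FDR.
7. **ora** — hypergeometric over-representation analysis of gene sets (GMT).

## CLI

```bash
apa-rhythm simulate --seed 1 --n-genes 200 --outdir sim/
apa-rhythm preprocess --in sim/reads.fastq --out clean.fastq
apa-rhythm call-pas --tags sim/tags.bed --samples sim/samples.tsv --out pacs.tsv
apa-rhythm annotate --pacs pacs.tsv --gtf sim/genes.gtf --out annot.tsv
apa-rhythm rhythm --pacs pacs.tsv --samples sim/samples.tsv --period 24 --out rhythm24.tsv
apa-rhythm diffexp --pacs pacs.tsv --samples sim/samples.tsv --out de.tsv
apa-rhythm ora --query genes.txt --gmt sets.gmt --universe universe.txt
apa-rhythm all --seed 1 --outdir out/        # whole pipeline + manifest.json
```

All coordinates in output TSVs are 1-based inclusive; phases are ZT hours of
the fitted peak; normalized counts are reads per 10^7.

## Conventions

- NB parameterization: var = μ + αμ² everywhere.
- Clustering distance inclusive (gap ≤ 25 nt merges); library-size boundary
  resolved as ≥ 1.7M → stricter rule.
- Rhythm detectors run on raw counts by default (normalized mode available).
- Lomb–Scargle uses the exact finite-sample single-frequency null by default;
  the asymptotic `exp(-P)` form is available as `p_mode="asymptotic"`.
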
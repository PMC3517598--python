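# beadvar

Variance decomposition, covariate-adjustment evaluation and in-probe
SNP artifact analysis for Illumina bead-array gene-expression studies.

Population-scale expression studies on BeadChip arrays (e.g. HumanHT-12:
12 single-sample arrays per chip, samples prepared on 96-well isolation
and amplification plates) carry strong technical structure: chip and
plate assignment, sample storage time and RNA quality leave fingerprints
on every probe, and a principal component analysis of the raw profiles
is dominated by them. This package implements, as a tested pipeline,
the methodological toolkit used to quantify and neutralize that
structure, plus a synthetic-study generator with known ground truth so
every stage is validated by parameter recovery rather than by eye.
It is aimed at analysts preparing bead-array expression data for
association studies and meta-analyses.

## What the pipeline computes

**Preprocessing.** Rank-based detection p-values against negative
controls, `p_gi = (1 + #{controls ≥ x_gi}) / (N + 1)`; sample and probe
detection filters; a Y-probe 2-means sex check; quantile normalization;
log2 transformation (L2T); and a generalized-log variance-stabilizing
transformation (VST)

&nbsp;&nbsp;&nbsp;&nbsp;h(x) = a·ln(c₁x + c₂ + √((c₁x + c₂)² + c₃²)) + b,

with (c₁, c₂) from a robust fit of the raw-scale sd-vs-mean relation
sd ≈ c₁·mean + c₂ and (a, b) calibrated so h coincides with log2 at the
75th and 95th percentiles of mean intensity.

**Variance decomposition.** PCA over samples (centered or uncentered)
and the Eigen-R² statistic: each eigengene **u**ₖ is regressed on a
factor, and the eigenvalue-weighted sum Σₖ (λₖ/Σλ)·R²ₖ (adjusted R²,
floored at 0) estimates the factor's share of total expression
variance. A factor × PC association scan and a technical-effect
residualization complete the module.

**Adjustment evaluation.** Probewise OLS of expression on a phenotype
plus covariate sets, summarized by the mean over probes of the
phenotype coefficient's standard error (mean SE). A standard-normal
pseudo-phenotype ("random phenotype") makes the comparison free of
confounding; the unexplained-variance curve traces mean (1 − adj. R²)
against the number of PC covariates.

**Probe annotation.** Exact sense-strand matching of 50-mer probe
sequences against transcript mRNA, uniqueness classification
(unique mRNA / unique gene / ambiguous / unmapped) and projection
through exon blocks to genomic coordinates.

**In-probe SNPs.** For probes that map uniquely to a single exon on the
forward strand, every SNP inside the probe interval defines a
mismatch-allele dosage (the allele the probe does *not* carry). The
probe's log2 expression is regressed on that dosage (adjusting for sex,
age and the leading PCs); a one-sided binomial test checks the excess
of decreased-signal directions; and each nominal hit is refit
conditional on its strongest LD partner (dosage R²) within 100 kb
upstream of the transcription start site, separating genuine
hybridization artifacts from cis-regulatory proxies.

## Worked example

The numbered scripts under `analysis/` run the full chain on one
synthetic study (192 samples × 1000 probes, technical variance shares
chip 0.34 / amplification plate 0.20 / isolation plate 0.16, ten
planted mismatch effects of −0.5 log2 per allele and ten null in-probe
SNPs), exchanging data through the on-disk formats (sample-probe TSV,
covariate TSV, VCF, FASTA, BED12):

```sh
python analysis/01_simulate_study.py
python analysis/02_qc_and_transform.py
python analysis/03_variance_decomposition.py
python analysis/04_adjustment_evaluation.py
python analysis/05_annotate_probes.py
python analysis/06_snp_in_probe.py
```

Output highlights (small tables land in `results/`):

```
L2T vs VST: max |difference| above 2^9 = 0.039; association -log10 p squared correlation = 0.9962
uncentered PCA: PC1 explains 99.2% of total variation (shared mean profile)
removing ['chip', 'amplification_plate', 'isolation_plate', 'storage_time'] drops centered PC1 from 37.4% to 17.7% of variance
technical covariates cut the mean SE by 15.1%; the first 50 PCs cut it by 42.8%
unexplained variance: 100% at 0 PCs -> 31.3% at 50 -> 25.4% at 100
20 tests (0 monomorphic skips), Bonferroni threshold 2.50e-03: 10 significant
direction: 16 decreased vs 4 increased signal per mismatch allele (one-sided binomial p = 0.00591)
LD conditioning of the 11 nominal hits: ... 9 of 10 stayed Bonferroni-significant
```

Reading: the two transformations disagree only in the compressed
low-intensity range and give essentially identical association
p-values; the dominant first PC is common-mode technical signal and
collapses once the batch factors are residualized; adjusting for a few
named technical covariates recovers most of the power gain of a 50-PC
adjustment without the risk of absorbing real phenotype signal; and the
conditioning step keeps the planted mismatch effects significant while
the null in-probe SNPs never reach the Bonferroni threshold.

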
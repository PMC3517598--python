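# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of the pipeline. It states
no empirical result that the test suite or `scripts/acceptance.py` do
not themselves compute.

## The synthetic study generator

The generator (`beadvar.simulate`) emulates the data structure of a
population-cohort bead-array expression study so that every downstream
stage can be validated by parameter recovery.

**Signal model.** The log2-scale signal for probe *g* and sample *i* is

    y_gi = μ_g + Σ_f s_g·√(frac_f)·ε_gf·z_f(i) + β_g·d_g(i) + e_gi

* μ_g — per-probe baseline. A configurable fraction of probes
  (default 70%) is "expressed" with μ_g ~ Uniform(8, 14) on the log2
  scale; the rest sit on a background distribution
  μ_g ~ N(6.0, 0.4) (raw ≈ 64 intensity units).
* z_f — standardized per-sample factor score. Categorical factors
  (chip, plates, sex) draw one normal effect per level; continuous
  factors (storage time, cell composition, BMI) use their standardized
  values.
* ε_gf ∈ {−1, +1} — per-probe Rademacher loading. With z standardized
  and the loading magnitude fixed at √(frac_f), every probe's share of
  log-scale variance attributable to factor *f* is exactly frac_f,
  which is what makes the recovery tests sharp.
* s_g — total log2 signal scale: 1.0 for expressed probes, reduced to
  0.3 for background probes (a bead with no complementary mRNA has
  little biological or batch-driven signal to vary; its variability is
  mostly additive scanner noise). Negative controls are generated
  exactly like background probes, which is what makes the rank-based
  detection p-values meaningful.
* β_g·d_g — planted mismatch effect: for a configurable set of
  expressed, forward-strand, single-exon probes a SNP is placed inside
  the probe's 50-mer, the probe carries the reference base, and the
  alt-allele dosage enters with β_g (default −0.5 log2 per allele).
  An equal-sized set of null in-probe SNPs (β = 0) is planted so the
  scan's specificity is visible against truth.
* e_gi — residual log-scale noise absorbing the remaining
  1 − Σ frac_f of the per-probe variance.

Raw intensities are x = 2^y perturbed with additive noise of standard
deviation c₁·x + c₂ (defaults c₁ = 0.1, c₂ = 6), reproducing the
mean-dependent noise that motivates a variance-stabilizing
transformation. Values are floored at 0.5 to keep the raw scale
positive.

**Batch structure.** Samples are assigned consecutively: 12 arrays per
chip, 8 chips per 96-well amplification plate; the isolation-plate
labels are the same grouping shifted by half a chip, so the two plate
factors are strongly confounded but not identical — mirroring
real processing chains in which almost all samples sharing a chip also
share their plates. Storage time is 30·(plate index) + Uniform(0, 30)
days, i.e. deliberately confounded with plate order, as happens when
samples are processed in collection order. Consequences:

* A label-based variance decomposition for `chip` necessarily absorbs
  the plate shares (chip labels are finer than, and nested in, plate
  labels). Recovery tests therefore plant the factor of interest alone
  (or independent factors), while the default study keeps the
  realistic confounded layout; on that layout the per-factor
  attributions overlap and their sum exceeds the planted total, which
  is the expected behaviour, not an error.
* Configs with fewer samples than one full chip are rejected.

**Sex.** A configurable set of probes is placed on chrY transcripts
with background baseline for females and a +3.0 log2 shift for males;
the truth record carries the per-sample sex, so the 2-means sex check
is testable for exact recovery.

**Genotypes.** Biallelic SNP dosages come from a latent-haplotype
block model: each of the two haplotype copies of a sample carries one
block-wide standard-normal latent; every SNP thresholds a noisy copy
(latent correlation 0.98 by default) at its own MAF quantile. Marginal
allele frequencies are exact; within-block dosage R² is high but
attenuated by MAF differences (binary variables cannot reach R² = 1
across unequal frequencies); blocks are independent. In the full study
each in-probe SNP heads a block whose remaining members sit upstream
of the probe's transcript TSS, so the LD-conditioning step finds
partners. The `generate_ld_scenario` helper builds the focused
two-SNP design (in-probe SNP + one high-LD upstream partner + a few
independent upstream SNPs) with the causal variant switchable between
them.

**Sequences.** Transcripts are random mRNA with 1–3 exon blocks laid
out far apart on a small set of chromosomes; probes are exact 50-mer
substrings. Ambiguity classes are constructed by embedding a probe's
sequence into a second transcript of the same or another gene; orphan
probes are random 50-mers (collision probability with a random
transcript is negligible at this length).

**What the generator does not emulate.** Bead-level replicates,
spatial chip artifacts, imputation dosage uncertainty (dosages are
integer genotypes; only a per-variant quality scalar is carried),
RNA-degradation kinetics, probe GC/affinity structure, and correlated
expression modules (probes are independent given the factors). Passing
tests therefore demonstrate the correctness and calibration of the
*methods* under a controlled data-generating process, not their
performance on any particular real cohort.

## Preprocessing

**Detection p-values** use the add-one rank estimator
p = (1 + #{controls ≥ x}) / (N + 1) per sample: p = 0 is impossible,
ties count against detection, and at least 20 controls are required.
The sample filter keeps a sample iff at least `min_detected` probes
(default 6000, the conventional full-array value) are detected at
p < 0.01 — a sample exactly at the threshold is kept. The analysis
scripts on the 1000-probe synthetic panel scale this to 600 (the same
~1/8 of the panel). The probe filter keeps probes detected in at least
half the samples; background probes dilute any variance-share estimate
because their variability is mostly measurement noise, so the
decomposition stages run on detected probes.

**Sex check.** Per sample, the mean log2 intensity over Y probes is
split by 1-d 2-means; the higher cluster is labelled male. If the two
centers are closer than a margin (default 1.0 log2 units) the cohort
is treated as single-sex and no calls are made (logged warning).

**Quantile normalization** maps each sample's sorted vector onto the
across-sample mean of sorted vectors; a tie group receives the mean of
the reference quantiles it spans. On tie-free data the operation is
idempotent and leaves all samples with identical sorted columns; with
ties the tie rule trades exact idempotence for determinism.

**VST.** The transform is the generalized log
h(x) = a·ln(c₁x + c₂ + √((c₁x + c₂)² + c₃²)) + b with c₃ = 0 by
default, so h is affine in ln(x + c₂/c₁): only the crossover c₂/c₁
shapes the low range, while (a, b) pin the high range to log2 exactly
at the 75th and 95th percentiles of per-probe mean intensity. Fitting:
samples are first rescaled to a common median (sample effects are
multiplicative on the raw scale; subtracting medians would inject the
expressed-probe median's variability into the background probes), then
the line sd = c₁·mean + c₂ is fit by Theil–Sen on the
bottom-quartile-intensity probes — the additive floor c₂ is only
identifiable where the multiplicative term does not dominate, and the
high range is pinned by the calibration anyway. On data following the
line exactly, slope and intercept are recovered. The noise model is a
property of the raw measurements, so the parameters are fit before
quantile normalization (which reshapes low-intensity ranks) and then
applied to the normalized matrix. Degenerate fits (nonpositive slope)
raise rather than silently producing a non-monotone transform. The
pipeline order is fixed as QC-filter → quantile-normalize → transform.

## Variance decomposition

PCA treats samples as observations and probes as variables, via SVD.
Centering is explicit: uncentered PCA shows the dominant shared-mean
component (PC1 typically > 95% of total variation); probe-centered PCA
feeds the Eigen-R² regressions and PC covariates. Score-vector signs
are fixed (largest-magnitude entry positive) for determinism.

**Eigen-R²** regresses each retained eigengene on the factor
(continuous: simple linear model; categorical: full dummy coding) and
returns Σₖ (λₖ/Σλ)·max(adj R²ₖ, 0) over components up to 99.9%
cumulative variance. Adjusted R² counters the small-sample
overestimation seen with raw R²; the floor at zero, however, induces a
positive bias that grows with the factor's dummy count (a permuted
16-level batch factor scores ≈ 0.04 where a permuted binary factor
scores < 0.02 at n = 192). Interpret many-level batch attributions
with that floor in mind. Component retention at 99.9% bounds cost
without materially changing the weighted sum. Batch identifiers are
treated as categorical, storage time as continuous.

**PC–factor scan**: F-test of score ~ factor per (factor, component),
with the Bonferroni threshold 0.05/(number of factors) attached.

**Technical-effect removal** residualizes each probe on the dummy-coded
technical factors and adds the probe's grand mean back; collinear
columns (e.g. plate dummies nested in chip dummies) are detected by
pivoted QR and dropped with a warning.

## Adjustment evaluation

All fits run through one vectorized OLS engine (shared design, many
response vectors; coefficient SEs from σ̂²·(XᵀX)⁻¹ with σ̂² = RSS/df;
two-sided t p-values), which the tests pin to a hand-rolled
normal-equations oracle at 1e-8. Samples with missing covariate values
are dropped per model with a logged count.

The **mean-SE metric** is the arithmetic mean over all fitted probes of
the phenotype coefficient's SE. The **random phenotype** (standard
normal draws, seeded) cannot be genuinely associated with anything, so
scenario differences in mean SE measure residual-variance reduction
only; adding pure-noise covariates must not reduce it (the df-corrected
σ̂² stays unbiased while the variance inflation of the phenotype column
grows with the covariate count — with 50 noise covariates at n = 192
the mean SE *increases* by roughly p/n, i.e. double-digit percent; a
decrease beyond 1% would indicate a broken metric). The default
scenario grid is: none; age+sex; technical (amplification plate, RIN,
storage time); age+sex+technical; technical+PC1; first 50 PCs;
technical+cell composition.

The **unexplained-variance curve** reports, per number k of PC
covariates, the mean over probes of (1 − adj R²) for
expr ~ phenotype + PC1..PCk, normalized to k = 0 (= 100%). PCs are
taken from the probe-centered PCA of the same matrix, so the curve is
nonincreasing in practice (each added component is the next-largest
in-sample variance direction); it is truncated with a warning when k
approaches the residual degrees of freedom.

PC adjustment is powerful but double-edged: data-derived PCs can
absorb genuine signal. This is visible in the in-probe SNP tests —
with a small probe panel, 50 PC covariates shrink a planted −0.5
log2/allele effect noticeably (detection is unaffected, estimation is
attenuated), so the estimation-accuracy tests use 10 PCs while the
power tests keep 50. On a full-size panel (tens of thousands of
probes) the attenuation is negligible.

## Probe annotation

Exact sense-strand substring matching of each probe against all
transcript mRNA sequences (probes target mRNA; a reverse-complement
scan exists as a diagnostic flag only). Classification: no hit →
unmapped; one transcript, one offset → unique_mrna; several
transcripts of one gene → unique_gene; several genes, or repeated
offsets within one transcript (coordinates would be ill-defined) →
ambiguous. For unique_gene probes the coordinates of the first
transcript in identifier order are reported. Genomic projection walks
the exon blocks (0-based half-open, forward-strand coordinates
throughout the package; minus-strand mRNA offsets count from the right
edge of the last block) and returns the genomic envelope plus the
number of blocks intersected; a per-base brute-force oracle pins the
projection in the tests. Coordinates are on the build of the supplied
models; the annotation file carries a build tag, and no lift-over is
performed.

## In-probe SNP analysis

Eligibility: unique_mrna mapping, exactly one exon spanned,
coordinates present, forward strand (position-in-probe arithmetic and
probe-allele lookup assume the probe sequence is collinear with the
genome). Matching: one pair per (variant, probe) — a variant inside
two overlapping probes yields two tests; indels and multiallelic
records are excluded; pairs where the probe base equals neither allele
are dropped and counted. The mismatch dosage is the alt dosage when
the probe carries the reference base, else 2 − alt dosage, so
mismatch dosage + probe-allele dosage = 2 always.

The association model is OLS of the probe's log2 expression on the
mismatch dosage with sex, age and the first 50 probe-centered PCs as
covariates; monomorphic dosages are skipped (not errors), and a
residual-df guard raises when the covariate count approaches the
sample count. Bonferroni corrections use the number of *completed*
tests (skips are not tests). The direction test is the one-sided exact
binomial test of #negative against 0.5, at three filters (all,
nominal p < 0.05, Bonferroni). The multi-SNP accumulation test is the
2×2 chi-square (no continuity correction) of nominal significance
against probe SNP burden (≥ 3 SNPs), counting one unit per association.

LD conditioning: for each association with p < 0.05, candidate
partners are variants within 100 kb upstream of the probe's transcript
TSS (strand-aware; TSS = transcript 5' end), LD measured as squared
Pearson correlation of dosages (the standard estimator when only
imputed dosages are available). The partner with the highest R² above
0.1 joins the model as a covariate and the mismatch p-value is
re-read; the summary reports partner counts at R² > 0.1 and > 0.5, the
fraction of conditioned pairs whose p increased, and how many
Bonferroni-significant pairs remain significant. A genuine mismatch
effect survives conditioning (with an inflated SE proportional to
1/√(1 − R²)); a pure cis-proxy collapses to the null.

## Problem sizes and determinism

The default study is 192 samples × 1000 probes — two amplification
plates, sixteen chips — the size at which planted variance fractions
are recoverable within ±0.05 and the full pipeline runs in seconds.
The null-calibration study uses 100 seeds of 96 × 200; power and
estimation use 504 samples; the LD scenarios use 50 replicates of 400
samples each. All randomness flows from explicit integer seeds
(`numpy.random.default_rng`); identical seeds give bit-identical
studies, and the acceptance script derives every sub-seed from its
`--seed` argument.

One calibration note: with twelve completed tests per null study, the
familywise error of the per-study Bonferroni check is just under 5%,
so the expected fraction of seeds with zero Bonferroni hits is ≈ 95% —
the "≥ 95% of seeds clean" check sits almost exactly at its
expectation and is the sharpest test in the suite.

## Known limitations

* Eigen-R² attributions of nested/confounded batch factors overlap by
  construction; the statistic answers "how much variance do these
  labels explain", not "how much is uniquely caused by this factor".
* The floor-at-zero bias of Eigen-R² for many-level factors (above).
* The VST's two-regime mean-variance fit assumes the bottom quartile
  of probes is background-dominated; on arrays where most probes are
  expressed the crossover estimate degrades gracefully toward a pure
  log (c₂ → 0).
* OLS only: no mixed models, no robust/sandwich SEs, Bonferroni is the
  only multiplicity correction.
* The package consumes genotype dosages; calling and imputation are
  out of scope, as are IDAT parsing and genome-build lift-over.
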
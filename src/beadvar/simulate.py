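"""Synthetic bead-array study generator with known ground truth.

Emulates the structure of a population-cohort Illumina expression study:
12-array chips nested in 96-well amplification plates, plate-confounded
storage times, factor-specific shares of log-scale expression variance,
a mean-dependent raw-intensity noise model (sd = c1*mean + c2),
Y-linked probes for sex checks, genotypes in LD blocks, and planted
mismatch (in-probe SNP) dosage effects on probes whose 50-mer sequences
overlap a SNP.

Every quantity a downstream stage is supposed to estimate (variance
fractions, noise coefficients, sex, SNP effect sizes) is recorded in a
:class:`StudyTruth` so each stage is testable by parameter recovery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    ExpressionMatrix,
    FactorTable,
    GenotypeMatrix,
    TranscriptModel,
    Variant,
)

BASES = np.array(list("ACGT"))

#: factor-specific shares of log2-scale variance used by default; the
#: technical shares dominate (chip > amplification > isolation plate),
#: storage time and cell composition contribute a few percent, and the
#: biological factors sex and BMI are small.
DEFAULT_VARIANCE_FRACTIONS: dict[str, float] = {
    "chip": 0.34,
    "amplification_plate": 0.20,
    "isolation_plate": 0.16,
    "storage_time": 0.03,
    "lymphocyte_pct": 0.03,
    "sex": 0.01,
    "bmi": 0.007,
}


@dataclass
class SimulationConfig:
    """Parameters of a synthetic study.

    ``variance_fractions`` maps factor name -> share of total log2-scale
    variance planted for that factor (keys must be factor-table column
    names). ``noise_c1``/``noise_c2`` parameterize the raw-scale
    mean-variance relation sd = c1*mean + c2. ``signal_log_sd`` is the
    total log2-scale standard deviation per probe; set to 0 (with
    ``raw_noise_enabled=False``) for noise-free baselines.
    """

    n_samples: int = 192
    n_probes: int = 1000
    n_negative_controls: int = 100
    chips_per_plate: int = 8
    arrays_per_chip: int = 12
    variance_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_VARIANCE_FRACTIONS)
    )
    noise_c1: float = 0.1
    noise_c2: float = 6.0
    n_snps: int = 60
    ld_block_size: int = 5
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_mismatch_probes: int = 10
    n_null_in_probe_snps: int = 10
    mismatch_effect_size: float = -0.5
    seed: int = 0
    # generator shape knobs
    signal_log_sd: float = 1.0
    raw_noise_enabled: bool = True
    expressed_fraction: float = 0.7
    baseline_range: tuple[float, float] = (8.0, 14.0)
    background_mean: float = 6.0
    background_sd: float = 0.4
    #: unexpressed probes (and negative controls) carry this fraction of
    #: the signal-scale log variance: background beads have no mRNA to
    #: vary, so their variability is mostly additive scanner noise
    background_signal_scale: float = 0.3
    n_y_probes: int = 20
    sex_effect_size: float = 3.0
    minus_strand_fraction: float = 0.1
    two_exon_fraction: float = 0.1
    probe_length: int = 50

    def validate(self) -> None:
        for name in ("n_samples", "n_probes", "n_negative_controls",
                     "chips_per_plate", "arrays_per_chip"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        total = sum(self.variance_fractions.values())
        if total > 1 + 1e-12:
            raise ValueError(f"variance fractions sum to {total:.3f} > 1")
        if any(f < 0 for f in self.variance_fractions.values()):
            raise ValueError("variance fractions must be nonnegative")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if self.noise_c1 <= 0:
            raise ValueError("noise_c1 must be > 0")
        if self.n_samples < self.arrays_per_chip:
            raise ValueError(
                f"n_samples ({self.n_samples}) smaller than arrays_per_chip "
                f"({self.arrays_per_chip}); at least one full chip is required"
            )


@dataclass
class PlantedSnpEffect:
    probe_id: str
    variant_id: str
    beta: float
    maf: float
    position_in_probe: int


@dataclass
class StudyTruth:
    """Ground truth of one generated study."""

    variance_fractions: dict[str, float]
    factor_scores: pd.DataFrame  # standardized per-factor score per sample
    sex: pd.Series  # "male"/"female" per sample
    baseline: pd.Series  # per-probe log2 baseline
    expressed: pd.Series  # bool per probe
    y_probe_ids: list[str]
    snp_effects: list[PlantedSnpEffect]
    noise_c1: float
    noise_c2: float
    signal_log_sd: float


@dataclass
class SyntheticStudy:
    expression: ExpressionMatrix  # raw intensities
    negative_controls: pd.DataFrame  # control x sample raw intensities
    factors: FactorTable
    genotypes: GenotypeMatrix
    probe_sequences: dict[str, str]
    transcript_models: list[TranscriptModel]
    probe_truth: pd.DataFrame  # probe_id, transcript_id, offset
    truth: StudyTruth


# ---------------------------------------------------------------------------
# genotypes


def _latent_block_alleles(rng: np.random.Generator, mafs: np.ndarray,
                          n_samples: int, latent_r: float) -> np.ndarray:
    """Dosages for one LD block via a shared latent haplotype signal.

    Each of the two haplotype copies of each sample carries a block-wide
    latent normal; each SNP thresholds a noisy copy of it at its own MAF
    quantile, so P(allele) = maf exactly while adjacent SNPs are highly
    correlated for latent_r near 1.
    """
    n_snps = len(mafs)
    shared = rng.normal(size=(2, n_samples))
    noise = rng.normal(size=(n_snps, 2, n_samples))
    z = np.sqrt(latent_r) * shared[None, :, :] + np.sqrt(1 - latent_r) * noise
    thresh = stats.norm.ppf(mafs)[:, None, None]
    alleles = (z < thresh).astype(float)
    return alleles.sum(axis=1)  # (n_snps, n_samples) dosages in {0,1,2}


def generate_genotypes(
    n_samples: int,
    n_snps: int,
    ld_block_size: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    latent_r: float = 0.98,
    chrom: str = "chr1",
    start_pos: int = 1000,
    spacing: int = 1000,
    sample_ids: list[str] | None = None,
    id_prefix: str = "rs",
) -> GenotypeMatrix:
    """Biallelic SNP dosages in mutually independent LD blocks.

    SNPs within a block share a latent haplotype signal (``latent_r``
    controls the block LD strength); blocks are independent. MAFs are
    drawn uniformly from ``maf_range``. Positions are 1-based,
    ``spacing`` bp apart on ``chrom``.
    """
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must lie within (0, 0.5], got {maf_range}")
    if ld_block_size > n_snps:
        raise ValueError("ld_block_size must not exceed n_snps")
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(lo, hi, size=n_snps)
    dosages = np.empty((n_snps, n_samples))
    for block_start in range(0, n_snps, ld_block_size):
        block = slice(block_start, min(block_start + ld_block_size, n_snps))
        dosages[block] = _latent_block_alleles(rng, mafs[block], n_samples, latent_r)
    variants = []
    for j in range(n_snps):
        ref, alt = rng.choice(BASES, size=2, replace=False)
        variants.append(Variant(chrom=chrom, pos=start_pos + j * spacing,
                                ref=str(ref), alt=str(alt), maf=float(mafs[j]),
                                variant_id=f"{id_prefix}{j + 1}"))
    if sample_ids is None:
        sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    return GenotypeMatrix(variants=variants, dosages=dosages, sample_ids=list(sample_ids))


# ---------------------------------------------------------------------------
# sequences


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def generate_sequences(
    transcript_count: int,
    probes_per_transcript: int = 1,
    probe_length: int = 50,
    seed: int = 0,
    transcript_length: int = 200,
    exon_counts: list[int] | None = None,
    strands: list[str] | None = None,
    chroms: list[str] | None = None,
    n_shared_same_gene: int = 0,
    n_shared_cross_gene: int = 0,
    n_orphan_probes: int = 0,
    junction_probes: int = 0,
    genomic_gap: int = 1_000_000,
    genomic_offset: int = 200_000,
) -> tuple[dict[str, str], list[TranscriptModel], pd.DataFrame]:
    """Random transcripts with probes that are exact mRNA substrings.

    Returns ``(probe_sequences, transcript_models, probe_truth)`` where
    ``probe_truth`` records each probe's source transcript and 0-based
    offset (NaN/None for orphan probes, which match no transcript).

    ``n_shared_same_gene`` probes are additionally embedded in a second
    transcript of the same gene, ``n_shared_cross_gene`` in a transcript
    of a different gene (to exercise the uniqueness classes), and
    ``junction_probes`` probes are placed across the first exon-exon
    junction of multi-exon transcripts.
    """
    if probe_length >= transcript_length:
        raise ValueError("probe_length must be smaller than transcript length")
    rng = np.random.default_rng(seed)
    n_extra = n_shared_same_gene + n_shared_cross_gene
    total_tx = transcript_count + n_extra  # host transcripts for shared probes
    if exon_counts is None:
        exon_counts = [1] * total_tx
    if strands is None:
        strands = ["+"] * total_tx
    if chroms is None:
        chroms = [f"chr{(i % 5) + 1}" for i in range(total_tx)]
    if not (len(exon_counts) == len(strands) == len(chroms) == total_tx):
        raise ValueError("exon_counts/strands/chroms must cover all transcripts "
                         f"({total_tx} incl. shared-probe hosts)")

    # lay transcripts out on their chromosomes, far apart
    per_chrom_index: dict[str, int] = {}
    seqs: list[str] = []
    models: list[TranscriptModel] = []
    for i in range(total_tx):
        idx = per_chrom_index.get(chroms[i], 0)
        per_chrom_index[chroms[i]] = idx + 1
        gstart = genomic_offset + idx * genomic_gap
        n_ex = exon_counts[i]
        # split transcript_length into n_ex exon blocks with random introns
        cuts = sorted(rng.choice(np.arange(1, transcript_length), size=n_ex - 1,
                                 replace=False)) if n_ex > 1 else []
        lengths = np.diff([0, *cuts, transcript_length]).astype(int)
        exons = []
        pos = gstart
        for L in lengths:
            exons.append((pos, pos + int(L)))
            pos += int(L) + int(rng.integers(100, 1000))  # intron
        seq = _random_seq(rng, transcript_length)
        seqs.append(seq)
        gene_id = f"GENE{i + 1:05d}"
        models.append(TranscriptModel(
            transcript_id=f"TX{i + 1:05d}", gene_id=gene_id, chrom=chroms[i],
            strand=strands[i], exons=exons, sequence=seq))

    # shared-probe hosts: transcripts transcript_count..total_tx-1
    # same-gene hosts share the gene of their source transcript
    for k in range(n_shared_same_gene):
        models[transcript_count + k].gene_id = models[k].gene_id

    # choose probe offsets per primary transcript
    probe_rows: list[dict] = []
    probe_sequences: dict[str, str] = {}
    probe_counter = 0
    offsets_of: list[list[int]] = []
    for i in range(transcript_count):
        offs = []
        if junction_probes and i < junction_probes and exon_counts[i] > 1:
            # straddle the first exon-exon junction
            first_len = models[i].exons[0][1] - models[i].exons[0][0]
            lo = max(0, first_len - probe_length + 1)
            hi = min(first_len - 1, transcript_length - probe_length)
            offs.append(int(rng.integers(lo, hi + 1)))
        while len(offs) < probes_per_transcript:
            offs.append(int(rng.integers(0, transcript_length - probe_length + 1)))
        offsets_of.append(offs)

    # embed shared probes into their host transcripts before extraction
    for k in range(n_extra):
        src = k  # probe 0 of transcript k is the shared one
        host = transcript_count + k
        off_src = offsets_of[src][0]
        sub = seqs[src][off_src:off_src + probe_length]
        off_host = int(rng.integers(0, transcript_length - probe_length + 1))
        s = seqs[host]
        seqs[host] = s[:off_host] + sub + s[off_host + probe_length:]
        models[host].sequence = seqs[host]

    for i in range(transcript_count):
        for off in offsets_of[i]:
            probe_counter += 1
            pid = f"PR{probe_counter:05d}"
            probe_sequences[pid] = seqs[i][off:off + probe_length]
            probe_rows.append({"probe_id": pid, "transcript_id": models[i].transcript_id,
                               "offset": off})
    for _ in range(n_orphan_probes):
        probe_counter += 1
        pid = f"PR{probe_counter:05d}"
        probe_sequences[pid] = _random_seq(rng, probe_length)
        probe_rows.append({"probe_id": pid, "transcript_id": None, "offset": None})

    probe_truth = pd.DataFrame(probe_rows).set_index("probe_id")
    return probe_sequences, models, probe_truth


# ---------------------------------------------------------------------------
# full study


def _standardize(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def generate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate a complete synthetic study from ``config``.

    Log2-scale signal for probe g, sample i is

        y_gi = mu_g + sum_f s * sqrt(frac_f) * sign_gf * z_f(i)
               + beta_g * d_mismatch(i) + eps_gi

    with s the total log2 sd, z_f the standardized per-sample factor
    score, sign_gf a per-probe Rademacher loading (so each factor's
    share of log-scale variance is exactly frac_f for every probe), and
    eps residual noise absorbing the remaining variance. Raw intensity
    is 2**y perturbed so the raw-scale sd is about c1*mean + c2.
    Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p = config.n_samples, config.n_probes
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    # --- nested batch structure (arrays -> chips -> plates), consecutive
    chip = np.arange(n) // config.arrays_per_chip
    samples_per_plate = config.arrays_per_chip * config.chips_per_plate
    amp_plate = chip // config.chips_per_plate
    # isolation plate: same plate layout shifted by half a chip, so the
    # two plate factors are confounded but not identical
    iso_plate = (np.arange(n) + config.arrays_per_chip // 2) // samples_per_plate

    storage_time = 30.0 * amp_plate + rng.uniform(0, 30, size=n)
    rin = np.clip(rng.normal(8.6, 0.5, size=n), 6.0, 10.0)
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    lymphocyte_pct = np.clip(rng.normal(30, 7, size=n), 5, 60)
    bmi = np.clip(rng.normal(27.3, 4.6, size=n), 16, 50)
    age = np.clip(rng.normal(50, 13, size=n), 20, 85)

    factor_df = pd.DataFrame({
        "chip": [f"chip{c + 1:03d}" for c in chip],
        "amplification_plate": [f"amp{c + 1:02d}" for c in amp_plate],
        "isolation_plate": [f"iso{c + 1:02d}" for c in iso_plate],
        "storage_time": storage_time,
        "rin": rin,
        "sex": sex,
        "age": age,
        "lymphocyte_pct": lymphocyte_pct,
        "bmi": bmi,
    }, index=pd.Index(sample_ids, name="sample_id"))
    types = {"chip": "categorical", "amplification_plate": "categorical",
             "isolation_plate": "categorical", "storage_time": "continuous",
             "rin": "continuous", "sex": "categorical", "age": "continuous",
             "lymphocyte_pct": "continuous", "bmi": "continuous"}
    factors = FactorTable(factor_df, types)

    # --- standardized factor scores
    scores = {}
    for name, frac in config.variance_fractions.items():
        if name not in factor_df.columns:
            raise ValueError(f"variance fraction for unknown factor {name!r}")
        col = factor_df[name]
        if types[name] == "categorical":
            levels = pd.unique(col)
            effects = dict(zip(levels, rng.normal(size=len(levels))))
            z = col.map(effects).to_numpy(dtype=float)
        else:
            z = col.to_numpy(dtype=float)
        scores[name] = _standardize(z)
    factor_scores = pd.DataFrame(scores, index=factor_df.index)

    # --- probe layout: strands / exon counts, chrY for sex-linked probes
    n_y = min(config.n_y_probes, p)
    exon_counts, strands, chroms = [], [], []
    for g in range(p):
        if g < n_y:
            exon_counts.append(1); strands.append("+"); chroms.append("chrY")
        else:
            two_exon = rng.random() < config.two_exon_fraction
            minus = rng.random() < config.minus_strand_fraction
            exon_counts.append(2 if two_exon else 1)
            strands.append("-" if minus else "+")
            chroms.append(f"chr{(g % 5) + 1}")
    probe_sequences, transcript_models, probe_truth = generate_sequences(
        transcript_count=p, probes_per_transcript=1,
        probe_length=config.probe_length, seed=int(rng.integers(2 ** 31)),
        exon_counts=exon_counts, strands=strands, chroms=chroms)
    probe_ids = list(probe_truth.index)
    tx_by_id = {t.transcript_id: t for t in transcript_models}

    # --- baselines: expressed vs background; Y probes male-only
    expressed = rng.random(p) < config.expressed_fraction
    expressed[:n_y] = False  # Y probes are background in females
    baseline = np.where(
        expressed,
        rng.uniform(*config.baseline_range, size=p),
        rng.normal(config.background_mean, config.background_sd, size=p),
    )
    y_probe_ids = probe_ids[:n_y]

    # --- log2 signal; background probes get a reduced signal scale
    s = config.signal_log_sd
    frac_total = sum(config.variance_fractions.values())
    resid_frac = np.sqrt(max(0.0, 1.0 - frac_total))
    probe_scale = np.where(expressed, 1.0, config.background_signal_scale) * s
    y = np.tile(baseline[:, None], (1, n)).astype(float)
    for name in factor_scores.columns:
        amp = probe_scale * np.sqrt(config.variance_fractions[name])
        loading = rng.choice([-1.0, 1.0], size=p)
        y += (amp * loading)[:, None] * factor_scores[name].to_numpy()[None, :]
    male = (sex == "male").astype(float)
    y[:n_y, :] += config.sex_effect_size * male[None, :]
    if s > 0:
        y += (resid_frac * probe_scale)[:, None] * rng.normal(size=(p, n))

    # --- genotypes: in-probe SNPs (effect + null) each heading an LD
    #     block whose partners sit upstream of the probe's transcript,
    #     plus independent background SNPs
    # mismatch effects only make sense on expressed, cleanly mapped,
    # forward-strand single-exon probes (a background bead has no
    # hybridizing mRNA whose efficiency a SNP could perturb)
    eligible = [
        pid for i, pid in enumerate(probe_ids)
        if i >= n_y and expressed[i]
        and (m := tx_by_id[probe_truth.loc[pid, "transcript_id"]]).strand == "+"
        and len(m.exons) == 1
    ]
    n_eff = min(config.n_mismatch_probes, len(eligible))
    n_null = min(config.n_null_in_probe_snps, max(0, len(eligible) - n_eff))
    chosen = list(rng.choice(eligible, size=n_eff + n_null, replace=False))
    lo, hi = config.maf_range
    snp_effects: list[PlantedSnpEffect] = []
    variant_rows: list[tuple[Variant, np.ndarray]] = []
    vid = 0
    probe_index = {pid: i for i, pid in enumerate(probe_ids)}
    for k, pid in enumerate(chosen):
        model = tx_by_id[probe_truth.loc[pid, "transcript_id"]]
        off = int(probe_truth.loc[pid, "offset"])
        gstart = model.exons[0][0] + off
        pos_in_probe = int(rng.integers(0, config.probe_length))
        maf = float(rng.uniform(max(lo, 0.1), hi))  # keep planted SNPs common
        block_size = max(2, config.ld_block_size)
        mafs = np.full(block_size, maf)
        mafs[1:] = rng.uniform(lo, hi, size=block_size - 1)
        alleles = _latent_block_alleles(rng, mafs, n, 0.95)
        # member 0 is the in-probe SNP; the rest sit upstream of the TSS
        probe_base = probe_sequences[pid][pos_in_probe]
        alt = str(rng.choice([b for b in "ACGT" if b != probe_base]))
        vid += 1
        v0 = Variant(chrom=model.chrom, pos=gstart + pos_in_probe + 1,
                     ref=probe_base, alt=alt, maf=maf, variant_id=f"rs{vid}",
                     imputation_quality=float(rng.uniform(0.8, 1.0)))
        variant_rows.append((v0, alleles[0]))
        tss0 = model.tss
        for j in range(1, block_size):
            vid += 1
            pos1 = tss0 - 1000 * j  # 0-based, upstream of the + strand TSS
            ref, altb = rng.choice(BASES, size=2, replace=False)
            variant_rows.append((
                Variant(chrom=model.chrom, pos=pos1 + 1, ref=str(ref), alt=str(altb),
                        maf=float(mafs[j]), variant_id=f"rs{vid}",
                        imputation_quality=float(rng.uniform(0.8, 1.0))),
                alleles[j]))
        beta = config.mismatch_effect_size if k < n_eff else 0.0
        # probe carries the ref base, so mismatch dosage = alt dosage
        if beta != 0.0:
            y[probe_index[pid], :] += beta * alleles[0]
        snp_effects.append(PlantedSnpEffect(
            probe_id=pid, variant_id=v0.variant_id, beta=beta, maf=maf,
            position_in_probe=pos_in_probe))

    n_background = max(0, config.n_snps - len(variant_rows))
    if n_background:
        bg = generate_genotypes(
            n, n_background, min(config.ld_block_size, n_background),
            config.maf_range, seed=int(rng.integers(2 ** 31)),
            chrom="chr9", start_pos=10_000_000, spacing=5000,
            sample_ids=sample_ids, id_prefix="bg")
        variant_rows.extend(zip(bg.variants, bg.dosages))
    order = sorted(range(len(variant_rows)),
                   key=lambda i: (variant_rows[i][0].chrom, variant_rows[i][0].pos))
    variants = [variant_rows[i][0] for i in order]
    dosages = np.array([variant_rows[i][1] for i in order])
    genotypes = GenotypeMatrix(variants=variants, dosages=dosages,
                               sample_ids=sample_ids)

    # --- raw intensities with mean-dependent noise
    def to_raw(log2_matrix: np.ndarray) -> np.ndarray:
        x = np.power(2.0, log2_matrix)
        if config.raw_noise_enabled:
            sd = config.noise_c1 * x + config.noise_c2
            x = x + sd * rng.normal(size=x.shape)
        return np.maximum(x, 0.5)

    expr_raw = to_raw(y)
    expression = ExpressionMatrix(
        pd.DataFrame(expr_raw, index=pd.Index(probe_ids, name="probe_id"),
                     columns=sample_ids), scale="raw")

    # --- negative controls: background distribution + the same factor
    #     effects and noise as unexpressed probes
    nc = config.n_negative_controls
    mu_c = rng.normal(config.background_mean, config.background_sd, size=nc)
    yc = np.tile(mu_c[:, None], (1, n))
    s_bg = config.background_signal_scale * s
    for name in factor_scores.columns:
        amp = s_bg * np.sqrt(config.variance_fractions[name])
        loading = rng.choice([-1.0, 1.0], size=nc)
        yc += amp * loading[:, None] * factor_scores[name].to_numpy()[None, :]
    if s_bg > 0:
        yc += resid_frac * s_bg * rng.normal(size=(nc, n))
    controls = pd.DataFrame(to_raw(yc),
                            index=[f"NC{i + 1:04d}" for i in range(nc)],
                            columns=sample_ids)

    truth = StudyTruth(
        variance_fractions=dict(config.variance_fractions),
        factor_scores=factor_scores,
        sex=pd.Series(sex, index=sample_ids, name="sex"),
        baseline=pd.Series(baseline, index=probe_ids, name="baseline"),
        expressed=pd.Series(expressed, index=probe_ids, name="expressed"),
        y_probe_ids=list(y_probe_ids),
        snp_effects=snp_effects,
        noise_c1=config.noise_c1, noise_c2=config.noise_c2,
        signal_log_sd=config.signal_log_sd)

    return SyntheticStudy(
        expression=expression, negative_controls=controls, factors=factors,
        genotypes=genotypes, probe_sequences=probe_sequences,
        transcript_models=transcript_models, probe_truth=probe_truth,
        truth=truth)


# ---------------------------------------------------------------------------
# focused scenario for LD conditioning


@dataclass
class LdScenario:
    """A single probe with an in-probe SNP and an upstream LD partner.

    ``causal`` says which variant drives the probe's expression: the
    in-probe mismatch dosage (a genuine hybridization artifact) or the
    upstream partner (the in-probe SNP is then a pure LD proxy of a
    cis-regulatory variant).
    """

    expression: ExpressionMatrix  # log2 scale
    factors: FactorTable
    genotypes: GenotypeMatrix
    probe_sequences: dict[str, str]
    transcript_models: list[TranscriptModel]
    probe_truth: pd.DataFrame
    probe_id: str
    in_probe_variant: str
    causal_variant: str


def generate_ld_scenario(
    causal: str = "upstream",
    n_samples: int = 400,
    beta: float = -0.5,
    maf: float = 0.3,
    latent_r: float = 0.9,
    noise_sd: float = 0.5,
    n_noise_probes: int = 30,
    n_extra_upstream: int = 4,
    seed: int = 0,
) -> LdScenario:
    """One probe whose in-probe SNP has a high-LD upstream partner.

    ``causal`` is ``"in_probe"`` (true mismatch effect) or ``"upstream"``
    (cis-effect proxy). The partner sits within 100 kb upstream of the
    transcript TSS; extra independent upstream SNPs are added so partner
    selection by top dosage R-squared is exercised.
    """
    if causal not in ("in_probe", "upstream"):
        raise ValueError("causal must be 'in_probe' or 'upstream'")
    rng = np.random.default_rng(seed)
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]

    probe_sequences, models, probe_truth = generate_sequences(
        transcript_count=1, probes_per_transcript=1, probe_length=50,
        seed=int(rng.integers(2 ** 31)), exon_counts=[1], strands=["+"],
        chroms=["chr1"])
    model = models[0]
    probe_id = probe_truth.index[0]
    off = int(probe_truth.loc[probe_id, "offset"])
    gstart = model.exons[0][0] + off

    # in-probe SNP + high-LD partner from a shared latent block
    mafs = np.array([maf, maf])
    pair = _latent_block_alleles(rng, mafs, n_samples, latent_r)
    pos_in_probe = int(rng.integers(0, 50))
    probe_base = probe_sequences[probe_id][pos_in_probe]
    alt = str(rng.choice([b for b in "ACGT" if b != probe_base]))
    tss0 = model.tss
    rows: list[tuple[Variant, np.ndarray]] = [
        (Variant(chrom=model.chrom, pos=gstart + pos_in_probe + 1, ref=probe_base,
                 alt=alt, maf=maf, variant_id="rs_probe"), pair[0]),
        (Variant(chrom=model.chrom, pos=tss0 - 5000 + 1, ref="A", alt="G",
                 maf=maf, variant_id="rs_partner"), pair[1]),
    ]
    for j in range(n_extra_upstream):
        d = rng.binomial(2, rng.uniform(0.1, 0.5), size=n_samples).astype(float)
        rows.append((Variant(chrom=model.chrom, pos=tss0 - 10_000 * (j + 1) + 1,
                             ref="C", alt="T", maf=0.3,
                             variant_id=f"rs_indep{j + 1}"), d))
    rows.sort(key=lambda r: r[0].pos)
    genotypes = GenotypeMatrix(variants=[r[0] for r in rows],
                               dosages=np.array([r[1] for r in rows]),
                               sample_ids=sample_ids)

    driver = pair[0] if causal == "in_probe" else pair[1]
    sex = np.where(rng.random(n_samples) < 0.5, "male", "female")
    age = rng.normal(50, 13, size=n_samples)
    exprs = {probe_id: 10.0 + beta * driver + noise_sd * rng.normal(size=n_samples)}
    for g in range(n_noise_probes):
        exprs[f"NP{g + 1:04d}"] = 8.0 + rng.normal(size=n_samples)
    expression = ExpressionMatrix(
        pd.DataFrame(exprs, index=sample_ids).T, scale="log2")
    factors = FactorTable(
        pd.DataFrame({"sex": sex, "age": age},
                     index=pd.Index(sample_ids, name="sample_id")),
        {"sex": "categorical", "age": "continuous"})
    return LdScenario(
        expression=expression, factors=factors, genotypes=genotypes,
        probe_sequences=probe_sequences, transcript_models=models,
        probe_truth=probe_truth, probe_id=probe_id,
        in_probe_variant="rs_probe",
        causal_variant="rs_probe" if causal == "in_probe" else "rs_partner")
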
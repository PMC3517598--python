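"""In-probe SNP mismatch analysis.

A SNP inside a probe's 50-mer target sequence creates a hybridization
mismatch in carriers of the allele the probe does not match. The scan
restricts to cleanly mapped probes (single mRNA, single exon, forward
strand, coordinates known), pairs each such probe with the SNPs inside
its genomic interval, and regresses the probe's log2 expression on the
per-sample mismatch-allele dosage (adjusted for sex, age and the first
PCs). A one-sided binomial test asks whether decreased-signal effects
outnumber increased-signal ones; a 2x2 chi-square test checks for
accumulation of nominal associations on probes spanning several SNPs;
and an LD-conditioning step refits each nominally significant pair with
the best upstream LD partner as covariate, separating true mismatch
effects from cis-regulatory proxies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import AnnotationRecord
from .containers import ExpressionMatrix, FactorTable, GenotypeMatrix, TranscriptModel, Variant
from .linmod import design_matrix, fit_ols
from .pca import PCADecomposition

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# eligibility and matching


def select_eligible_probes(
    annotations: list[AnnotationRecord],
) -> tuple[list[AnnotationRecord], dict[str, int]]:
    """Probes eligible for the in-probe SNP scan, plus an exclusion tally.

    Eligible: mapping_class unique_mrna, exactly one exon spanned,
    coordinates present, forward strand. The tally counts exclusions by
    first matching reason.
    """
    tally = {"not_unique_mrna": 0, "multi_exon": 0, "missing_coordinates": 0,
             "reverse_strand": 0}
    eligible = []
    for rec in annotations:
        if rec.mapping_class != "unique_mrna":
            tally["not_unique_mrna"] += 1
        elif rec.start is None or rec.end is None:
            tally["missing_coordinates"] += 1
        elif rec.n_exons_spanned != 1:
            tally["multi_exon"] += 1
        elif rec.strand != "+":
            tally["reverse_strand"] += 1
        else:
            eligible.append(rec)
    return eligible, tally


@dataclass
class SnpProbePair:
    """A SNP inside a probe's target sequence.

    ``mismatch_dosage`` is the per-sample count (0-2) of the allele the
    probe does NOT carry: the alt dosage when the probe sequence shows
    the ref base, else 2 - alt dosage.
    """

    probe_id: str
    transcript_id: str
    variant: Variant
    position_in_probe: int  # 0-based from the probe 5' end
    probe_allele: str
    mismatch_allele: str
    mismatch_dosage: np.ndarray
    sample_ids: list[str]


def match_snps_to_probes(
    eligible: list[AnnotationRecord],
    genotypes: GenotypeMatrix,
    probe_sequences: dict[str, str],
) -> tuple[list[SnpProbePair], dict[str, int]]:
    """Pair every SNP with every eligible probe whose interval holds it.

    A variant inside two overlapping probes yields two pairs. Dropped
    (and counted): non-SNP variants (indels, i.e. ref or alt longer
    than one base) and pairs where the probe base matches neither
    allele.
    """
    dropped = {"indel": 0, "allele_mismatch": 0}
    by_chrom: dict[str, list[AnnotationRecord]] = {}
    for rec in eligible:
        if len(probe_sequences[rec.probe_id]) != rec.end - rec.start:
            raise ValueError(
                f"probe {rec.probe_id}: sequence length "
                f"{len(probe_sequences[rec.probe_id])} inconsistent with interval "
                f"[{rec.start}, {rec.end})")
        by_chrom.setdefault(rec.chromosome, []).append(rec)
    pairs: list[SnpProbePair] = []
    for v, dosage in zip(genotypes.variants, genotypes.dosages):
        hosts = [r for r in by_chrom.get(v.chrom, ()) if r.start <= v.pos0 < r.end]
        if not hosts:
            continue
        if len(v.ref) != 1 or len(v.alt) != 1:
            dropped["indel"] += len(hosts)
            continue
        for rec in hosts:
            pos_in_probe = v.pos0 - rec.start  # forward-strand probes only
            probe_base = probe_sequences[rec.probe_id][pos_in_probe].upper()
            if probe_base == v.ref:
                mismatch_allele, mdos = v.alt, dosage.astype(float)
            elif probe_base == v.alt:
                mismatch_allele, mdos = v.ref, 2.0 - dosage
            else:
                dropped["allele_mismatch"] += 1
                continue
            pairs.append(SnpProbePair(
                probe_id=rec.probe_id, transcript_id=rec.transcript_id,
                variant=v, position_in_probe=pos_in_probe,
                probe_allele=probe_base, mismatch_allele=mismatch_allele,
                mismatch_dosage=mdos, sample_ids=list(genotypes.sample_ids)))
    return pairs, dropped


# ---------------------------------------------------------------------------
# association


@dataclass
class MismatchAssociation:
    pair: SnpProbePair
    beta: float   # log2 expression change per mismatch allele
    se: float
    p: float

    @property
    def direction(self) -> str:
        return "negative" if self.beta < 0 else "positive"


def _association_design(
    expression: ExpressionMatrix,
    factors: FactorTable | None,
    covariates: tuple[str, ...],
    pca: PCADecomposition | None,
    n_pcs: int,
) -> pd.DataFrame:
    extra = pca.score_columns(n_pcs) if (pca is not None and n_pcs) else None
    return design_matrix(factors, list(covariates), list(expression.sample_ids),
                         extra=extra)


def test_mismatch_effect(
    expression: ExpressionMatrix,
    pair: SnpProbePair,
    factors: FactorTable | None = None,
    covariates: tuple[str, ...] = ("sex", "age"),
    pca: PCADecomposition | None = None,
    n_pcs: int = 50,
    min_df: int = 8,
) -> MismatchAssociation | None:
    """OLS of the probe's log2 expression on the mismatch dosage.

    Returns None (a skip, not an error) for in-sample monomorphic
    dosages. Raises when the residual degrees of freedom fall below
    ``min_df``.
    """
    if expression.scale == "raw":
        raise ValueError("mismatch test expects log2- or vst-scale expression")
    if pair.probe_id not in expression.probe_ids:
        raise KeyError(f"probe {pair.probe_id} absent from expression matrix")
    dos = pd.Series(pair.mismatch_dosage, index=pair.sample_ids)
    dos = dos.loc[expression.sample_ids]
    if float(dos.std()) == 0.0:
        logger.info("skipping monomorphic pair %s/%s", pair.probe_id,
                    pair.variant.variant_id)
        return None
    X = _association_design(expression, factors, covariates, pca, n_pcs)
    X.insert(1, "mismatch_dosage", dos.to_numpy())
    n, p = X.shape
    if n - p < min_df:
        raise ValueError(
            f"{n - p} residual degrees of freedom (< {min_df}); reduce the "
            f"covariate set or supply more samples")
    y = expression.values.loc[[pair.probe_id]].T
    fit = fit_ols(X, y)
    return MismatchAssociation(
        pair=pair,
        beta=float(fit.coef.loc["mismatch_dosage"].iloc[0]),
        se=float(fit.se.loc["mismatch_dosage"].iloc[0]),
        p=float(fit.pvalues.loc["mismatch_dosage"].iloc[0]))


def run_association_scan(
    expression: ExpressionMatrix,
    pairs: list[SnpProbePair],
    factors: FactorTable | None = None,
    covariates: tuple[str, ...] = ("sex", "age"),
    pca: PCADecomposition | None = None,
    n_pcs: int = 50,
) -> tuple[list[MismatchAssociation], int]:
    """Run the mismatch test for every pair; returns (results, n_skipped)."""
    out, skipped = [], 0
    for pair in pairs:
        res = test_mismatch_effect(expression, pair, factors, covariates, pca, n_pcs)
        if res is None:
            skipped += 1
        else:
            out.append(res)
    return out, skipped


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def direction_binomial_test(
    associations: list[MismatchAssociation],
    filter: str = "all",
    alpha: float = 0.05,
    n_tests: int | None = None,
) -> tuple[int, int, float]:
    """One-sided binomial test of the excess of negative directions.

    ``filter`` keeps all associations, the nominal p < 0.05 subset, or
    the Bonferroni-significant subset (threshold alpha/n_tests with
    n_tests the number of completed tests). Returns
    (n_negative, n_positive, one-sided p for #negative > half).
    """
    n_tests = n_tests if n_tests is not None else len(associations)
    if filter == "all":
        kept = associations
    elif filter == "nominal_0.05":
        kept = [a for a in associations if a.p < 0.05]
    elif filter == "bonferroni":
        thr = bonferroni_threshold(n_tests, alpha)
        kept = [a for a in associations if a.p < thr]
    else:
        raise ValueError(f"unknown filter {filter!r}")
    if not kept:
        raise ValueError(f"no associations pass filter {filter!r}")
    n_neg = sum(1 for a in kept if a.direction == "negative")
    n_pos = len(kept) - n_neg
    p = stats.binomtest(n_neg, len(kept), 0.5, alternative="greater").pvalue
    return n_neg, n_pos, float(p)


def multi_snp_accumulation_test(
    associations: list[MismatchAssociation],
    pairs: list[SnpProbePair],
    min_snps: int = 3,
    alpha: float = 0.05,
) -> tuple[float, float, np.ndarray]:
    """2x2 chi-square: nominal significance vs probe SNP burden.

    Rows: association p < alpha yes/no; columns: host probe carries
    >= min_snps SNPs yes/no (counted over attempted pairs). One unit
    per association test; no continuity correction. Returns
    (statistic, p, table).
    """
    snps_per_probe: dict[str, int] = {}
    for p_ in pairs:
        snps_per_probe[p_.probe_id] = snps_per_probe.get(p_.probe_id, 0) + 1
    table = np.zeros((2, 2))
    for a in associations:
        i = 0 if a.p < alpha else 1
        j = 0 if snps_per_probe.get(a.pair.probe_id, 0) >= min_snps else 1
        table[i, j] += 1
    if table[:, 0].sum() == 0:
        raise ValueError(f"no associations on probes with >= {min_snps} SNPs")
    if table[:, 1].sum() == 0:
        raise ValueError(f"no associations on probes with < {min_snps} SNPs")
    n = table.sum()
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / n
    if (expected == 0).any() or table[0].sum() == 0:
        return 0.0, 1.0, table
    chi2 = float(((table - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, 1))
    return chi2, p, table


# ---------------------------------------------------------------------------
# LD conditioning


@dataclass
class ConditioningOutcome:
    probe_id: str
    variant_id: str
    partner_id: str | None
    partner_r2: float | None
    p_unconditional: float
    p_conditional: float | None
    p_increased: bool | None


def _dosage_r2(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def ld_conditioning(
    associations: list[MismatchAssociation],
    expression: ExpressionMatrix,
    genotypes: GenotypeMatrix,
    models: dict[str, TranscriptModel],
    factors: FactorTable | None = None,
    covariates: tuple[str, ...] = ("sex", "age"),
    pca: PCADecomposition | None = None,
    n_pcs: int = 50,
    window: int = 100_000,
    r2_thresholds: tuple[float, float] = (0.1, 0.5),
    alpha: float = 0.05,
    n_tests: int | None = None,
) -> tuple[list[ConditioningOutcome], dict]:
    """Refit nominally significant pairs conditional on the top LD partner.

    For each association with p < alpha, candidate partners are the
    variants within ``window`` bp upstream of the probe's transcript TSS
    (strand-aware: positions below the TSS for plus-strand transcripts,
    above it for minus-strand). Dosage R-squared (squared Pearson
    correlation) is computed against the in-probe SNP; the partner with
    the highest R-squared above the lower threshold is added to the
    association model as a covariate and the mismatch-dosage p-value is
    re-read. The summary reports partner counts at both thresholds, the
    fraction of conditioned pairs whose p increased, and how many
    Bonferroni-significant pairs stay significant.
    """
    lo_thr, hi_thr = r2_thresholds
    n_tests = n_tests if n_tests is not None else len(associations)
    bonf = bonferroni_threshold(n_tests, alpha)
    sample_index = {s: i for i, s in enumerate(genotypes.sample_ids)}
    order = [sample_index[s] for s in expression.sample_ids]
    outcomes: list[ConditioningOutcome] = []
    n_lo = n_hi = 0
    for a in associations:
        if a.p >= alpha:
            continue
        pair = a.pair
        model = models[pair.transcript_id]
        tss = model.tss
        if model.strand == "+":
            lo_pos, hi_pos = tss - window, tss
        else:
            lo_pos, hi_pos = tss + 1, tss + window + 1
        own_dos = pair.mismatch_dosage  # genotype sample order by construction
        best_r2, best_idx = 0.0, None
        any_lo = any_hi = False
        for idx, v in enumerate(genotypes.variants):
            if v.chrom != model.chrom or not (lo_pos <= v.pos0 < hi_pos):
                continue
            if v.chrom == pair.variant.chrom and v.pos == pair.variant.pos:
                continue
            r2 = _dosage_r2(own_dos, genotypes.dosages[idx])
            any_lo |= r2 > lo_thr
            any_hi |= r2 > hi_thr
            if r2 > best_r2:
                best_r2, best_idx = r2, idx
        n_lo += int(any_lo)
        n_hi += int(any_hi)
        if best_idx is None or best_r2 <= lo_thr:
            outcomes.append(ConditioningOutcome(
                probe_id=pair.probe_id, variant_id=pair.variant.variant_id,
                partner_id=None, partner_r2=None, p_unconditional=a.p,
                p_conditional=None, p_increased=None))
            continue
        partner = genotypes.variants[best_idx]
        partner_dos = pd.DataFrame(
            {"partner_dosage": genotypes.dosages[best_idx][order]},
            index=expression.sample_ids)
        X = _association_design(expression, factors, covariates, pca, n_pcs)
        X.insert(1, "mismatch_dosage",
                 pd.Series(pair.mismatch_dosage, index=pair.sample_ids)
                 .loc[expression.sample_ids].to_numpy())
        X["partner_dosage"] = partner_dos["partner_dosage"]
        y = expression.values.loc[[pair.probe_id]].T
        fit = fit_ols(X, y)
        p_cond = float(fit.pvalues.loc["mismatch_dosage"].iloc[0])
        outcomes.append(ConditioningOutcome(
            probe_id=pair.probe_id, variant_id=pair.variant.variant_id,
            partner_id=partner.variant_id, partner_r2=best_r2,
            p_unconditional=a.p, p_conditional=p_cond,
            p_increased=p_cond > a.p))
    conditioned = [o for o in outcomes if o.p_conditional is not None]
    n_increased = sum(1 for o in conditioned if o.p_increased)
    sig_before = [o for o in outcomes if o.p_unconditional < bonf]
    sig_after = [o for o in sig_before
                 if (o.p_conditional if o.p_conditional is not None
                     else o.p_unconditional) < bonf]
    summary = {
        "n_considered": len(outcomes),
        f"n_partner_r2_gt_{lo_thr}": n_lo,
        f"n_partner_r2_gt_{hi_thr}": n_hi,
        "n_conditioned": len(conditioned),
        "frac_p_increased": n_increased / len(conditioned) if conditioned else float("nan"),
        "bonferroni_threshold": bonf,
        "n_bonferroni_significant": len(sig_before),
        "n_remaining_significant": len(sig_after),
    }
    return outcomes, summary
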
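"""Eligibility filtering, SNP-probe matching, the mismatch-dosage
association, direction/accumulation tests and LD conditioning."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from beadvar.annotate import AnnotationRecord, annotate_all
from beadvar.containers import ExpressionMatrix, FactorTable, GenotypeMatrix, Variant
from beadvar.pca import compute_pca
from beadvar.preprocess import log2_transform
from beadvar.simulate import SimulationConfig, generate_ld_scenario, generate_study
from beadvar.snpinprobe import (
    MismatchAssociation,
    SnpProbePair,
    bonferroni_threshold,
    direction_binomial_test,
    ld_conditioning,
    match_snps_to_probes,
    multi_snp_accumulation_test,
    run_association_scan,
    select_eligible_probes,
    test_mismatch_effect as mismatch_effect_test,
)
from conftest import ols_oracle


def rec(pid, cls="unique_mrna", strand="+", n_ex=1, start=1000, end=1050,
        tid="t1", chrom="chr1"):
    return AnnotationRecord(probe_id=pid, mapping_class=cls, transcript_id=tid,
                            gene_id="g1", chromosome=chrom, strand=strand,
                            start=start, end=end, n_exons_spanned=n_ex,
                            offset_in_transcript=0)


class TestEligibility:
    def test_one_probe_per_exclusion_reason(self):
        records = [
            rec("ok"),
            AnnotationRecord(probe_id="amb", mapping_class="ambiguous"),
            rec("multi", n_ex=2),
            rec("minus", strand="-"),
            AnnotationRecord(probe_id="nocoord", mapping_class="unique_mrna",
                             strand="+"),
        ]
        eligible, tally = select_eligible_probes(records)
        assert [r.probe_id for r in eligible] == ["ok"]
        assert tally == {"not_unique_mrna": 1, "multi_exon": 1,
                         "missing_coordinates": 1, "reverse_strand": 1}

    def test_clean_input_has_empty_tally(self):
        eligible, tally = select_eligible_probes([rec(f"p{i}") for i in range(4)])
        assert len(eligible) == 4 and sum(tally.values()) == 0

    def test_reverse_strand_excluded_even_if_single_exon(self):
        _, tally = select_eligible_probes([rec("m", strand="-", n_ex=1)])
        assert tally["reverse_strand"] == 1


def geno(variants, dosages, n=4):
    return GenotypeMatrix(variants=variants, dosages=np.asarray(dosages, float),
                          sample_ids=[f"s{i}" for i in range(n)])


class TestMatching:
    SEQ = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTAC"  # 50-mer

    def test_snp_at_probe_start_has_position_zero(self):
        g = geno([Variant("chr1", 1001, "A", "G")], [[0, 1, 2, 0]])
        pairs, dropped = match_snps_to_probes([rec("p")], g, {"p": self.SEQ})
        assert pairs[0].position_in_probe == 0

    def test_probe_base_ref_means_mismatch_is_alt(self):
        g = geno([Variant("chr1", 1004, "T", "G")], [[0, 1, 2, 0]])  # probe base T
        pairs, _ = match_snps_to_probes([rec("p")], g, {"p": self.SEQ})
        p = pairs[0]
        assert p.probe_allele == "T" and p.mismatch_allele == "G"
        assert np.allclose(p.mismatch_dosage, [0, 1, 2, 0])

    def test_probe_base_alt_flips_dosage(self):
        g = geno([Variant("chr1", 1003, "T", "G")], [[0, 1, 2, 0]])  # probe base G = alt
        pairs, _ = match_snps_to_probes([rec("p")], g, {"p": self.SEQ})
        p = pairs[0]
        assert p.mismatch_allele == "T"
        assert np.allclose(p.mismatch_dosage, [2, 1, 0, 2])

    def test_neither_allele_matching_is_dropped_and_counted(self):
        g = geno([Variant("chr1", 1003, "C", "A")], [[0, 1, 2, 0]])  # probe base G
        pairs, dropped = match_snps_to_probes([rec("p")], g, {"p": self.SEQ})
        assert pairs == [] and dropped["allele_mismatch"] == 1

    def test_indels_excluded(self):
        g = geno([Variant("chr1", 1003, "TA", "T")], [[0, 1, 2, 0]])
        pairs, dropped = match_snps_to_probes([rec("p")], g, {"p": self.SEQ})
        assert pairs == [] and dropped["indel"] == 1

    def test_variant_in_two_overlapping_probes_yields_two_pairs(self):
        recs = [rec("p1", start=1000, end=1050),
                rec("p2", start=1030, end=1080, tid="t2")]
        g = geno([Variant("chr1", 1041, "A", "G")], [[0, 1, 2, 0]])
        seqs = {"p1": self.SEQ, "p2": self.SEQ}
        pairs, _ = match_snps_to_probes(recs, g, seqs)
        assert {p.probe_id for p in pairs} == {"p1", "p2"}
        assert [p.position_in_probe for p in pairs] == [40, 10]

    def test_allele_bookkeeping_invariant(self, default_study):
        recs, _ = annotate_all(default_study.probe_sequences,
                               default_study.transcript_models)
        eligible, _ = select_eligible_probes(recs)
        pairs, _ = match_snps_to_probes(eligible, default_study.genotypes,
                                        default_study.probe_sequences)
        assert pairs, "default study must contain in-probe SNPs"
        by_id = {(v.chrom, v.pos): d for v, d in
                 zip(default_study.genotypes.variants, default_study.genotypes.dosages)}
        for p in pairs:
            alt_dos = by_id[(p.variant.chrom, p.variant.pos)]
            probe_allele_dos = alt_dos if p.probe_allele == p.variant.alt \
                else 2.0 - alt_dos
            assert np.allclose(p.mismatch_dosage + probe_allele_dos, 2.0)

    def test_sequence_interval_mismatch_rejected(self):
        g = geno([Variant("chr1", 1003, "T", "G")], [[0, 1, 2, 0]])
        with pytest.raises(ValueError, match="inconsistent"):
            match_snps_to_probes([rec("p", end=1060)], g, {"p": self.SEQ})


class TestMismatchEffect:
    def test_planted_effect_recovered_at_n500(self):
        st = generate_study(SimulationConfig(
            seed=50, n_samples=504, n_probes=300, n_mismatch_probes=8,
            n_null_in_probe_snps=0, mismatch_effect_size=-0.5,
            maf_range=(0.3, 0.3), n_snps=30, n_y_probes=5, n_negative_controls=30))
        recs, _ = annotate_all(st.probe_sequences, st.transcript_models)
        eligible, _ = select_eligible_probes(recs)
        pairs, _ = match_snps_to_probes(eligible, st.genotypes, st.probe_sequences)
        l2 = log2_transform(st.expression)
        pca = compute_pca(l2, "probe")
        planted = {e.probe_id for e in st.truth.snp_effects if e.beta != 0}
        # 10 PC covariates: enough to soak up the planted technical
        # variance at this panel size without absorbing the SNP effect
        # itself (many data-derived PCs shrink true effects toward zero)
        assoc, _ = run_association_scan(l2, pairs, st.factors, ("sex", "age"),
                                        pca, n_pcs=10)
        betas = [a.beta for a in assoc if a.pair.probe_id in planted]
        assert len(betas) == 8
        assert all(abs(b - (-0.5)) < 0.1 for b in betas)

    def test_monomorphic_dosage_is_skipped_not_error(self):
        ids = [f"s{i}" for i in range(80)]
        r = np.random.default_rng(1)
        e = ExpressionMatrix(pd.DataFrame(r.normal(size=(3, 80)),
                                          index=["p", "q", "z"], columns=ids),
                             scale="log2")
        pair = SnpProbePair(probe_id="p", transcript_id="t",
                            variant=Variant("chr1", 10, "A", "G"),
                            position_in_probe=0, probe_allele="A",
                            mismatch_allele="G",
                            mismatch_dosage=np.zeros(80), sample_ids=ids)
        assert mismatch_effect_test(e, pair) is None

    def test_matches_ols_oracle_on_toy(self):
        n = 70
        r = np.random.default_rng(9)
        ids = [f"s{i}" for i in range(n)]
        dos = r.binomial(2, 0.4, size=n).astype(float)
        age = r.normal(50, 10, size=n)
        sex = r.choice(["male", "female"], size=n)
        y = 8 - 0.4 * dos + 0.02 * age + r.normal(size=n)
        e = ExpressionMatrix(pd.DataFrame(y[None, :], index=["p"], columns=ids),
                             scale="log2")
        factors = FactorTable(pd.DataFrame({"sex": sex, "age": age}, index=ids),
                              {"sex": "categorical", "age": "continuous"})
        pair = SnpProbePair(probe_id="p", transcript_id="t",
                            variant=Variant("chr1", 10, "A", "G"),
                            position_in_probe=0, probe_allele="A",
                            mismatch_allele="G", mismatch_dosage=dos,
                            sample_ids=ids)
        res = mismatch_effect_test(e, pair, factors, ("sex", "age"), None, 0)
        X = np.column_stack([np.ones(n), dos, (sex == "male").astype(float), age])
        beta, se, p = ols_oracle(X, y)
        assert res.beta == pytest.approx(beta[1], abs=1e-8)
        assert res.se == pytest.approx(se[1], abs=1e-8)
        assert res.p == pytest.approx(p[1], abs=1e-8)

    def test_df_guard(self):
        ids = [f"s{i}" for i in range(12)]
        r = np.random.default_rng(2)
        e = ExpressionMatrix(pd.DataFrame(r.normal(size=(60, 12)),
                                          index=[f"p{i}" for i in range(60)],
                                          columns=ids), scale="log2")
        pca = compute_pca(e, "probe")
        pair = SnpProbePair(probe_id="p0", transcript_id="t",
                            variant=Variant("chr1", 10, "A", "G"),
                            position_in_probe=0, probe_allele="A",
                            mismatch_allele="G",
                            mismatch_dosage=r.binomial(2, .5, 12).astype(float),
                            sample_ids=ids)
        with pytest.raises(ValueError, match="degrees of freedom"):
            mismatch_effect_test(e, pair, None, (), pca, n_pcs=10)


def fake_assoc(probe_id, beta, p):
    pair = SnpProbePair(probe_id=probe_id, transcript_id="t",
                        variant=Variant("chr1", 1, "A", "G", variant_id=probe_id),
                        position_in_probe=0, probe_allele="A", mismatch_allele="G",
                        mismatch_dosage=np.array([0.0, 1.0]), sample_ids=["a", "b"])
    return MismatchAssociation(pair=pair, beta=beta, se=1.0, p=p)


class TestDirectionBinomial:
    def test_all_negative_closed_form(self):
        assoc = [fake_assoc(f"p{i}", -1.0, 0.5) for i in range(10)]
        n_neg, n_pos, p = direction_binomial_test(assoc)
        assert (n_neg, n_pos) == (10, 0)
        assert p == pytest.approx(2.0 ** -10)

    def test_balanced_split_is_null(self):
        assoc = [fake_assoc(f"p{i}", -1.0, 0.5) for i in range(5)] + \
                [fake_assoc(f"q{i}", 1.0, 0.5) for i in range(5)]
        _, _, p = direction_binomial_test(assoc)
        assert p > 0.5

    def test_matches_tail_sum_oracle(self):
        assoc = [fake_assoc(f"p{i}", -1.0, 0.5) for i in range(110)] + \
                [fake_assoc(f"q{i}", 1.0, 0.5) for i in range(90)]
        _, _, p = direction_binomial_test(assoc)
        oracle = sum(stats.binom.pmf(k, 200, 0.5) for k in range(110, 201))
        assert p == pytest.approx(oracle, rel=1e-10)

    def test_filters(self):
        assoc = [fake_assoc("a", -1, 0.03), fake_assoc("b", -1, 0.2),
                 fake_assoc("c", 1, 1e-9)]
        n_neg, n_pos, _ = direction_binomial_test(assoc, "nominal_0.05")
        assert (n_neg, n_pos) == (1, 1)
        n_neg, n_pos, _ = direction_binomial_test(assoc, "bonferroni")
        assert (n_neg, n_pos) == (0, 1)  # 0.05/3 = 0.017; only 1e-9 passes
        with pytest.raises(ValueError, match="unknown filter"):
            direction_binomial_test(assoc, "fdr")


class TestBonferroni:
    def test_printed_thresholds(self):
        assert float(f"{bonferroni_threshold(2148):.1e}") == 2.3e-5
        assert float(f"{bonferroni_threshold(66):.1e}") == 7.6e-4
        assert bonferroni_threshold(1) == 0.05


class TestAccumulation:
    @staticmethod
    def build(counts_sig, counts_nonsig, snps_per_probe):
        """counts are per-stratum (>=3 SNPs, <3 SNPs) association counts."""
        assoc, pairs, idx = [], [], 0
        for stratum, (n_sig, n_non) in enumerate(zip(counts_sig, counts_nonsig)):
            nsnp = 3 if stratum == 0 else 1
            for k in range(n_sig + n_non):
                idx += 1
                pid = f"pr{idx}"
                p = 0.01 if k < n_sig else 0.5
                assoc.append(fake_assoc(pid, -1.0, p))
                for j in range(nsnp):
                    pairs.append(fake_assoc(pid, 0, 1).pair)
        return assoc, pairs

    def test_identical_proportions_give_zero_statistic(self):
        assoc, pairs = self.build([10, 10], [90, 90], None)
        chi2, p, table = multi_snp_accumulation_test(assoc, pairs)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_table(self):
        assoc, pairs = self.build([10, 20], [90, 80], None)
        chi2, p, table = multi_snp_accumulation_test(assoc, pairs)
        t = np.array([[10, 20], [90, 80]], float)
        n = t.sum()
        expected = t.sum(1, keepdims=True) @ t.sum(0, keepdims=True) / n
        oracle = ((t - expected) ** 2 / expected).sum()
        assert chi2 == pytest.approx(oracle)
        assert p == pytest.approx(stats.chi2.sf(oracle, 1))

    def test_empty_stratum_rejected(self):
        assoc, pairs = self.build([10, 0], [90, 0], None)
        with pytest.raises(ValueError, match="< 3 SNPs"):
            multi_snp_accumulation_test(assoc, pairs)

    def test_type_i_rate_calibrated(self):
        r = np.random.default_rng(2024)
        rejections = 0
        n_seeds = 500
        for _ in range(n_seeds):
            p_multi = r.uniform(size=40)
            p_single = r.uniform(size=120)
            assoc = [fake_assoc(f"m{i}", -1, p) for i, p in enumerate(p_multi)] + \
                    [fake_assoc(f"s{i}", -1, p) for i, p in enumerate(p_single)]
            pairs = []
            for i in range(40):
                pairs.extend(fake_assoc(f"m{i}", 0, 1).pair for _ in range(3))
            pairs += [fake_assoc(f"s{i}", 0, 1).pair for i in range(120)]
            _, p, _ = multi_snp_accumulation_test(assoc, pairs)
            rejections += p < 0.05
        ci = stats.binomtest(rejections, n_seeds, 0.05).proportion_ci(0.999)
        assert ci.low <= 0.05 <= ci.high


class TestLdConditioning:
    def test_partner_r2_matches_closed_form_on_toy(self):
        a = np.array([0.0, 1.0, 2.0, 1.0])
        b = np.array([0.0, 2.0, 2.0, 0.0])
        from beadvar.snpinprobe import _dosage_r2

        assert _dosage_r2(a, b) == pytest.approx(np.corrcoef(a, b)[0, 1] ** 2)

    @staticmethod
    def run_scenario(causal, seed):
        sc = generate_ld_scenario(causal=causal, seed=seed)
        recs, _ = annotate_all(sc.probe_sequences, sc.transcript_models)
        eligible, _ = select_eligible_probes(recs)
        pairs, _ = match_snps_to_probes(eligible, sc.genotypes, sc.probe_sequences)
        pca = compute_pca(sc.expression, "probe")
        assoc, _ = run_association_scan(sc.expression, pairs, sc.factors,
                                        ("sex", "age"), pca, n_pcs=5)
        models = {m.transcript_id: m for m in sc.transcript_models}
        outcomes, summary = ld_conditioning(
            assoc, sc.expression, sc.genotypes, models, sc.factors,
            ("sex", "age"), pca, 5, n_tests=len(assoc))
        return outcomes[0], summary

    def test_ld_proxy_loses_significance(self):
        lost = increased = 0
        reps = 15
        for seed in range(reps):
            o, s = self.run_scenario("upstream", seed)
            bonf = s["bonferroni_threshold"]
            assert o.partner_id == "rs_partner"
            increased += bool(o.p_increased)
            lost += o.p_unconditional < bonf and o.p_conditional >= bonf
        assert increased >= 0.9 * reps
        assert lost >= 0.9 * reps

    def test_true_mismatch_effect_survives_conditioning(self):
        retained = 0
        reps = 15
        for seed in range(reps):
            o, s = self.run_scenario("in_probe", seed)
            retained += o.p_unconditional < s["bonferroni_threshold"] and \
                o.p_conditional < s["bonferroni_threshold"]
        assert retained >= 0.9 * reps

    def test_no_partner_above_threshold_recorded_as_absent(self):
        sc = generate_ld_scenario(causal="in_probe", seed=3, latent_r=0.0,
                                  n_extra_upstream=0)
        recs, _ = annotate_all(sc.probe_sequences, sc.transcript_models)
        eligible, _ = select_eligible_probes(recs)
        pairs, _ = match_snps_to_probes(eligible, sc.genotypes, sc.probe_sequences)
        pca = compute_pca(sc.expression, "probe")
        assoc, _ = run_association_scan(sc.expression, pairs, sc.factors,
                                        ("sex", "age"), pca, n_pcs=5)
        models = {m.transcript_id: m for m in sc.transcript_models}
        outcomes, _ = ld_conditioning(assoc, sc.expression, sc.genotypes, models,
                                      sc.factors, ("sex", "age"), pca, 5,
                                      n_tests=len(assoc))
        o = outcomes[0]
        if o.partner_id is None:
            assert o.p_conditional is None and o.p_increased is None


class TestGlobalNull:
    def test_direction_proportion_and_bonferroni_over_seeds(self):
        neg = pos = 0
        clean = 0
        n_seeds = 25
        for seed in range(n_seeds):
            st = generate_study(SimulationConfig(
                seed=1000 + seed, n_samples=96, n_probes=200, n_mismatch_probes=0,
                n_null_in_probe_snps=12, n_snps=40, n_y_probes=5,
                n_negative_controls=30))
            recs, _ = annotate_all(st.probe_sequences, st.transcript_models)
            eligible, _ = select_eligible_probes(recs)
            pairs, _ = match_snps_to_probes(eligible, st.genotypes,
                                            st.probe_sequences)
            l2 = log2_transform(st.expression)
            pca = compute_pca(l2, "probe")
            assoc, _ = run_association_scan(l2, pairs, st.factors, ("sex", "age"),
                                            pca, n_pcs=50)
            thr = bonferroni_threshold(len(assoc))
            clean += not any(a.p < thr for a in assoc)
            neg += sum(a.direction == "negative" for a in assoc)
            pos += sum(a.direction == "positive" for a in assoc)
        ci = stats.binomtest(neg, neg + pos, 0.5).proportion_ci(0.95)
        assert ci.low <= 0.5 <= ci.high
        assert clean >= 0.9 * n_seeds
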
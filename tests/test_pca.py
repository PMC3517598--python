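"""PCA decomposition, Eigen-R-squared attribution, PC-factor scanning
and technical-effect removal."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from beadvar.containers import ExpressionMatrix, FactorTable
from beadvar.pca import (
    PCADecomposition,
    compute_pca,
    eigen_r2,
    pc_factor_scan,
    remove_technical_effects,
    variance_explained,
)
from beadvar.preprocess import log2_transform
from beadvar.simulate import SimulationConfig, generate_study


def expr(arr, scale="log2"):
    arr = np.asarray(arr, dtype=float)
    return ExpressionMatrix(
        pd.DataFrame(arr, index=[f"p{i}" for i in range(arr.shape[0])],
                     columns=[f"s{j}" for j in range(arr.shape[1])]), scale=scale)


@pytest.fixture(scope="module")
def l2(default_study):
    return log2_transform(default_study.expression)


@pytest.fixture(scope="module")
def pca_centered(l2):
    return compute_pca(l2, "probe")


class TestComputePca:
    def test_matches_dense_eigendecomposition_on_toy(self, rng):
        x = rng.normal(size=(5, 4))  # 5 probes x 4 samples
        e = expr(x)
        pca = compute_pca(e, "probe")
        xc = x.T - x.T.mean(axis=0)
        cov = xc @ xc.T / (xc.shape[0] - 1)  # sample-space Gram, same spectrum
        ev = np.sort(np.linalg.eigvalsh(cov))[::-1][: len(pca.eigenvalues)]
        assert np.allclose(pca.eigenvalues, ev, atol=1e-10)

    def test_two_samples_probe_centered_has_rank_one(self, rng):
        e = expr(rng.normal(size=(10, 2)))
        pca = compute_pca(e, "probe")
        assert pca.eigenvalues[0] > 1e-8
        assert np.all(pca.eigenvalues[1:] < 1e-10)

    def test_variance_fractions_sum_to_one(self, pca_centered):
        assert pca_centered.variance_fractions.sum() == pytest.approx(1.0)

    def test_scores_orthogonal(self, pca_centered):
        s = pca_centered.scores.to_numpy()[:, :20]
        g = s.T @ s
        off = g - np.diag(np.diag(g))
        assert np.abs(off).max() < 1e-6 * np.abs(np.diag(g)).max()

    def test_sign_convention_deterministic(self, l2):
        a = compute_pca(l2, "probe").scores
        b = compute_pca(l2, "probe").scores
        assert a.equals(b)
        for k in range(5):
            col = a.iloc[:, k].to_numpy()
            assert col[np.abs(col).argmax()] > 0

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            compute_pca(expr(np.full((5, 5), 3.0)))


class TestVarianceExplained:
    def test_full_rank_reaches_one(self, pca_centered):
        assert variance_explained(pca_centered, pca_centered.n_components) == \
            pytest.approx(1.0)

    def test_monotone_in_k(self, pca_centered):
        vals = [variance_explained(pca_centered, k) for k in range(1, 30)]
        assert (np.diff(vals) >= -1e-12).all()

    def test_k_out_of_range(self, pca_centered):
        with pytest.raises(ValueError):
            variance_explained(pca_centered, 0)

    def test_uncentered_pca_dominated_by_shared_mean_profile(self, l2):
        pca = compute_pca(l2, "none")
        assert variance_explained(pca, 1) > 0.9


class TestEigenR2:
    def test_factor_equal_to_first_score_recovers_its_fraction(self, pca_centered):
        fac = pca_centered.scores["PC1"].rename("fac")
        res = eigen_r2(pca_centered, fac, "continuous")
        assert res.eigen_r2 == pytest.approx(float(pca_centered.variance_fractions[0]),
                                             abs=1e-6)

    def test_permuted_factor_near_zero(self, pca_centered, default_study, rng):
        # low-df null factors: permuted binary and random continuous
        fac = default_study.factors.column("sex").sample(frac=1.0, random_state=1)
        fac.index = default_study.factors.sample_ids  # break the alignment
        assert eigen_r2(pca_centered, fac, "categorical").eigen_r2 < 0.02
        cont = pd.Series(rng.normal(size=len(fac)), index=fac.index, name="z")
        assert eigen_r2(pca_centered, cont, "continuous").eigen_r2 < 0.02
        # many-level categoricals carry a positive floor-at-zero bias that
        # grows with the dummy count; it must stay well below a real signal
        chip = default_study.factors.column("chip").sample(frac=1.0, random_state=1)
        chip.index = default_study.factors.sample_ids
        assert eigen_r2(pca_centered, chip, "categorical").eigen_r2 < 0.08

    def test_chip_fraction_recovered(self, chip_only_study):
        from beadvar.preprocess import detection_pvalues, filter_probes_by_detection

        st = chip_only_study
        det = detection_pvalues(st.expression, st.negative_controls)
        kept, _ = filter_probes_by_detection(st.expression, det)
        pca = compute_pca(log2_transform(kept), "probe")
        res = eigen_r2(pca, st.factors.column("chip"), "categorical")
        assert abs(res.eigen_r2 - 0.30) < 0.05

    def test_weighted_sum_identity(self, pca_centered, default_study):
        res = eigen_r2(pca_centered, default_study.factors.column("storage_time"),
                       "continuous")
        recomputed = float((res.per_component["r2"] * res.per_component["weight"]).sum())
        assert res.eigen_r2 == pytest.approx(recomputed)
        assert 0.0 <= res.eigen_r2 <= 1.0

    def test_degenerate_factors_rejected(self, pca_centered):
        n = len(pca_centered.scores)
        const = pd.Series(["a"] * n, index=pca_centered.scores.index, name="f")
        with pytest.raises(ValueError, match="single level"):
            eigen_r2(pca_centered, const, "categorical")
        saturated = pd.Series([str(i) for i in range(n)],
                              index=pca_centered.scores.index, name="f")
        with pytest.raises(ValueError, match="saturated"):
            eigen_r2(pca_centered, saturated, "categorical")


class TestPcFactorScan:
    def test_bonferroni_threshold_for_66_factors(self, pca_centered, default_study):
        # the scan attaches 0.05/n_factors; at 66 factors this rounds to 7.6e-4
        scan = pc_factor_scan(pca_centered, default_study.factors, n_pcs=5)
        assert scan.bonferroni_threshold == pytest.approx(
            0.05 / len(default_study.factors.factor_names))
        assert float(f"{0.05 / 66:.1e}") == 7.6e-4

    def test_factor_equal_to_score_gives_argmin_at_that_pc(self, pca_centered,
                                                           default_study):
        fac = pca_centered.scores["PC3"].rename("fac3")
        table = default_study.factors.table.copy()
        table["fac3"] = fac
        types = dict(default_study.factors.types, fac3="continuous")
        scan = pc_factor_scan(pca_centered, FactorTable(table, types), n_pcs=10)
        assert scan.best_component.loc["fac3"] == 3
        assert scan.pvalues.loc["fac3", "PC3"] <= scan.pvalues.loc["fac3"].min()

    def test_type_i_error_calibrated_for_random_factor(self, rng):
        e = expr(rng.normal(size=(80, 60)))
        pca = compute_pca(e, "probe")
        reps, n_pcs = 40, 50
        pvals = []
        for _ in range(reps):
            fac = pd.Series(rng.normal(size=60), index=pca.scores.index, name="z")
            scan = pc_factor_scan(
                pca, FactorTable(fac.to_frame(), {"z": "continuous"}), n_pcs=n_pcs)
            pvals.extend(scan.pvalues.loc["z"].tolist())
        rate = np.mean(np.asarray(pvals) < 0.05)
        n = reps * n_pcs
        ci = stats.binomtest(int(rate * n), n, 0.05).proportion_ci(0.999)
        assert ci.low <= 0.05 <= ci.high

    def test_n_pcs_bounded(self, pca_centered, default_study):
        with pytest.raises(ValueError, match="n_pcs"):
            pc_factor_scan(pca_centered, default_study.factors, n_pcs=10_000)


class TestRemoveTechnicalEffects:
    TECH = ["chip", "amplification_plate", "isolation_plate", "storage_time"]

    def test_residuals_orthogonal_to_design(self, l2, default_study):
        from beadvar.linmod import design_matrix, drop_aliased

        out = remove_technical_effects(l2, default_study.factors, self.TECH)
        X = drop_aliased(design_matrix(default_study.factors, self.TECH,
                                       l2.sample_ids))
        resid = out.values.to_numpy().T - out.values.to_numpy().T.mean(axis=0)
        dots = X.to_numpy().T @ resid
        # center the design columns too (grand mean was added back)
        Xc = X.to_numpy() - X.to_numpy().mean(axis=0)
        assert np.abs(Xc.T @ out.values.to_numpy().T).max() < 1e-6

    def test_grand_means_preserved(self, l2, default_study):
        out = remove_technical_effects(l2, default_study.factors, self.TECH)
        assert np.allclose(out.values.mean(axis=1), l2.values.mean(axis=1),
                           atol=1e-10)

    def test_removal_kills_planted_chip_signal(self, chip_only_study):
        st = chip_only_study
        l2c = log2_transform(st.expression)
        out = remove_technical_effects(l2c, st.factors, ["chip"])
        pca = compute_pca(out, "probe")
        res = eigen_r2(pca, st.factors.column("chip"), "categorical")
        assert res.eigen_r2 < 0.01

    def test_pc1_collapses_on_technical_only_study(self):
        cfg = SimulationConfig(seed=23, variance_fractions={"chip": 0.35,
                                                            "amplification_plate": 0.2},
                               n_mismatch_probes=0, n_null_in_probe_snps=0,
                               n_y_probes=0)
        st = generate_study(cfg)
        l2s = log2_transform(st.expression)
        before = variance_explained(compute_pca(l2s, "probe"), 1)
        cleaned = remove_technical_effects(l2s, st.factors,
                                           ["chip", "amplification_plate"])
        after = variance_explained(compute_pca(cleaned, "probe"), 1)
        assert after < 0.5 * before

    def test_collinear_factors_dropped_with_warning(self, l2, default_study, caplog):
        # chip determines amplification_plate, so plate dummies are aliased
        with caplog.at_level("WARNING"):
            remove_technical_effects(l2, default_study.factors,
                                     ["chip", "amplification_plate"])
        assert any("aliased" in r.message for r in caplog.records)
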
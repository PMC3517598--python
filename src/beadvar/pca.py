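"""PCA of expression profiles and Eigen-R-squared variance attribution.

Samples are the observations and probes the variables. The eigengene
(score) vectors feed three consumers: the Eigen-R-squared statistic
(eigenvalue-weighted average of per-eigengene regression R-squared on a
factor, estimating the factor's share of total expression variance),
the PC-factor association scan, and PC covariates for the adjustment
evaluation.

Centering is explicit: uncentered PCA reproduces the dominant-PC1
regime driven by the shared mean profile; probe-centered PCA is used
for the Eigen-R-squared regressions and PC covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, FactorTable
from .linmod import design_matrix, dummy_code, f_test_vs_intercept, fit_ols


@dataclass
class PCADecomposition:
    eigenvalues: np.ndarray          # nonincreasing, variance units
    variance_fractions: np.ndarray   # eigenvalues / sum
    scores: pd.DataFrame             # samples x components (PC1, PC2, ...)
    centering: str                   # "none" | "probe"

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    def score_columns(self, k: int) -> pd.DataFrame:
        return self.scores.iloc[:, :k]


def compute_pca(expression: ExpressionMatrix, centering: str = "probe") -> PCADecomposition:
    """Singular-value decomposition of the (optionally probe-centered)
    sample x probe matrix.

    Deterministic up to sign; the sign of each score vector is fixed so
    its largest-magnitude entry is positive.
    """
    if centering not in ("none", "probe"):
        raise ValueError("centering must be 'none' or 'probe'")
    if expression.n_samples < 2 or expression.n_probes < 2:
        raise ValueError("PCA needs at least 2 samples and 2 probes")
    X = expression.values.to_numpy(dtype=float).T  # samples x probes
    if np.ptp(X) == 0:
        raise ValueError("constant expression matrix has no principal components")
    if centering == "probe":
        X = X - X.mean(axis=0, keepdims=True)
        if np.ptp(X) == 0:
            raise ValueError("matrix is constant after probe-centering")
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    n = X.shape[0]
    eigenvalues = s ** 2 / (n - 1)
    fractions = eigenvalues / eigenvalues.sum()
    scores = U * s[None, :]
    flip = np.sign(scores[np.abs(scores).argmax(axis=0), np.arange(scores.shape[1])])
    flip[flip == 0] = 1.0
    scores = scores * flip[None, :]
    score_df = pd.DataFrame(
        scores, index=expression.sample_ids,
        columns=[f"PC{k + 1}" for k in range(scores.shape[1])])
    return PCADecomposition(eigenvalues=eigenvalues, variance_fractions=fractions,
                            scores=score_df, centering=centering)


def variance_explained(pca: PCADecomposition, k: int) -> float:
    """Cumulative variance fraction of the first k components."""
    if not 1 <= k <= pca.n_components:
        raise ValueError(f"k must be in [1, {pca.n_components}], got {k}")
    return float(pca.variance_fractions[:k].sum())


def _factor_design(factor: pd.Series, factor_type: str) -> pd.DataFrame:
    """Intercept + factor columns for a single-factor regression."""
    n = len(factor)
    if factor_type == "categorical":
        levels = pd.unique(factor.astype(str))
        if len(levels) < 2:
            raise ValueError("factor has a single level; variance attribution undefined")
        if len(levels) >= n:
            raise ValueError("factor is saturated (one level per sample)")
        cols = dummy_code(factor, str(factor.name or "factor"))
    elif factor_type == "continuous":
        vals = pd.to_numeric(factor)
        if vals.nunique() < 2:
            raise ValueError("factor has no variation")
        cols = vals.to_frame(str(factor.name or "factor"))
    else:
        raise ValueError(f"unknown factor type {factor_type!r}")
    X = pd.concat([pd.Series(1.0, index=factor.index, name="intercept"), cols], axis=1)
    return X


@dataclass
class EigenR2Result:
    factor: str
    eigen_r2: float
    n_components_used: int
    per_component: pd.DataFrame  # columns: r2 (adjusted, floored), weight


def eigen_r2(
    pca: PCADecomposition,
    factor: pd.Series,
    factor_type: str,
    retain: float = 0.999,
) -> EigenR2Result:
    """Share of total expression variance explained by one factor.

    Each eigengene retained up to ``retain`` cumulative variance is
    regressed on the factor (continuous: simple linear model;
    categorical: full dummy coding); its adjusted R-squared (floored at
    0, mitigating small-sample overestimation) is weighted by the
    component's variance fraction and summed.
    """
    X = _factor_design(factor.loc[pca.scores.index], factor_type)
    cum = np.cumsum(pca.variance_fractions)
    k = int(np.searchsorted(cum, retain) + 1)
    k = min(k, pca.n_components)
    fit = fit_ols(X, pca.score_columns(k))
    r2 = np.maximum(fit.adj_r2.to_numpy(), 0.0)
    weights = pca.variance_fractions[:k]
    per = pd.DataFrame({"r2": r2, "weight": weights},
                       index=pca.scores.columns[:k])
    value = float((r2 * weights).sum())
    return EigenR2Result(factor=str(factor.name), eigen_r2=value,
                         n_components_used=k, per_component=per)


@dataclass
class PCFactorScan:
    pvalues: pd.DataFrame        # factors x components
    best_component: pd.Series    # per factor, 1-based index of argmin p
    bonferroni_threshold: float  # 0.05 / n_factors


def pc_factor_scan(pca: PCADecomposition, factors: FactorTable,
                   n_pcs: int = 50, alpha: float = 0.05) -> PCFactorScan:
    """F-test p-value of score ~ factor for every (factor, component).

    The attached Bonferroni threshold is ``alpha / n_factors`` (the
    number of factors scanned), matching the convention of correcting
    the per-factor minimum over components.
    """
    if n_pcs > pca.n_components:
        raise ValueError(f"n_pcs={n_pcs} exceeds available components ({pca.n_components})")
    aligned = factors.align_to(pca.scores.index)
    grid = {}
    for name in aligned.factor_names:
        ftype = aligned.types[name]
        X = _factor_design(aligned.column(name), ftype)
        grid[name] = [f_test_vs_intercept(X, pca.scores.iloc[:, k]) for k in range(n_pcs)]
    pv = pd.DataFrame(grid, index=pca.scores.columns[:n_pcs]).T
    best = pv.to_numpy().argmin(axis=1) + 1
    return PCFactorScan(
        pvalues=pv,
        best_component=pd.Series(best, index=pv.index, name="best_pc"),
        bonferroni_threshold=alpha / len(aligned.factor_names))


def remove_technical_effects(
    expression: ExpressionMatrix,
    factors: FactorTable,
    technical: list[str],
) -> ExpressionMatrix:
    """Residualize every probe on the technical factors.

    Per probe, returns the residuals of expr ~ technical factors
    (dummy-coded) plus the probe's grand mean, so the intensity scale
    is preserved. Collinear design columns are dropped with a warning.
    """
    X = design_matrix(factors, technical, expression.sample_ids)
    Y = expression.values.T  # samples x probes
    fit = fit_ols(X, Y)
    adjusted = fit.residuals + Y.to_numpy().mean(axis=0, keepdims=True)
    return ExpressionMatrix(
        pd.DataFrame(adjusted.T, index=expression.probe_ids,
                     columns=expression.sample_ids),
        scale=expression.scale)
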
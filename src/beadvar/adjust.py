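"""Probewise association engine and covariate-adjustment evaluation.

The evaluation framework regresses every probe's (transformed)
expression on a phenotype of interest plus a chosen covariate set and
summarizes each scenario by the arithmetic mean over probes of the
phenotype coefficient's standard error (mean SE): lower mean SE means
greater power under that adjustment. A pseudo-phenotype of standard
normal draws ("random phenotype") provides a phenotype that is free of
confounding with any technical factor, so mean-SE differences between
scenarios reflect pure residual-variance reduction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, FactorTable
from .linmod import design_matrix, fit_ols
from .pca import PCADecomposition

logger = logging.getLogger(__name__)


def random_phenotype(sample_ids, seed: int) -> pd.Series:
    """Independent standard normal draws indexed by sample."""
    ids = list(sample_ids)
    if len(ids) < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    return pd.Series(rng.normal(size=len(ids)), index=ids, name="random_phenotype")


@dataclass
class AssociationResult:
    """Per-probe phenotype association statistics for one covariate set."""

    table: pd.DataFrame  # index probe_id; beta, se, p, adjusted_r2, n_used
    phenotype: str
    covariate_set: str


def probewise_regression(
    expression: ExpressionMatrix,
    phenotype: pd.Series,
    factors: FactorTable | None = None,
    covariates: list[str] | None = None,
    extra: pd.DataFrame | None = None,
    covariate_set: str = "custom",
) -> AssociationResult:
    """OLS of every probe on phenotype + covariates.

    ``beta``/``se``/``p`` refer to the phenotype column (two-sided
    t-test). Samples with a missing value in the phenotype or any used
    covariate are dropped for this model only, with a logged count.
    ``extra`` columns (e.g. PC scores or a dosage) enter the design
    unchanged.
    """
    if expression.scale == "raw":
        raise ValueError("probewise regression expects log2- or vst-scale data")
    covariates = covariates or []
    sample_ids = list(expression.sample_ids)
    pheno = phenotype.loc[sample_ids].astype(float)
    X = design_matrix(factors, covariates, sample_ids, extra=extra)
    X.insert(1, "phenotype", pheno.to_numpy())
    complete = ~X.isna().any(axis=1).to_numpy()
    if not complete.all():
        logger.info("dropping %d samples with missing covariate values",
                    int((~complete).sum()))
    X = X.loc[complete]
    Y = expression.values.T.loc[complete]
    n_used = int(complete.sum())
    if n_used - X.shape[1] < 3:
        raise ValueError(f"only {n_used - X.shape[1]} residual degrees of freedom")
    fit = fit_ols(X, Y)
    tab = pd.DataFrame({
        "beta": fit.coef.loc["phenotype"],
        "se": fit.se.loc["phenotype"],
        "p": fit.pvalues.loc["phenotype"],
        "adjusted_r2": fit.adj_r2,
        "n_used": n_used,
    })
    tab.index.name = "probe_id"
    return AssociationResult(table=tab, phenotype=str(phenotype.name),
                             covariate_set=covariate_set)


def mean_se(result: AssociationResult) -> float:
    """Arithmetic mean of the per-probe phenotype-coefficient SEs."""
    if len(result.table) < 1:
        raise ValueError("no probes in association result")
    return float(result.table["se"].mean())


def default_scenarios() -> dict[str, dict]:
    """The standard covariate-adjustment comparison grid.

    ``technical`` is amplification plate + RIN + storage time; ``cell``
    the white-cell composition covariate(s).
    """
    tech = ["amplification_plate", "rin", "storage_time"]
    return {
        "unadjusted": {"factors": [], "n_pcs": 0},
        "age_sex": {"factors": ["age", "sex"], "n_pcs": 0},
        "technical": {"factors": tech, "n_pcs": 0},
        "age_sex_technical": {"factors": ["age", "sex", *tech], "n_pcs": 0},
        "technical_pc1": {"factors": tech, "n_pcs": 1},
        "pcs_50": {"factors": [], "n_pcs": 50},
        "technical_cell_types": {"factors": [*tech, "lymphocyte_pct"], "n_pcs": 0},
    }


@dataclass
class ScenarioReport:
    table: pd.DataFrame  # index scenario; mean_se, pct_reduction
    phenotype: str


def compare_scenarios(
    expression: ExpressionMatrix,
    phenotype: pd.Series,
    factors: FactorTable,
    scenarios: dict[str, dict] | None = None,
    pca: PCADecomposition | None = None,
) -> ScenarioReport:
    """Mean SE per covariate scenario and percent reduction vs unadjusted.

    Each scenario is ``{"factors": [names], "n_pcs": k}``; PCs are taken
    from ``pca`` (required if any scenario uses them). The unadjusted
    (phenotype-only) model is always fit as the reference.
    """
    scenarios = scenarios if scenarios is not None else default_scenarios()
    if any(s.get("n_pcs", 0) > 0 for s in scenarios.values()) and pca is None:
        raise ValueError("scenarios reference PCs but no PCA was supplied")
    rows = {}
    results: dict[str, AssociationResult] = {}
    base = probewise_regression(expression, phenotype, factors, [],
                                covariate_set="unadjusted")
    base_se = mean_se(base)
    for name, spec in scenarios.items():
        n_pcs = int(spec.get("n_pcs", 0))
        extra = pca.score_columns(n_pcs) if n_pcs else None
        res = probewise_regression(expression, phenotype, factors,
                                   list(spec.get("factors", [])), extra=extra,
                                   covariate_set=name)
        m = mean_se(res)
        rows[name] = {"mean_se": m, "pct_reduction": 100.0 * (1.0 - m / base_se)}
        results[name] = res
    report = pd.DataFrame(rows).T
    report.index.name = "scenario"
    return ScenarioReport(table=report, phenotype=str(phenotype.name))


def unexplained_variance_curve(
    expression: ExpressionMatrix,
    phenotype: pd.Series,
    pca: PCADecomposition,
    max_k: int = 100,
) -> pd.Series:
    """Percent unexplained variance vs number of PC covariates.

    For each k the model expr ~ phenotype + PC1..PCk is fit per probe;
    value(k) is the mean over probes of (1 - adjusted R-squared),
    expressed as a percentage of the covariate-free value, so
    value(0) = 100 by construction. If k would exhaust the residual
    degrees of freedom the curve is truncated with a warning.
    """
    if max_k > pca.n_components:
        raise ValueError(f"max_k={max_k} exceeds available components")
    n = expression.n_samples
    usable = min(max_k, n - 5)  # keep >= 3 residual df beyond intercept+phenotype
    if usable < max_k:
        logger.warning("truncating PC curve at k=%d to preserve residual df", usable)
    values = {}
    for k in range(usable + 1):
        extra = pca.score_columns(k) if k else None
        res = probewise_regression(expression, phenotype, None, [], extra=extra,
                                   covariate_set=f"pcs_{k}")
        values[k] = float((1.0 - res.table["adjusted_r2"]).mean())
    base = values[0]
    curve = pd.Series({k: 100.0 * v / base for k, v in values.items()},
                      name="pct_unexplained")
    curve.index.name = "n_pcs"
    return curve
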
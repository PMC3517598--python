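"""Design-matrix construction and a vectorized OLS engine.

Every regression in the pipeline (eigengene-on-factor, probewise
phenotype association, SNP mismatch-dosage tests) runs through
:func:`fit_ols`, which fits one design against many response vectors at
once and returns per-response coefficient, standard error, t-test
p-value and adjusted R-squared. Categorical factors enter as full dummy
codings (first level dropped when an intercept is present); aliased
columns are detected by pivoted QR and dropped with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .containers import FactorTable

logger = logging.getLogger(__name__)


def dummy_code(values: pd.Series, name: str, drop_first: bool = True) -> pd.DataFrame:
    """Full dummy coding of a categorical column (levels in sorted order)."""
    levels = sorted(pd.unique(values.astype(str)))
    use = levels[1:] if drop_first else levels
    out = pd.DataFrame(
        {f"{name}[{lv}]": (values.astype(str) == lv).astype(float) for lv in use},
        index=values.index)
    return out


def design_matrix(
    factors: FactorTable,
    names: list[str],
    sample_ids,
    intercept: bool = True,
    extra: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Build a design matrix for the given factor names.

    Continuous factors enter as numeric columns, categorical ones as
    dummy codings. ``extra`` columns (e.g. PC scores, a dosage) are
    appended as-is.
    """
    cols: list[pd.DataFrame | pd.Series] = []
    if names and factors is None:
        raise ValueError("covariate names given but no factor table supplied")
    aligned = factors.align_to(sample_ids) if factors is not None else None
    for name in names:
        if name not in aligned.table.columns:
            raise KeyError(f"unknown covariate {name!r}")
        if aligned.is_categorical(name):
            cols.append(dummy_code(aligned.column(name), name))
        else:
            cols.append(aligned.column(name).astype(float))
    parts = [pd.DataFrame({"intercept": np.ones(len(list(sample_ids)))},
                          index=pd.Index(list(sample_ids)))] if intercept else []
    for c in cols:
        parts.append(c if isinstance(c, pd.DataFrame) else c.to_frame())
    if extra is not None:
        parts.append(extra.loc[list(sample_ids)])
    X = pd.concat(parts, axis=1) if parts else pd.DataFrame(index=list(sample_ids))
    return X


def drop_aliased(X: pd.DataFrame, rtol: float = 1e-9) -> pd.DataFrame:
    """Drop linearly dependent columns (pivoted-QR rank detection)."""
    arr = X.to_numpy(dtype=float)
    if arr.shape[1] == 0:
        return X
    _, R, piv = linalg.qr(arr, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int((diag > rtol * max(diag.max(), 1.0)).sum())
    if rank == arr.shape[1]:
        return X
    keep = sorted(piv[:rank])
    dropped = [X.columns[i] for i in range(arr.shape[1]) if i not in keep]
    logger.warning("dropping %d aliased design column(s): %s", len(dropped), dropped)
    return X.iloc[:, keep]


@dataclass
class OlsFit:
    """Vectorized OLS results for one design and many responses."""

    coef: pd.DataFrame        # (n_columns, n_responses)
    se: pd.DataFrame          # same shape
    pvalues: pd.DataFrame     # two-sided t-test per coefficient
    sigma2: pd.Series         # residual variance per response
    r2: pd.Series
    adj_r2: pd.Series
    df_resid: int
    residuals: np.ndarray     # (n_obs, n_responses)
    fitted: np.ndarray


def fit_ols(X: pd.DataFrame, Y: pd.DataFrame, drop_collinear: bool = True) -> OlsFit:
    """OLS of every column of ``Y`` on the common design ``X``.

    Two-sided t-test p-values per coefficient; adjusted R-squared uses
    the centered total sum of squares (so a pure-intercept model has
    R-squared 0).
    """
    if drop_collinear:
        X = drop_aliased(X)
    Xa = X.to_numpy(dtype=float)
    Ya = Y.to_numpy(dtype=float)
    n, p = Xa.shape
    df = n - p
    if df < 1:
        raise ValueError(f"no residual degrees of freedom (n={n}, p={p})")
    XtX = Xa.T @ Xa
    XtX_inv = np.linalg.inv(XtX)
    B = XtX_inv @ (Xa.T @ Ya)                     # (p, m)
    fitted = Xa @ B
    resid = Ya - fitted
    rss = (resid ** 2).sum(axis=0)
    sigma2 = rss / df
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, B / se, np.inf * np.sign(B))
    pv = 2.0 * stats.t.sf(np.abs(tstat), df)
    pv = np.clip(pv, np.finfo(float).tiny, 1.0)
    tss = ((Ya - Ya.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(tss > 0, 1.0 - rss / tss, 0.0)
        adj = np.where(tss > 0, 1.0 - (rss / df) / (tss / (n - 1)), 0.0)
    cols = Y.columns
    return OlsFit(
        coef=pd.DataFrame(B, index=X.columns, columns=cols),
        se=pd.DataFrame(se, index=X.columns, columns=cols),
        pvalues=pd.DataFrame(pv, index=X.columns, columns=cols),
        sigma2=pd.Series(sigma2, index=cols),
        r2=pd.Series(r2, index=cols),
        adj_r2=pd.Series(adj, index=cols),
        df_resid=df,
        residuals=resid,
        fitted=fitted,
    )


def f_test_vs_intercept(X: pd.DataFrame, y: pd.Series) -> float:
    """F-test p-value of a model (with intercept) against intercept-only."""
    X = drop_aliased(X)
    q = X.shape[1] - 1  # non-intercept columns
    if q < 1:
        return 1.0
    fit = fit_ols(X, y.to_frame("y"), drop_collinear=False)
    n = len(y)
    rss = float((fit.residuals ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    df = n - X.shape[1]
    if tss <= 0 or df < 1:
        return 1.0
    num = (tss - rss) / q
    den = rss / df
    if den <= 0:
        return np.finfo(float).tiny
    f = num / den
    return float(max(stats.f.sf(f, q, df), np.finfo(float).tiny))
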
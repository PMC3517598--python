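"""Sample QC and intensity transformation.

Detection p-values against negative-control background, the
detected-probe sample filter, the Y-probe sex check, quantile
normalization, log2 transformation (L2T) and a generalized-log
variance-stabilizing transformation (VST) calibrated to coincide with
log2 at high intensity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)

MIN_CONTROLS = 20


# ---------------------------------------------------------------------------
# detection


def detection_pvalues(expression: ExpressionMatrix,
                      negative_controls: pd.DataFrame) -> pd.DataFrame:
    """Rank-based detection p-values against the control background.

    For probe g in sample i with N controls,

        p_gi = (1 + #{controls in sample i with intensity >= x_gi}) / (N + 1)

    so values lie in (0, 1] and a signal above every control gets
    p = 1/(N+1) (add-one estimator; p = 0 is impossible).
    """
    if expression.scale != "raw":
        raise ValueError("detection p-values are defined on raw intensities")
    n_controls = negative_controls.shape[0]
    if n_controls < MIN_CONTROLS:
        raise ValueError(f"need >= {MIN_CONTROLS} negative controls, got {n_controls}")
    ctrl = negative_controls[expression.sample_ids].to_numpy()
    x = expression.values.to_numpy()
    # per sample: count controls >= signal via searchsorted on sorted controls
    out = np.empty_like(x)
    for i in range(x.shape[1]):
        sorted_ctrl = np.sort(ctrl[:, i])
        n_below = np.searchsorted(sorted_ctrl, x[:, i], side="left")
        n_ge = n_controls - n_below
        out[:, i] = (1.0 + n_ge) / (n_controls + 1.0)
    return pd.DataFrame(out, index=expression.probe_ids, columns=expression.sample_ids)


def filter_samples_by_detection(
    expression: ExpressionMatrix,
    detection: pd.DataFrame,
    min_detected: int = 6000,
    alpha: float = 0.01,
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop samples with fewer than ``min_detected`` probes at p < alpha.

    A sample is kept iff #{probes with detection p < alpha} >= min_detected
    (the exclusion rule is "less than", so a sample exactly at the
    threshold is kept). Sample order is preserved.
    """
    det = detection.loc[expression.probe_ids, expression.sample_ids]
    n_detected = (det.to_numpy() < alpha).sum(axis=0)
    keep = n_detected >= min_detected
    kept_ids = [s for s, k in zip(expression.sample_ids, keep) if k]
    excluded = [s for s, k in zip(expression.sample_ids, keep) if not k]
    if excluded:
        logger.info("detection filter excluded %d samples", len(excluded))
    return expression.subset_samples(kept_ids), excluded


def filter_probes_by_detection(
    expression: ExpressionMatrix,
    detection: pd.DataFrame,
    min_fraction: float = 0.5,
    alpha: float = 0.01,
) -> tuple[ExpressionMatrix, list[str]]:
    """Keep probes significantly detected above background.

    A probe is kept iff its detection p-value is below ``alpha`` in at
    least ``min_fraction`` of the samples; the rest measure background
    noise only. Returns the filtered matrix and the excluded probe ids.
    """
    det = detection.loc[expression.probe_ids, expression.sample_ids]
    frac = (det.to_numpy() < alpha).mean(axis=1)
    keep = frac >= min_fraction
    kept = ExpressionMatrix(expression.values.loc[keep], scale=expression.scale)
    excluded = list(expression.probe_ids[~keep])
    if excluded:
        logger.info("probe detection filter excluded %d probes", len(excluded))
    return kept, excluded


# ---------------------------------------------------------------------------
# sex check


def sex_check(
    expression: ExpressionMatrix,
    y_probe_ids: list[str],
    reported_sex: pd.Series,
    min_separation: float = 1.0,
) -> list[str]:
    """Samples whose Y-probe-predicted sex disagrees with the report.

    Predicted sex comes from a 1-dimensional 2-means split of the mean
    log2 Y-probe intensity per sample; the higher-mean group is labelled
    male. If the two group centers are closer than ``min_separation``
    log2 units the cohort is treated as single-sex (no calls; a warning
    is logged) and an empty list is returned.
    """
    y_ids = [p for p in y_probe_ids if p in expression.probe_ids]
    if len(y_ids) < 5:
        raise ValueError(f"need >= 5 Y-chromosome probes, got {len(y_ids)}")
    vals = expression.values.loc[y_ids]
    if expression.scale == "raw":
        vals = np.log2(vals)
    score = vals.mean(axis=0)  # per sample

    # 1-d 2-means: initialize at min/max, iterate assignment/means
    lo, hi = float(score.min()), float(score.max())
    if hi - lo < 1e-12:
        logger.warning("sex check: Y-probe intensities are constant; no calls made")
        return []
    c = np.array([lo, hi])
    for _ in range(100):
        assign = (np.abs(score.to_numpy()[:, None] - c[None, :])).argmin(axis=1)
        new_c = np.array([
            score.to_numpy()[assign == k].mean() if (assign == k).any() else c[k]
            for k in (0, 1)
        ])
        if np.allclose(new_c, c):
            break
        c = new_c
    if abs(c[1] - c[0]) < min_separation:
        logger.warning(
            "sex check: group separation %.3f below margin %.3f; assuming "
            "single-sex cohort, no mismatch calls", abs(c[1] - c[0]), min_separation)
        return []
    predicted = pd.Series(np.where(assign == int(np.argmax(c)), "male", "female"),
                          index=score.index)
    reported = reported_sex.loc[predicted.index].astype(str)
    return list(predicted.index[predicted != reported])


# ---------------------------------------------------------------------------
# quantile normalization


def quantile_normalize(expression: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the mean of the sorted sample vectors.

    After normalization each sample's sorted intensity vector equals the
    across-sample mean of sorted vectors; ties within a sample receive
    the mean of the reference quantiles they span.
    """
    x = expression.values.to_numpy(dtype=float)
    order = np.argsort(x, axis=0, kind="stable")
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for i in range(x.shape[1]):
        col = np.empty(x.shape[0])
        col[order[:, i]] = reference
        # average reference values over tie groups
        vals = x[:, i]
        if np.unique(vals).size != vals.size:
            s = pd.Series(col).groupby(vals).transform("mean").to_numpy()
            col = s
        out[:, i] = col
    return ExpressionMatrix(
        pd.DataFrame(out, index=expression.probe_ids, columns=expression.sample_ids),
        scale=expression.scale)


# ---------------------------------------------------------------------------
# transformations


def log2_transform(expression: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2 (L2T)."""
    arr = expression.values.to_numpy()
    if np.any(arr <= 0):
        g, s = np.argwhere(arr <= 0)[0]
        raise ValueError(
            f"log2 requires positive intensities; probe {expression.probe_ids[g]!r}, "
            f"sample {expression.sample_ids[s]!r} has {arr[g, s]}")
    return ExpressionMatrix(np.log2(expression.values), scale="log2")


@dataclass
class VSTParams:
    """Parameters of the generalized-log variance-stabilizing transform.

    ``c1``/``c2`` are the slope/intercept of the raw-scale sd-vs-mean
    line, ``c3`` an optional additive-noise floor, and
    ``calib_a``/``calib_b`` the affine calibration mapping the
    stabilized scale onto log2 so that the transform coincides with
    log2 at two high-intensity anchor points.
    """

    c1: float
    c2: float
    c3: float = 0.0
    calib_a: float = 1.0
    calib_b: float = 0.0
    anchor_lo: float | None = None  # intensities where transform == log2 exactly
    anchor_hi: float | None = None

    def validate(self) -> None:
        if not np.isfinite([self.c1, self.c2, self.c3, self.calib_a, self.calib_b]).all():
            raise ValueError("VST parameters must be finite")
        if self.c1 <= 0:
            raise ValueError("c1 must be > 0")

    def core(self, x: np.ndarray) -> np.ndarray:
        u = self.c1 * np.asarray(x, dtype=float) + self.c2
        return np.log(u + np.sqrt(u * u + self.c3 * self.c3))

    def transform(self, x: np.ndarray) -> np.ndarray:
        return self.calib_a * self.core(x) + self.calib_b

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({k: (float(v) if v is not None else None)
                            for k, v in self.__dict__.items()}, fh)

    @classmethod
    def from_yaml(cls, path) -> "VSTParams":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def fit_vst(expression: ExpressionMatrix,
            anchor_quantiles: tuple[float, float] = (0.75, 0.95)) -> VSTParams:
    """Fit the mean-variance line and the log2 calibration.

    Per-probe means and sds are computed across samples after removing
    per-sample median offsets; (c1, c2) come from a robust Theil-Sen
    fit of sd against mean. The calibration (calib_a, calib_b) makes
    the transform agree with log2 exactly at the ``anchor_quantiles``
    of the per-probe mean-intensity distribution.
    """
    if expression.scale != "raw":
        raise ValueError("fit_vst expects raw-scale intensities")
    x = expression.values.to_numpy(dtype=float)
    if x.shape[0] < 50 or x.shape[1] < 8:
        raise ValueError("need >= 50 probes and >= 8 samples to fit the VST")
    # remove per-sample offsets first; on the raw scale sample effects
    # are multiplicative, so rescale each sample to the common median
    med = np.median(x, axis=0)
    if np.any(med <= 0):
        raise ValueError("nonpositive sample median; raw intensities expected")
    centered = x * (np.median(med) / med)[None, :]
    means = centered.mean(axis=1)
    sds = centered.std(axis=1, ddof=1)
    ok = means > 0
    # With c3 = 0 the transform is affine in ln(x + c2/c1): what matters
    # is the low-intensity crossover c2/c1, while the high range is
    # pinned to log2 by the calibration below. The additive floor c2 is
    # only identifiable where it is not swamped by the multiplicative
    # term, so the line is fit on the bottom-quartile-intensity probes.
    low = means[ok] <= np.quantile(means[ok], 0.25)
    slope, intercept, _, _ = stats.theilslopes(sds[ok][low], means[ok][low])
    if not np.isfinite(slope) or slope <= 0:
        raise ValueError(
            "degenerate mean-variance fit (c1 <= 0); inspect the raw-scale "
            "sd-vs-mean relation before applying a VST")
    params = VSTParams(c1=float(slope), c2=float(max(intercept, 0.0)))
    q1, q2 = np.quantile(means[ok], anchor_quantiles)
    if not q1 < q2:
        raise ValueError("anchor intensities are not distinct; cannot calibrate")
    h1, h2 = params.core(q1), params.core(q2)
    a = (np.log2(q2) - np.log2(q1)) / (h2 - h1)
    b = np.log2(q1) - a * h1
    params.calib_a, params.calib_b = float(a), float(b)
    params.anchor_lo, params.anchor_hi = float(q1), float(q2)
    params.validate()
    return params


def apply_vst(expression: ExpressionMatrix, params: VSTParams) -> ExpressionMatrix:
    """Apply the calibrated generalized-log transform.

    h(x) = calib_a * ln(c1*x + c2 + sqrt((c1*x + c2)^2 + c3^2)) + calib_b.
    Strictly increasing in x; close to log2(x) at high intensity and
    finite (compressive) as x -> 0 where log2 diverges.
    """
    if expression.scale != "raw":
        raise ValueError("apply_vst expects raw-scale intensities")
    params.validate()
    out = params.transform(expression.values.to_numpy())
    return ExpressionMatrix(
        pd.DataFrame(out, index=expression.probe_ids, columns=expression.sample_ids),
        scale="vst")
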
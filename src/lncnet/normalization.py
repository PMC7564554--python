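"""Count normalization: upper-quartile scaling and a variance-stabilizing
transform (VST) for negative-binomial counts.

Upper-quartile (UQUA) normalization divides each sample by the 75th
percentile of its non-zero counts and rescales by the across-sample mean of
those percentiles, so values stay on a count-like scale. It is the input for
rank-based co-expression, where the rescaling is irrelevant.

The VST assumes NB counts whose dispersion follows the parametric trend
``alpha(mu) = a/mu + alpha0``. Size factors come from the median-of-ratios
estimator, gene-wise dispersions from method-of-moments, the trend from an
iteratively trimmed relative least-squares fit, and the transform is the
closed form

    vst(q) = log2( (1 + a + 2*alpha0*q + 2*sqrt(alpha0*q*(1 + a + alpha0*q)))
                   / (4*alpha0) )

which is strictly increasing in q and has approximately constant variance
across the mean range when the trend holds. If the trend fit degenerates
(non-positive asymptotic dispersion or fewer than 10 usable genes) the
transform falls back to log2(q + pseudocount), and says so in the log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .data_model import CountMatrix, DataModelError

logger = logging.getLogger("lncnet")


@dataclass
class NormalizationModel:
    """Fitted normalization parameters.

    ``scale_factors`` are the per-sample UQUA factors (or median-of-ratios
    size factors for the VST); ``a_slope``/``a0_intercept`` parameterize the
    dispersion-mean trend; ``used_fallback`` flags the log2 fallback.
    """

    scale_factors: pd.Series
    a_slope: float | None = None
    a0_intercept: float | None = None
    pseudocount: float = 1.0
    used_fallback: bool = False


def filter_nonzero(cm: CountMatrix) -> CountMatrix:
    """Drop genes whose counts are zero in every sample."""
    keep = (cm.values != 0).any(axis=1)
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_nonzero: removed %d all-zero genes", removed)
    return cm.with_values(cm.values.loc[keep], cm.normalization_state)


def _upper_quartiles(values: pd.DataFrame) -> pd.Series:
    uq = {}
    for s in values.columns:
        col = values[s]
        nz = col[col > 0]
        if len(nz) < 4:
            raise DataModelError(
                f"sample {s!r} has {len(nz)} non-zero genes; "
                "need at least 4 for an upper quartile"
            )
        uq[s] = float(np.percentile(nz, 75))  # linear interpolation
    return pd.Series(uq)


def uqua_normalize(cm: CountMatrix, rescale: bool = True) -> tuple[CountMatrix, NormalizationModel]:
    """Upper-quartile normalization of a zero-filtered raw count matrix."""
    if cm.normalization_state != "raw":
        raise DataModelError("uqua_normalize expects raw counts")
    uq = _upper_quartiles(cm.values)
    scale = uq / uq.mean() if rescale else uq
    out = cm.values.div(scale, axis=1)
    model = NormalizationModel(scale_factors=scale)
    return cm.with_values(out, "uqua"), model


def median_of_ratios_size_factors(values: pd.DataFrame) -> pd.Series:
    """DESeq-style size factors from genes expressed in all samples."""
    pos = (values > 0).all(axis=1)
    if pos.sum() < 1:
        raise DataModelError("no gene is expressed in every sample")
    logc = np.log(values.loc[pos].to_numpy(float))
    log_geo_mean = logc.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logc - log_geo_mean, axis=0))
    return pd.Series(sf, index=values.columns)


def fit_dispersion_trend(
    mu: np.ndarray, disp: np.ndarray, max_iter: int = 10
) -> tuple[float, float, int]:
    """Fit ``alpha(mu) = a/mu + alpha0`` by trimmed relative least squares.

    Gene-wise method-of-moments dispersions at small n are extremely noisy
    and right-skewed; fitting relative residuals ``disp/pred - 1`` with
    iterative exclusion of genes whose ratio to the trend leaves
    [1e-4, 15] keeps the handful of outliers from dragging the asymptote up.
    Returns (a, alpha0, n_genes_used).
    """
    use = np.isfinite(mu) & np.isfinite(disp) & (mu > 0) & (disp > 1e-8)
    mu_f, d_f = mu[use], disp[use]
    a, a0 = 1.0, 0.1
    for _ in range(max_iter):
        if len(mu_f) < 2:
            break
        res = least_squares(
            lambda p: d_f / (p[0] / mu_f + p[1]) - 1.0,
            x0=[a, a0],
            bounds=([0.0, 1e-12], [np.inf, np.inf]),
        )
        a, a0 = float(res.x[0]), float(res.x[1])
        ratio = d_f / (a / mu_f + a0)
        keep = (ratio > 1e-4) & (ratio < 15.0)
        if keep.all():
            break
        mu_f, d_f = mu_f[keep], d_f[keep]
    return a, a0, int(len(mu_f))


def vst_closed_form(q: np.ndarray, a: float, a0: float) -> np.ndarray:
    t = (1.0 + a + 2.0 * a0 * q + 2.0 * np.sqrt(a0 * q * (1.0 + a + a0 * q))) / (4.0 * a0)
    return np.log2(t)


def vst_transform(
    cm: CountMatrix, pseudocount: float = 1.0
) -> tuple[CountMatrix, NormalizationModel]:
    """Variance-stabilizing transform of a zero-filtered raw count matrix."""
    if cm.normalization_state != "raw":
        raise DataModelError("vst_transform expects raw counts")
    if cm.n_samples < 2:
        raise DataModelError("vst_transform needs at least 2 samples")
    sf = median_of_ratios_size_factors(cm.values)
    q = cm.values.div(sf, axis=1)
    mu = q.mean(axis=1).to_numpy()
    var = q.var(axis=1, ddof=1).to_numpy()
    # method-of-moments NB dispersion on the common scale; the mean(1/sf)
    # term accounts for shot noise inflated by division by size factors
    xim = float(np.mean(1.0 / sf))
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = (var - xim * mu) / mu**2
    usable = disp > 0
    model = NormalizationModel(scale_factors=sf, pseudocount=pseudocount)
    if usable.sum() < 10:
        a, a0, nused = float("nan"), float("nan"), int(usable.sum())
    else:
        a, a0, nused = fit_dispersion_trend(mu[usable], disp[usable])
    if not np.isfinite(a0) or a0 <= 0 or nused < 10:
        logger.warning(
            "vst_transform: dispersion trend fit failed "
            "(a0=%s, usable=%s); falling back to log2(q + %g)",
            a0, nused, pseudocount,
        )
        out = np.log2(q + pseudocount)
        model.used_fallback = True
        return cm.with_values(out, "vst"), model
    model.a_slope, model.a0_intercept = a, a0
    out = pd.DataFrame(
        vst_closed_form(q.to_numpy(float), a, a0), index=q.index, columns=q.columns
    )
    return cm.with_values(out, "vst"), model
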
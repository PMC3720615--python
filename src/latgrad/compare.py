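"""Comparing richness surfaces: Pearson correlation and model-II regression.

To ask whether the richness pattern of a species subset (e.g. the basal
or derived quartile) mirrors the total richness pattern, two statistics
are used.  Per-cell richness values are compared with the sample Pearson
correlation.  The spatial structures are compared by regressing the
subset's Moran's I correlogram on the total's with a model-II regression
— both variables are estimates, so neither is an error-free predictor.

Two model-II estimators are provided:

* reduced major axis (RMA): slope = sign(r) · sd(y)/sd(x);
* major axis (MA): slope of the principal eigenvector of the 2×2
  covariance matrix.

Standard errors of the slope and R² come from the one-delete jackknife:
the statistic is recomputed on every leave-one-out sample and
SE = sqrt(((n−1)/n) · Σ (θ_(i) − θ̄_(·))²).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def pearson_r(a, b) -> float:
    """Sample Pearson correlation between two per-cell vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 observations")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance: Pearson correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class ModelIIFit:
    """Model-II regression fit of y on x."""

    method: str
    slope: float
    intercept: float
    r_squared: float
    n: int
    se_slope: float | None = None
    se_r_squared: float | None = None
    n_dropped_classes: int = 0
    degenerate_replicates: int = 0


def _slope(x: np.ndarray, y: np.ndarray, method: str) -> float:
    sx, sy = np.std(x, ddof=1), np.std(y, ddof=1)
    if sx == 0:
        raise ValueError("zero variance in x: model-II slope undefined")
    sxy = float(np.cov(x, y, ddof=1)[0, 1])
    if method == "rma":
        r = sxy / (sx * sy) if sy > 0 else 0.0
        # sign convention: positive slope when r = 0 (flagged by caller)
        sign = 1.0 if r >= 0 else -1.0
        return sign * sy / sx
    if method == "ma":
        if sxy == 0.0:
            # principal axis aligned with the larger-variance coordinate
            return 0.0 if sx >= sy else np.inf
        sxx, syy = sx * sx, sy * sy
        return (syy - sxx + np.hypot(syy - sxx, 2 * sxy)) / (2 * sxy)
    raise ValueError(f"unknown model-II method {method!r}")


def model2_fit(x, y, method: str = "rma") -> ModelIIFit:
    """Model-II (RMA or MA) regression of y on x.

    The slope passes through the bivariate mean: intercept = ȳ − b·x̄.
    r_squared is the squared Pearson correlation of the two variables.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two 1-D vectors of equal length >= 3")
    slope = _slope(x, y, method)
    intercept = float(np.mean(y) - slope * np.mean(x))
    sy = np.std(y, ddof=1)
    r = pearson_r(x, y) if sy > 0 else 0.0
    return ModelIIFit(method=method, slope=float(slope),
                      intercept=intercept, r_squared=float(r * r), n=len(x))


def jackknife(x, y, method: str = "rma") -> tuple[float, float, int]:
    """One-delete jackknife SEs of the model-II slope and R².

    Returns (se_slope, se_r_squared, n_degenerate) where n_degenerate
    counts leave-one-out replicates that were flagged and excluded
    because the reduced sample was degenerate (zero variance).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("jackknife requires at least 4 observations")
    slopes, r2s = [], []
    degenerate = 0
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        xi, yi = x[keep], y[keep]
        try:
            b = _slope(xi, yi, method)
            sy = np.std(yi, ddof=1)
            r = pearson_r(xi, yi) if (sy > 0 and np.std(xi, ddof=1) > 0) else 0.0
        except ValueError:
            degenerate += 1
            continue
        slopes.append(b)
        r2s.append(r * r)
    if len(slopes) < 2:
        raise ValueError("too many degenerate jackknife replicates")
    return jackknife_se(slopes), jackknife_se(r2s), degenerate


def jackknife_se(leave_one_out_values) -> float:
    """Jackknife SE from the n leave-one-out replicate values of a statistic.

    SE = sqrt(((n−1)/n) · Σ (θ_(i) − θ̄_(·))²).  For the sample mean this
    reduces algebraically to the classical sd/√n.
    """
    vals = np.asarray(leave_one_out_values, dtype=float)
    m = len(vals)
    return float(np.sqrt((m - 1) / m * np.sum((vals - vals.mean()) ** 2)))


def compare_correlograms(total, subset, method: str = "rma") -> ModelIIFit:
    """Model-II regression of a subset correlogram on the total's.

    x = Moran's I of total richness per distance class, y = the subset's;
    a slope near 1 with high R² means the subset reproduces the total's
    spatial structure.  Classes where either correlogram is undefined are
    dropped (the count is recorded); at least 3 shared defined classes
    are required.  Jackknife SEs are computed over the distance classes.
    """
    xi = np.asarray(total.moran_i, dtype=float)
    yi = np.asarray(subset.moran_i, dtype=float)
    if len(xi) != len(yi):
        raise ValueError("correlograms have different numbers of classes")
    ok = np.isfinite(xi) & np.isfinite(yi)
    dropped = int(len(xi) - ok.sum())
    x, y = xi[ok], yi[ok]
    if len(x) < 3:
        raise ValueError(
            f"only {len(x)} shared defined distance classes; need >= 3"
        )
    fit = model2_fit(x, y, method=method)
    fit.n_dropped_classes = dropped
    if len(x) >= 4:
        se_b, se_r2, degen = jackknife(x, y, method=method)
        fit.se_slope, fit.se_r_squared = se_b, se_r2
        fit.degenerate_replicates = degen
    return fit
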
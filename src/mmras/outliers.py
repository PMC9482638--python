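"""Between-group essentiality outliers via an extra sum-of-squares F test.

Given per-gene CSS averaged within two groups of cell lines (e.g. RAS-
dependent on x, RAS-independent on y), most genes fall on a common trend:
universally essential genes are essential in both groups.  A gene is a
group-selective outlier when letting its point off the global regression
line reduces the residual sum of squares more than chance allows.

For each focal gene the reduced model is the OLS line through all n points
(2 parameters); the full model adds an indicator for the focal point
(3 parameters) — equivalently the focal point is fit exactly and the line
refit on the remaining n-1 points.  F = (SSE_red - SSE_full) / (SSE_full /
(n-3)) with an upper-tail p from F(1, n-3).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["fit_global_line", "extra_ss_f_test", "call_outliers"]


class FitError(ValueError):
    pass


def fit_global_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, np.ndarray, float]:
    """Ordinary least squares of y on x.

    Returns (intercept, slope, residuals, SSE).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4:
        raise FitError("global line fit requires >= 4 points")
    if np.ptp(x) == 0:
        raise FitError("x is constant; line fit is degenerate")
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    slope = np.sum((x - xm) * (y - ym)) / sxx
    intercept = ym - slope * xm
    residuals = y - (intercept + slope * x)
    return intercept, slope, residuals, float(np.sum(residuals**2))


def extra_ss_f_test(x: np.ndarray, y: np.ndarray, index: int) -> tuple[float, float]:
    """Extra sum-of-squares F test for a single focal point.

    Reduced model: one line through all n points.  Full model: that line
    plus a point indicator (the focal point fitted exactly; line refit
    without it).  Requires n >= 5 so the full model has residual df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 5:
        raise FitError("extra sum-of-squares F test requires >= 5 points")
    _, _, _, sse_red = fit_global_line(x, y)
    mask = np.ones(n, dtype=bool)
    mask[index] = False
    _, _, _, sse_full = fit_global_line(x[mask], y[mask])
    df_full = n - 3
    if sse_full <= 0:
        # remaining points are exactly collinear: any deviation is infinitely
        # significant, a point on the line is not significant at all
        f = np.inf if sse_red > sse_full else 0.0
    else:
        f = max(sse_red - sse_full, 0.0) / (sse_full / df_full)
    p = float(stats.f.sf(f, 1, df_full))
    return float(f), p


def _loo_sse(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """SSE of the OLS line refit without each point, for all points at once.

    Exact rank-one downdates of the sufficient statistics; algebraically
    identical to refitting n separate (n-1)-point regressions.
    """
    n = len(x)
    xm, ym = x.mean(), y.mean()
    dx, dy = x - xm, y - ym
    sxx, syy, sxy = np.sum(dx * dx), np.sum(dy * dy), np.sum(dx * dy)
    f = n / (n - 1.0)
    sxx_i = sxx - f * dx * dx
    syy_i = syy - f * dy * dy
    sxy_i = sxy - f * dx * dy
    with np.errstate(divide="ignore", invalid="ignore"):
        sse = syy_i - np.where(sxx_i > 0, sxy_i**2 / np.where(sxx_i > 0, sxx_i, 1.0), 0.0)
    return np.maximum(sse, 0.0)


def call_outliers(points: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Test every gene as the focal point; call those with p < alpha.

    ``points`` needs columns ``gene``, ``x`` (group A mean CSS) and ``y``
    (group B mean CSS).  No multiple-testing correction is applied: each
    gene is tested at the nominal level.  Direction: a gene lying above the
    fitted line (positive vertical residual; anomalously negative x for its
    y) is selectively essential in group A, below the line in group B.
    """
    x = points["x"].to_numpy(dtype=float)
    y = points["y"].to_numpy(dtype=float)
    n = len(points)
    if n < 5:
        raise FitError("outlier calling requires >= 5 points")
    intercept, slope, residuals, sse_red = fit_global_line(x, y)
    sse_full = _loo_sse(x, y)
    df_full = n - 3
    with np.errstate(divide="ignore"):
        f_stats = np.where(
            sse_full > 0,
            np.maximum(sse_red - sse_full, 0.0) / (sse_full / df_full),
            np.where(sse_red > sse_full, np.inf, 0.0),
        )
    p_values = stats.f.sf(f_stats, 1, df_full)
    out = pd.DataFrame(
        {
            "gene": points["gene"].to_numpy(),
            "x": x,
            "y": y,
            "residual": residuals,
            "f_stat": f_stats,
            "p_value": p_values,
            "direction": np.where(residuals > 0, "A-selective", "B-selective"),
            "is_outlier": p_values < alpha,
        }
    )
    out.attrs["intercept"] = intercept
    out.attrs["slope"] = slope
    return out
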
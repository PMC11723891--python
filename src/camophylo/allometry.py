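"""Major-axis regression of male contrasts on female contrasts.

Independent contrasts have arbitrary sign and zero expectation, so the
line is fitted through the origin.  The major-axis (MA) slope minimizes
the summed squared perpendicular distances of the contrast pairs to a
line through the origin; with uncentered sums Suu, Svv, Suv it is

    beta = (Svv - Suu + sqrt((Svv - Suu)^2 + 4 Suv^2)) / (2 Suv).

A slope above 1 means the trait diverges faster in males (the v axis)
than in females.  The slope test correlates the residual-axis scores
(v - b0*u) with the fitted-axis scores (u + b0*v); under the MA model
with slope b0 this correlation r_w is zero, and t = r_w*sqrt(df/(1-r_w^2))
is t-distributed with df = n - 1 (through-origin fitting spends no
degree of freedom on an intercept).  The confidence interval inverts the
same test, so the interval and the test agree exactly.  Outliers are
screened once, before fitting, by studentized residuals of the
through-origin least-squares fit of v on u.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats


class DegenerateFitError(ValueError):
    pass


@dataclass(frozen=True)
class MAFit:
    """One MA regression row: slope, CI, fit quality, slope=1 test."""

    beta: float
    lcl: float
    ucl: float
    r2: float
    wald_r: float
    df: int
    p_slope1: float
    n_used: int
    removed_indices: tuple[int, ...] = ()
    degenerate: bool = False       # slope sign undefined (independent evolution)
    exact_fit: bool = False
    ci_unbounded: bool = False


def positivize(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip each contrast pair so the u (female) member is non-negative.

    The sign of a contrast is arbitrary; flipping both members of a pair
    together leaves every through-origin statistic unchanged.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    sign = np.where(u < 0, -1.0, 1.0)
    return u * sign, v * sign


def _sums(u: np.ndarray, v: np.ndarray) -> tuple[float, float, float]:
    return float(u @ u), float(v @ v), float(u @ v)


def ma_slope_through_origin(u, v) -> MAFit:
    """MA point estimate and r^2 (CI and slope test filled in by ma_fit)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if len(u) != len(v) or len(u) < 3:
        raise ValueError("need >= 3 contrast pairs of equal length")
    Suu, Svv, Suv = _sums(u, v)
    if Suu == 0.0 and Svv == 0.0:
        raise ValueError("all contrasts are zero; MA slope undefined")
    n = len(u)
    if Suv == 0.0:
        # perpendicular-distance objective is symmetric in the slope sign
        return MAFit(
            beta=math.nan, lcl=math.nan, ucl=math.nan, r2=0.0,
            wald_r=math.nan, df=n - 1, p_slope1=math.nan,
            n_used=n, degenerate=True,
        )
    beta = (Svv - Suu + math.hypot(Svv - Suu, 2.0 * Suv)) / (2.0 * Suv)
    r2 = Suv**2 / (Suu * Svv)
    return MAFit(
        beta=float(beta), lcl=math.nan, ucl=math.nan, r2=float(r2),
        wald_r=math.nan, df=n - 1, p_slope1=math.nan, n_used=n,
    )


def ma_slope_test(u, v, b0: float = 1.0) -> tuple[float, float]:
    """Test slope = b0: r_w correlation and its two-sided p-value.

    r_w is the uncentered correlation between residual-axis scores
    v - b0*u and fitted-axis scores u + b0*v; df = n - 1.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    n = len(u)
    resid = v - b0 * u
    fitted = u + b0 * v
    Srr = float(resid @ resid)
    Sff = float(fitted @ fitted)
    if Srr == 0.0:
        return 0.0, 1.0  # data lie exactly on the hypothesized line
    if Sff == 0.0:
        return 1.0, 0.0
    r_w = float(resid @ fitted) / math.sqrt(Srr * Sff)
    df = n - 1
    r_w = max(min(r_w, 1.0), -1.0)
    if abs(r_w) >= 1.0:
        return r_w, 0.0
    t = r_w * math.sqrt(df / (1.0 - r_w**2))
    return r_w, float(2.0 * stats.t.sf(abs(t), df))


def _acceptance_quartic(u, v, alpha: float) -> tuple[np.ndarray, float, float]:
    """Quartic g(b) with {b : g(b) <= 0} = acceptance region of the r_w
    test at level alpha; also returns (r2, critical r^2)."""
    Suu, Svv, Suv = _sums(u, v)
    n = len(u)
    df = n - 1
    tc = stats.t.ppf(1.0 - alpha / 2.0, df)
    rc2 = tc**2 / (tc**2 + df)
    # N(b) = sum (v - b u)(u + b v) = -Suv b^2 + (Svv - Suu) b + Suv
    # Srr(b) = Svv - 2 b Suv + b^2 Suu ;  Sff(b) = Suu + 2 b Suv + b^2 Svv
    N = np.array([-Suv, Svv - Suu, Suv])
    Srr = np.array([Suu, -2.0 * Suv, Svv])
    Sff = np.array([Svv, 2.0 * Suv, Suu])
    g = np.polysub(np.polymul(N, N), rc2 * np.polymul(Srr, Sff))
    r2 = Suv**2 / (Suu * Svv) if Suu > 0 and Svv > 0 else 0.0
    return g, r2, rc2


def ma_ci_region(u, v, alpha: float = 0.05) -> list[tuple[float, float]]:
    """The full slope acceptance region {b0 : p(b0) >= alpha}.

    A union of intervals (endpoints may be +-inf).  When the data
    correlation exceeds the critical value the region is two bounded
    intervals, one around the major-axis estimate and one around the
    minor axis; otherwise arbitrarily steep slopes cannot be rejected
    and the region is unbounded.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    g, _, _ = _acceptance_quartic(u, v, alpha)
    roots = np.roots(g)
    real = np.sort(roots[np.abs(roots.imag) < 1e-8 * (1 + np.abs(roots))].real)
    # g <= 0 at -inf iff the leading coefficient is negative
    inside = g[0] < 0
    edges = [-math.inf, *real, math.inf]
    region = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if inside and lo < hi:
            region.append((float(lo), float(hi)))
        inside = not inside
    # merge intervals touching at a double root
    merged: list[tuple[float, float]] = []
    for lo, hi in region:
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], hi)
        else:
            merged.append((lo, hi))
    return merged


def slope_in_region(region: list[tuple[float, float]], b0: float) -> bool:
    return any(lo <= b0 <= hi for lo, hi in region)


def ma_confidence_interval(u, v, alpha: float = 0.05) -> tuple[float, float, bool]:
    """(lcl, ucl, unbounded) for the MA slope by inverting the r_w test.

    Reports the branch of the acceptance region containing the point
    estimate.  When the observed r^2 does not exceed the critical
    correlation the region is unbounded — no slope magnitude can be
    excluded — and the limits are NaN with unbounded=True.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    fit = ma_slope_through_origin(u, v)
    if fit.degenerate:
        raise DegenerateFitError("confidence interval undefined for degenerate fit")
    resid = v - fit.beta * u
    if float(resid @ resid) <= 1e-24 * float(v @ v + u @ u):
        return fit.beta, fit.beta, False  # exact fit: zero-width interval
    _, r2, rc2 = _acceptance_quartic(u, v, alpha)
    if r2 <= rc2:
        return math.nan, math.nan, True
    for lo, hi in ma_ci_region(u, v, alpha):
        if lo - 1e-12 <= fit.beta <= hi + 1e-12:
            return lo, hi, not (math.isfinite(lo) and math.isfinite(hi))
    return math.nan, math.nan, True  # numerical fallback; treat as unbounded


def studentized_outlier_filter(
    u, v, threshold: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """One-shot outlier screen on the through-origin OLS fit of v on u.

    Indices whose internally studentized residual exceeds the threshold
    in magnitude are removed.  Returns (kept, removed) index arrays.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if len(u) < 4:
        raise ValueError("need >= 4 pairs to screen outliers")
    if not math.isfinite(threshold):
        return np.arange(len(u)), np.array([], dtype=int)
    ols = sm.OLS(v, u[:, None]).fit()
    resid = ols.get_influence().resid_studentized_internal
    removed = np.flatnonzero(np.abs(resid) > threshold)
    kept = np.setdiff1d(np.arange(len(u)), removed)
    if len(kept) < 3:
        raise ValueError(
            f"outlier filter left only {len(kept)} pairs; cannot fit"
        )
    return kept, removed


def ma_fit(
    u,
    v,
    *,
    b0: float = 1.0,
    alpha: float = 0.05,
    outlier_threshold: float = 3.0,
    filter_outliers: bool = True,
) -> MAFit:
    """Full MA analysis of one trait: positivize, screen outliers, fit,
    confidence limits, and the slope = b0 test."""
    u, v = positivize(u, v)
    if filter_outliers:
        kept, removed = studentized_outlier_filter(u, v, outlier_threshold)
    else:
        kept, removed = np.arange(len(u)), np.array([], dtype=int)
    uu, vv = u[kept], v[kept]
    fit = ma_slope_through_origin(uu, vv)
    if fit.degenerate:
        return MAFit(
            beta=fit.beta, lcl=math.nan, ucl=math.nan, r2=fit.r2,
            wald_r=math.nan, df=fit.df, p_slope1=math.nan,
            n_used=len(uu), removed_indices=tuple(int(i) for i in removed),
            degenerate=True,
        )
    r_w, p = ma_slope_test(uu, vv, b0)
    exact = bool(np.allclose(vv, fit.beta * uu))
    lcl, ucl, unbounded = ma_confidence_interval(uu, vv, alpha)
    return MAFit(
        beta=fit.beta, lcl=lcl, ucl=ucl, r2=fit.r2, wald_r=r_w,
        df=len(uu) - 1, p_slope1=p, n_used=len(uu),
        removed_indices=tuple(int(i) for i in removed),
        exact_fit=exact, ci_unbounded=unbounded,
    )
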
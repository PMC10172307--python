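"""Standardised major axis (SMA) estimation and homogeneity-of-slopes tests.

SMA (a.k.a. reduced major axis) fits a line symmetric in x and y, with slope
sign(s_xy) * sqrt(s_yy / s_xx): the standard choice for allometric scaling,
where both variables carry sampling error. The inference suite follows the
classical residual-fitted correlation construction:

* slope test against a fixed value b0 — correlation between the residual
  axis (y - b0 x) and the fitted axis (y + b0 x);
* common-slope likelihood-ratio test across groups — the common slope
  minimises LR(b) = sum_g -n_g ln(1 - r_g(b)^2), which vanishes iff all
  group SMA slopes coincide;
* elevation (intercept) Wald test at the common slope, with slope
  uncertainty propagated through the group intercepts;
* Sidak-corrected pairwise comparisons over species, orders, diets or
  partition x diet cells, using a composite shape score (PC1 of the
  log-shape-ratio matrix over the specimens being compared) as the
  bivariate response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .shape import ShapeData

__all__ = ["SMAFit", "HOSResult", "sma_fit", "test_isometry",
           "common_slope_lr_test", "elevation_wald_test", "pairwise_hos",
           "sidak"]


@dataclass
class SMAFit:
    slope: float
    intercept: float
    n: int
    r: float
    group: str = ""


@dataclass
class HOSResult:
    statistic: float
    df: int
    p: float
    test: str
    common_slope: float | None = None
    group_estimates: dict = field(default_factory=dict)


def sma_fit(x: np.ndarray, y: np.ndarray, group: str = "") -> SMAFit:
    """Closed-form SMA line: b = sign(s_xy) sqrt(s_yy/s_xx), a = ybar - b xbar."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        raise ValueError("SMA requires n >= 3")
    sxx = np.var(x, ddof=1)
    syy = np.var(y, ddof=1)
    if sxx == 0 or syy == 0:
        raise ValueError("SMA requires positive variance in both variables")
    sxy = np.cov(x, y, ddof=1)[0, 1]
    sign = np.sign(sxy)
    if sign == 0:
        warnings.warn("zero covariance: SMA slope sign set to +1", stacklevel=2)
        sign = 1.0
    b = sign * np.sqrt(syy / sxx)
    a = y.mean() - b * x.mean()
    r = sxy / np.sqrt(sxx * syy)
    return SMAFit(float(b), float(a), len(x), float(r), group)


def _resid_fitted_corr(x: np.ndarray, y: np.ndarray, b: float) -> float:
    """Correlation between residual axis (y - b x) and fitted axis (y + b x)."""
    u = y - b * x
    v = y + b * x
    su, sv = u.std(ddof=1), v.std(ddof=1)
    if su == 0 or sv == 0:
        return 0.0
    return float(np.corrcoef(u, v)[0, 1])


def test_isometry(x: np.ndarray, y: np.ndarray, b0: float = 1.0) -> HOSResult:
    """Test the SMA slope against a fixed null value (default: isometry).

    Uses F = r_rf^2 (n-2) / (1 - r_rf^2) with r_rf the residual-fitted
    correlation at b0, referred to F(1, n-2).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n < 4:
        raise ValueError("slope test requires n >= 4")
    resid = y - b0 * x
    if np.allclose(resid, resid[0]):
        raise ValueError("residuals identically constant at b0: test undefined")
    r = _resid_fitted_corr(x, y, b0)
    if abs(r) >= 1.0:
        warnings.warn("perfect residual-fitted correlation: p = 0", stacklevel=2)
        return HOSResult(np.inf, 1, 0.0, "slope_vs_b0")
    F = r * r * (n - 2) / (1 - r * r)
    p = float(stats.f.sf(F, 1, n - 2))
    return HOSResult(float(F), 1, p, "slope_vs_b0")


test_isometry.__test__ = False  # statistical test, not a pytest case


def _lr_profile(groups: list[tuple[np.ndarray, np.ndarray]]):
    def lr(b: float) -> float:
        tot = 0.0
        for x, y in groups:
            r = _resid_fitted_corr(x, y, b)
            r2 = min(r * r, 1 - 1e-15)
            tot += -len(x) * np.log1p(-r2)
        return tot
    return lr


def common_slope_lr_test(
    groups: list[tuple[np.ndarray, np.ndarray]],
    tol: float = 1e-10,
) -> HOSResult:
    """Likelihood-ratio homogeneity-of-slopes test across g groups.

    The common slope minimises LR(b); the minimised LR is referred to a
    chi-square with g-1 degrees of freedom. LR(b_hat) = 0 exactly when all
    group SMA slopes agree, since each group's residual-fitted correlation
    vanishes at its own slope.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    fits = []
    for i, (x, y) in enumerate(groups):
        if len(x) < 3:
            raise ValueError(f"group {i} has n < 3")
        fits.append(sma_fit(x, y))
    slopes = np.array([f.slope for f in fits])
    lr = _lr_profile(groups)

    if np.all(slopes > 0) or np.all(slopes < 0):
        # golden-section on log|b| over a bracket spanning all group slopes
        sgn = np.sign(slopes[0])
        lo = np.log(np.abs(slopes).min() / 3.0)
        hi = np.log(np.abs(slopes).max() * 3.0)
        res = optimize.minimize_scalar(
            lambda u: lr(sgn * np.exp(u)), bounds=(lo, hi), method="bounded",
            options={"xatol": tol})
        b_hat = float(sgn * np.exp(res.x))
    else:
        span = max(1.0, np.abs(slopes).max()) * 3.0
        res = optimize.minimize_scalar(
            lr, bounds=(-span, span), method="bounded", options={"xatol": tol})
        b_hat = float(res.x)
    if not res.success:  # pragma: no cover - bounded Brent always converges
        raise RuntimeError(f"common-slope optimisation failed: {res.message}")

    stat = max(float(lr(b_hat)), 0.0)
    dfree = len(groups) - 1
    p = float(stats.chi2.sf(stat, dfree))
    return HOSResult(stat, dfree, p, "common_slope_LR", common_slope=b_hat,
                     group_estimates={i: f.slope for i, f in enumerate(fits)})


def _common_slope_var(groups, b_hat: float) -> float:
    """Sampling variance of the common slope from the observed information:
    inverse numerical second derivative of LR(b)/2 at b_hat."""
    lr = _lr_profile(groups)
    h = 1e-5 * max(abs(b_hat), 1e-8)
    d2 = (lr(b_hat + h) - 2 * lr(b_hat) + lr(b_hat - h)) / (h * h) / 2.0
    if d2 <= 0:
        raise ValueError("non-positive curvature at common slope")
    return 1.0 / d2


def elevation_wald_test(
    groups: list[tuple[np.ndarray, np.ndarray]],
    common_slope: float | None = None,
) -> HOSResult:
    """Wald test of equal intercepts at the common SMA slope.

    Group intercepts a_g = ybar_g - b_hat xbar_g share the slope estimate, so
    their covariance couples through var(b_hat): var(a_g) = s2_rg/n_g +
    xbar_g^2 var(b), cov(a_g, a_h) = xbar_g xbar_h var(b).
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if common_slope is None:
        common_slope = common_slope_lr_test(groups).common_slope
    b = float(common_slope)
    var_b = _common_slope_var(groups, b)
    xbar = np.array([np.mean(x) for x, _ in groups])
    abar = np.array([np.mean(y) - b * np.mean(x) for x, y in groups])
    n = np.array([len(x) for x, _ in groups], dtype=float)
    s2r = np.array([np.var(y - b * x, ddof=1) for x, y in groups])
    g = len(groups)
    cov = np.outer(xbar, xbar) * var_b
    cov[np.diag_indices(g)] = s2r / n + xbar ** 2 * var_b
    # contrasts: differences to group 0
    D = np.zeros((g - 1, g))
    D[:, 0] = -1.0
    D[np.arange(g - 1), np.arange(1, g)] = 1.0
    d = D @ abar
    C = D @ cov @ D.T
    try:
        W = float(d @ np.linalg.solve(C, d))
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular intercept covariance") from exc
    p = float(stats.chi2.sf(W, g - 1))
    return HOSResult(W, g - 1, p, "elevation_Wald", common_slope=b,
                     group_estimates={i: float(a) for i, a in enumerate(abar)})


def sidak(p: np.ndarray, m: int | None = None) -> np.ndarray:
    """Sidak family-wise adjustment: p_adj = 1 - (1 - p)^m."""
    p = np.asarray(p, float)
    if m is None:
        m = p.size
    return -np.expm1(m * np.log1p(-np.minimum(p, 1.0)))


def composite_shape_score(shape: ShapeData, mask: np.ndarray) -> np.ndarray:
    """PC1 of the log-shape-ratio matrix over the masked specimens,
    sign-aligned to log size. This is the bivariate response used in the
    pooled HOS tests."""
    Y = shape.y[mask]
    x = shape.x[mask]
    Yc = Y - Y.mean(axis=0)
    _, _, vt = np.linalg.svd(Yc, full_matrices=False)
    s = Yc @ vt[0]
    if len(x) > 1 and np.ptp(x) > 0 and s.std() > 0 and np.corrcoef(s, x)[0, 1] < 0:
        s = -s
    return s


def pairwise_hos(
    shape: ShapeData,
    units: np.ndarray,
    alpha: float = 0.05,
    min_n: int = 3,
) -> pd.DataFrame:
    """All unordered pairwise slope (and, where homogeneous, elevation)
    comparisons among units, Sidak-corrected within each test family.

    ``units`` is a per-specimen label array (species, order, diet or
    partition x diet cell). For each pair, the composite shape score is
    recomputed over that pair's specimens so each comparison is a bivariate
    (log size, composite shape) HOS test. Returns a long-format table.
    """
    units = np.asarray(units)
    labels = sorted(np.unique(units))
    sizes = {u: int((units == u).sum()) for u in labels}
    usable = [u for u in labels if sizes[u] >= min_n]
    skipped = [u for u in labels if sizes[u] < min_n]
    if skipped:
        warnings.warn(f"units below minimum size skipped: {skipped}", stacklevel=2)
    pairs = list(combinations(usable, 2))
    rows = []
    for a, b in pairs:
        mask = (units == a) | (units == b)
        s = composite_shape_score(shape, mask)
        x = shape.x[mask]
        ua = (units[mask] == a)
        ga = (x[ua], s[ua])
        gb = (x[~ua], s[~ua])
        try:
            slope = common_slope_lr_test([ga, gb])
        except ValueError as exc:
            warnings.warn(f"pair ({a}, {b}) slope test failed: {exc}", stacklevel=2)
            continue
        row = {"unit_a": a, "unit_b": b, "test": "slope",
               "statistic": slope.statistic, "df": slope.df, "p": slope.p,
               "common_slope": slope.common_slope}
        rows.append(row)
        if slope.p >= alpha:  # slopes homogeneous: elevation is interpretable
            try:
                elev = elevation_wald_test([ga, gb], slope.common_slope)
            except ValueError:
                continue
            rows.append({"unit_a": a, "unit_b": b, "test": "elevation",
                         "statistic": elev.statistic, "df": elev.df,
                         "p": elev.p, "common_slope": slope.common_slope})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    for test in out["test"].unique():
        m = out["test"] == test
        out.loc[m, "p_adj"] = sidak(out.loc[m, "p"].to_numpy(), int(m.sum()))
    out["significant"] = out["p_adj"] < alpha
    return out
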
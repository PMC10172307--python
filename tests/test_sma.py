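import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from allometree.sma import (common_slope_lr_test, elevation_wald_test,
                            sidak, sma_fit)
from allometree.sma import test_isometry as isometry_test


def test_sma_exact_line():
    x = np.array([0.0, 1.0, 2.0, 3.0])
    fit = sma_fit(x, 2 * x + 1)
    assert fit.slope == pytest.approx(2.0, rel=1e-12)
    assert fit.intercept == pytest.approx(1.0, rel=1e-12)


def test_sma_closed_form_and_symmetry():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.array([1.2, 1.9, 3.2, 3.7])
    fit = sma_fit(x, y)
    expect = np.sqrt(np.var(y, ddof=1) / np.var(x, ddof=1))
    assert fit.slope == pytest.approx(expect, rel=1e-12)
    assert fit.slope > 0
    # swapping x and y inverts the slope
    assert sma_fit(y, x).slope == pytest.approx(1.0 / fit.slope, rel=1e-12)


def test_sma_zero_variance_raises():
    with pytest.raises(ValueError):
        sma_fit(np.ones(5), np.arange(5.0))


def test_isometry_detects_steep_slope():
    rng = np.random.default_rng(0)
    x = rng.normal(0, 1, 200)
    y = 3 * x + rng.normal(0, 1, 200)
    res = isometry_test(x, y, b0=1.0)
    assert res.p < 0.01


def test_isometry_degenerate_perfect_line_raises():
    x = np.linspace(0, 1, 10)
    with pytest.raises(ValueError):
        isometry_test(x, 1.0 * x, b0=1.0)


def test_common_slope_zero_on_identical_groups():
    rng = np.random.default_rng(1)
    x = rng.normal(0, 1, 40)
    y = 1.5 * x + rng.normal(0, 0.3, 40)
    res = common_slope_lr_test([(x, y), (x.copy(), y.copy())])
    assert res.statistic == pytest.approx(0.0, abs=1e-8)
    assert res.p == pytest.approx(1.0, abs=1e-6)


def test_common_slope_matches_grid_search():
    rng = np.random.default_rng(2)
    groups = []
    for slope in (1.2, 1.8, 1.5):
        x = rng.normal(0, 1, 30)
        groups.append((x, slope * x + rng.normal(0, 0.4, 30)))
    res = common_slope_lr_test(groups)

    def lr(b):
        tot = 0.0
        for x, y in groups:
            r = np.corrcoef(y - b * x, y + b * x)[0, 1]
            tot += -len(x) * np.log(1 - r * r)
        return tot

    grid = np.linspace(0.8, 2.5, 200001)
    vals = np.array([lr(b) for b in grid[:: 400]])  # coarse pass
    b0 = grid[::400][vals.argmin()]
    fine = np.linspace(b0 - 0.01, b0 + 0.01, 20001)
    best = min(lr(b) for b in fine)
    assert res.statistic == pytest.approx(best, abs=1e-6)


def test_elevation_wald_identical_groups_zero():
    rng = np.random.default_rng(3)
    x = rng.normal(0, 1, 50)
    y = 2 * x + rng.normal(0, 0.5, 50)
    res = elevation_wald_test([(x, y), (x.copy(), y.copy())])
    assert res.statistic == pytest.approx(0.0, abs=1e-8)
    assert res.p == pytest.approx(1.0, abs=1e-6)


def test_elevation_recovers_injected_offset():
    rng = np.random.default_rng(4)
    x1 = rng.normal(0, 1, 4000)
    x2 = rng.normal(0, 1, 4000)
    d = 0.8
    g1 = (x1, 1.5 * x1 + rng.normal(0, 0.5, 4000))
    g2 = (x2, 1.5 * x2 + d + rng.normal(0, 0.5, 4000))
    res = elevation_wald_test([g1, g2])
    est = res.group_estimates[1] - res.group_estimates[0]
    assert est == pytest.approx(d, abs=0.05)
    assert res.p < 1e-6


def test_lr_and_wald_affine_invariance():
    """Common rescaling/shift of x and y across groups leaves LR and W
    unchanged."""
    rng = np.random.default_rng(5)
    groups = []
    for slope in (1.0, 1.4):
        x = rng.normal(0, 1, 35)
        groups.append((x, slope * x + rng.normal(0, 0.5, 35)))
    base_lr = common_slope_lr_test(groups)
    base_w = elevation_wald_test(groups, base_lr.common_slope)
    scaled = [(3.0 * x + 2.0, 3.0 * y - 1.0) for x, y in groups]
    s_lr = common_slope_lr_test(scaled)
    s_w = elevation_wald_test(scaled, s_lr.common_slope)
    assert s_lr.statistic == pytest.approx(base_lr.statistic, rel=1e-6)
    assert s_w.statistic == pytest.approx(base_w.statistic, rel=1e-4)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.floats(1e-6, 1.0 - 1e-9), st.integers(1, 50))
def test_sidak_monotone_and_bounded(p, m):
    adj = float(sidak(np.array([p]), m)[0])
    assert adj >= p - 1e-15
    assert adj <= 1.0
    if m == 1:
        assert adj == pytest.approx(p, rel=1e-12)
    assert float(sidak(np.array([p]), m + 1)[0]) >= adj - 1e-15
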
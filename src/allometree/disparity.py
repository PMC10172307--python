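"""Disparity of allometric trajectories: Procrustes variance and permutation
tests.

Procrustes variance (PV) of a group is the trace of its covariance matrix
with divisor n_g — equivalently the mean squared distance of the group's
points from their centroid — which makes group sizes comparable. Group
differences are tested by permuting group labels and comparing absolute PV
differences. PV is rotation-invariant, so computing it on all PC scores or
on the raw coefficient vectors gives identical values; the full coefficient
space is the default here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DisparityResult", "procrustes_variance",
           "disparity_permutation_test", "residual_disparity"]


@dataclass
class DisparityResult:
    pv: dict
    pairwise_delta: pd.DataFrame
    pairwise_p: pd.DataFrame
    iterations: int
    seed: int


def _pv(points: np.ndarray) -> float:
    c = points.mean(axis=0)
    return float(((points - c) ** 2).sum(axis=1).mean())


def procrustes_variance(points: np.ndarray, groups: np.ndarray) -> dict:
    """PV per group: (1/n_g) * sum_i ||z_i - zbar_g||^2."""
    points = np.atleast_2d(np.asarray(points, float))
    groups = np.asarray(groups)
    out = {}
    for g in sorted(np.unique(groups)):
        pts = points[groups == g]
        if len(pts) == 1:
            warnings.warn(f"group {g!r} has a single member: PV = 0", stacklevel=2)
        out[g] = _pv(pts)
    return out


def disparity_permutation_test(
    points: np.ndarray,
    groups: np.ndarray,
    iterations: int = 10000,
    seed: int = 0,
) -> DisparityResult:
    """Pairwise |PV_g - PV_h| permutation tests.

    For each unordered pair of groups the labels are permuted over the
    species in that comparison; p = (1 + #{null >= observed}) / (1 + N),
    which never returns an exact zero.
    """
    if iterations < 100:
        warnings.warn("fewer than 100 permutation iterations", stacklevel=2)
    points = np.atleast_2d(np.asarray(points, float))
    groups = np.asarray(groups)
    labels = sorted(np.unique(groups))
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    pv = procrustes_variance(points, groups)
    rng = np.random.default_rng(seed)
    delta = pd.DataFrame(0.0, index=labels, columns=labels)
    pmat = pd.DataFrame(1.0, index=labels, columns=labels)
    for i, g in enumerate(labels):
        for h in labels[i + 1:]:
            mask = (groups == g) | (groups == h)
            pts = points[mask]
            n_g = int((groups[mask] == g).sum())
            obs = abs(pv[g] - pv[h])
            # vectorised label permutations: first n_g shuffled rows -> group g
            perm = np.argsort(rng.random((iterations, len(pts))), axis=1)
            a = pts[perm[:, :n_g]]          # (iters, n_g, d)
            b = pts[perm[:, n_g:]]
            pv_a = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=2).mean(axis=1)
            pv_b = ((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=2).mean(axis=1)
            null = np.abs(pv_a - pv_b)
            p = (1.0 + (null >= obs - 1e-12).sum()) / (1.0 + iterations)
            delta.loc[g, h] = delta.loc[h, g] = obs
            pmat.loc[g, h] = pmat.loc[h, g] = p
    return DisparityResult(pv, delta, pmat, iterations, seed)


def residual_disparity(
    x: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    common_slope: float,
) -> dict:
    """Allometry-corrected disparity: PV of specimen-level residuals from
    each group's common-slope SMA line (divisor = specimen count).

    ``y`` is the bivariate (composite) shape score used in the HOS fit and
    ``common_slope`` the fitted common slope for this grouping family.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    groups = np.asarray(groups)
    out = {}
    for g in sorted(np.unique(groups)):
        m = groups == g
        res = y[m] - (y[m].mean() - common_slope * x[m].mean()) - common_slope * x[m]
        out[g] = float(np.mean(res ** 2))
    return out
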
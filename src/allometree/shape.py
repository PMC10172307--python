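"""Log-shape ratios and species-level ontogenetic allometric trajectories.

Size for each specimen is the geometric mean of its p linear measurements;
shape is the vector of log-shape ratios ln(m_j) - ln(GM). Because the log
geometric mean is the average of the log measurements, the p log-shape
ratios of every specimen sum to zero exactly, and ordinary least-squares
slopes of each ratio on log size therefore also sum to zero across traits:
a species' trajectory lives in a (p-1)-dimensional subspace.

Natural logarithms are used throughout; allometric slopes are invariant to
the log base, so this is purely a display convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SpecimenTable

__all__ = ["ShapeData", "TrajectoryCoefficients", "to_shape_ratios",
           "fit_species_trajectory", "fit_all_trajectories",
           "trajectory_display_scores"]


@dataclass
class ShapeData:
    """Per-specimen log size ``x`` and log-shape ratios ``y`` (n x p)."""

    specimen_id: np.ndarray
    species: np.ndarray
    x: np.ndarray
    y: np.ndarray
    traits: tuple[str, ...]

    def for_species(self, sp: str) -> "ShapeData":
        m = self.species == sp
        return ShapeData(self.specimen_id[m], self.species[m],
                         self.x[m], self.y[m], self.traits)

    def subset(self, mask: np.ndarray) -> "ShapeData":
        return ShapeData(self.specimen_id[mask], self.species[mask],
                         self.x[mask], self.y[mask], self.traits)


@dataclass
class TrajectoryCoefficients:
    """OLS trajectory of one species: slopes ``b`` and intercepts ``a`` of
    each log-shape ratio on log size, plus per-trait r^2."""

    species: str
    a: np.ndarray
    b: np.ndarray
    n: int
    r2: np.ndarray
    traits: tuple[str, ...]


def to_shape_ratios(table: SpecimenTable) -> ShapeData:
    """Transform measurements to (log size, log-shape ratios)."""
    m = table.measurements()
    logm = np.log(m)
    x = logm.mean(axis=1)          # ln of the geometric mean
    y = logm - x[:, None]
    return ShapeData(
        specimen_id=table.df["specimen_id"].to_numpy(),
        species=table.df["species"].to_numpy(),
        x=x, y=y, traits=table.traits,
    )


def _ols_multi(x: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS of each column of Y on x; returns (a, b, r2)."""
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx <= 0:
        raise ValueError("degenerate ontogenetic series: zero variance in log size")
    Yc = Y - Y.mean(axis=0)
    b = (xc @ Yc) / sxx
    a = Y.mean(axis=0) - b * x.mean()
    syy = (Yc ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(syy > 0, (b ** 2) * sxx / syy, np.nan)
    return a, b, r2


def fit_species_trajectory(shape: ShapeData) -> TrajectoryCoefficients:
    """Fit one species' multivariate trajectory (shape ratios ~ log size).

    Requires at least two distinct sizes; the slope vector ``b`` is the
    species' point in allometric space.
    """
    sp = np.unique(shape.species)
    if len(sp) != 1:
        raise ValueError("fit_species_trajectory expects exactly one species")
    if len(shape.x) < 2 or np.ptp(shape.x) == 0:
        raise ValueError("degenerate ontogenetic series: need >= 2 distinct sizes")
    a, b, r2 = _ols_multi(shape.x, shape.y)
    return TrajectoryCoefficients(str(sp[0]), a, b, len(shape.x), r2, shape.traits)


def fit_all_trajectories(shape: ShapeData) -> list[TrajectoryCoefficients]:
    return [fit_species_trajectory(shape.for_species(sp))
            for sp in sorted(np.unique(shape.species))]


def coefficients_frame(coeffs: list[TrajectoryCoefficients]) -> pd.DataFrame:
    """Long-to-wide export: species x [a_*, b_*, n]."""
    traits = coeffs[0].traits
    rows = []
    for c in coeffs:
        row = {"species": c.species, "n": c.n}
        row.update({f"a_{t}": v for t, v in zip(traits, c.a)})
        row.update({f"b_{t}": v for t, v in zip(traits, c.b)})
        rows.append(row)
    return pd.DataFrame(rows)


def trajectory_display_scores(
    shape: ShapeData,
    grouping: np.ndarray | None = None,
    global_axes: bool = False,
) -> pd.DataFrame:
    """Per-specimen (x, PC1-of-fitted-values) for trajectory plots.

    For each group (default: species) the multivariate regression of shape
    on size is fitted, and specimens are scored on PC1 of the fitted-value
    matrix, sign-fixed so the score correlates positively with size. With
    ``global_axes`` the PCA is computed once on the pooled fitted values and
    all groups are projected onto that common axis.
    """
    groups = shape.species if grouping is None else np.asarray(grouping)
    out = []
    fitted_all, meta_all = [], []
    for g in sorted(np.unique(groups)):
        m = groups == g
        if m.sum() < 3:
            import warnings
            warnings.warn(f"group {g!r} has <3 specimens; skipped", stacklevel=2)
            continue
        x, Y = shape.x[m], shape.y[m]
        if np.ptp(x) == 0:
            import warnings
            warnings.warn(f"group {g!r} has zero size variance; skipped", stacklevel=2)
            continue
        a, b, _ = _ols_multi(x, Y)
        F = a[None, :] + np.outer(x, b)
        fitted_all.append(F)
        meta_all.append((g, m, x))
    if global_axes:
        pooled = np.vstack(fitted_all)
        center = pooled.mean(axis=0)
        _, _, vt = np.linalg.svd(pooled - center, full_matrices=False)
        axis = vt[0]
        for (g, m, x), F in zip(meta_all, fitted_all):
            s = (F - center) @ axis
            if len(x) > 1 and np.ptp(x) > 0 and np.corrcoef(s, x)[0, 1] < 0:
                s = -s
            out.append(pd.DataFrame({
                "specimen_id": shape.specimen_id[m], "group": g, "x": x, "pc1": s}))
    else:
        for (g, m, x), F in zip(meta_all, fitted_all):
            Fc = F - F.mean(axis=0)
            if np.allclose(Fc, 0):
                s = np.zeros(len(x))
            else:
                _, sv, vt = np.linalg.svd(Fc, full_matrices=False)
                s = Fc @ vt[0]
                if np.ptp(x) > 0 and np.corrcoef(s, x)[0, 1] < 0:
                    s = -s
            out.append(pd.DataFrame({
                "specimen_id": shape.specimen_id[m], "group": g, "x": x, "pc1": s}))
    return pd.concat(out, ignore_index=True)
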
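"""Allometric space: PCA over species' allometric-coefficient vectors.

Each species contributes its p-vector of ontogenetic allometric slopes; a
covariance PCA (no unit-variance scaling, since all coefficients are log-log
slopes sharing a scale) places every species as one point. The origin is the
mean trajectory, so positive/negative loadings read directly as faster or
slower than average growth of a trait. Axis retention uses the broken-stick
rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .shape import TrajectoryCoefficients

__all__ = ["AllometricSpace", "build_space", "broken_stick_axes",
           "broken_stick_fractions"]


@dataclass
class AllometricSpace:
    species: list[str]
    scores: np.ndarray        # n_species x k
    loadings: np.ndarray      # p x k, orthonormal columns
    var_fraction: np.ndarray  # k, non-increasing, sums to 1
    eigenvalues: np.ndarray   # k
    center: np.ndarray        # p
    traits: tuple[str, ...]

    def scores_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores,
                          columns=[f"PC{i+1}" for i in range(self.scores.shape[1])])
        df.insert(0, "species", self.species)
        return df

    def loadings_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.loadings,
                          columns=[f"PC{i+1}" for i in range(self.loadings.shape[1])])
        df.insert(0, "trait", list(self.traits))
        return df


def build_space(coeffs: list[TrajectoryCoefficients]) -> AllometricSpace:
    """Covariance PCA of the species x p slope matrix.

    Sign convention: the largest-magnitude element of each loading column is
    made positive, so output is deterministic across platforms.
    """
    if len(coeffs) < 3:
        raise ValueError("allometric space needs >= 3 species")
    p = len(coeffs[0].b)
    if any(len(c.b) != p for c in coeffs):
        raise ValueError("coefficient vectors differ in length")
    species = [c.species for c in coeffs]
    B = np.array([c.b for c in coeffs])
    center = B.mean(axis=0)
    Bc = B - center
    if np.allclose(Bc, 0):
        raise ValueError("rank-zero coefficient matrix")
    u, s, vt = np.linalg.svd(Bc, full_matrices=False)
    k = int((s > s[0] * 1e-12).sum())
    u, s, vt = u[:, :k], s[:k], vt[:k]
    # deterministic sign: largest |loading| positive per axis
    flip = np.sign(vt[np.arange(k), np.abs(vt).argmax(axis=1)])
    vt = vt * flip[:, None]
    u = u * flip[None, :]
    n = len(coeffs)
    eig = s ** 2 / (n - 1)
    return AllometricSpace(
        species=species,
        scores=u * s,
        loadings=vt.T,
        var_fraction=eig / eig.sum(),
        eigenvalues=eig,
        center=center,
        traits=coeffs[0].traits,
    )


def broken_stick_fractions(p: int) -> np.ndarray:
    """Expected variance fraction of axis i out of p under the broken-stick
    null: bs_i = (1/p) * sum_{j=i..p} 1/j."""
    inv = 1.0 / np.arange(1, p + 1)
    return np.cumsum(inv[::-1])[::-1] / p


def broken_stick_axes(space: AllometricSpace, p: int | None = None) -> int:
    """Number of leading axes whose observed variance fraction strictly
    exceeds the broken-stick expectation (the leading run only)."""
    if p is None:
        p = len(space.traits)
    bs = broken_stick_fractions(p)
    k = 0
    for i, frac in enumerate(space.var_fraction):
        if i < p and frac > bs[i]:
            k += 1
        else:
            break
    return k


def significant_axes(space: AllometricSpace, cap: int = 4) -> int:
    """Axes used by downstream convergence/model stages:
    min(broken-stick k*, cap), but at least 1."""
    return max(1, min(broken_stick_axes(space), cap))
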
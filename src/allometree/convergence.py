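"""Phylogenetic convergence tests on allometric-space positions.

Two complementary approaches:

* distance-based indices C1-C4. For a focal pair of tips, Dtip is their
  phenotypic distance and Dmax the maximum distance between reconstructed
  states (nodes and tips) on the two paths from their MRCA. C1 = 1 -
  Dtip/Dmax measures how much subsequent evolution closed the largest gap;
  C2 = Dmax - Dtip its magnitude; C3 and C4 scale C2 by the total
  branch-wise phenotypic change along the two paths and over the whole
  clade rooted at the MRCA, respectively. Significance comes from
  simulating Brownian motion on the tree with a rate matrix estimated from
  the data (independent contrasts) and asking how often simulated indices
  reach the observed ones.

* angle-based within-state convergence: the mean angle between the
  mean-centred phenotype vectors of species pairs sharing a state (e.g. a
  diet), optionally scaled by the patristic time separating them; small
  angles indicate convergent directions. Significance by permuting state
  labels across tips.

Ancestral states are maximum-likelihood reconstructions under Brownian
motion (the GLS solution), computed through a single linear map from tip
values so that hundreds of simulated datasets can be reconstructed with one
matrix product.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tree import Phylo

__all__ = ["ConvergenceResult", "AngleConvergenceResult",
           "ancestral_states_bm", "ancestral_linear_map", "pic_rate_matrix",
           "c_metrics", "c_significance", "simulate_bm_tips",
           "angle_state_convergence"]

C_NAMES = ("C1", "C2", "C3", "C4")


@dataclass
class ConvergenceResult:
    C: dict
    p: dict
    pairs: pd.DataFrame
    focal: tuple[str, ...]
    n_sims: int = 0
    seed: int | None = None


@dataclass
class AngleConvergenceResult:
    state: str
    ang_state: float
    ang_state_time: float
    p_ang: float
    p_ang_time: float
    pairs: pd.DataFrame = field(default_factory=pd.DataFrame)
    n_null: int = 0
    seed: int | None = None


# -- ancestral reconstruction ---------------------------------------------

def _safe_tree(tree: Phylo) -> Phylo:
    zero_term = [i for i in range(tree.n_tips) if tree.edge_len[i] == 0]
    if zero_term:
        warnings.warn(
            f"{len(zero_term)} zero-length terminal branches perturbed",
            stacklevel=3)
        edge = tree.edge_len.copy()
        edge[zero_term] = 1e-8 * max(tree.height, 1.0)
        return Phylo(tree.labels, tree.parent, edge)
    return tree


def ancestral_linear_map(tree: Phylo) -> np.ndarray:
    """(n_nodes x n_tips) matrix M with states = M @ tip_values.

    Rows for tips are unit vectors; rows for internal nodes give the ML/GLS
    Brownian-motion reconstruction conditional on the tips, with the root
    mean itself GLS-estimated.
    """
    tree = _safe_tree(tree)
    n = tree.n_tips
    C_all = tree.vcv_all()
    Ctt = C_all[:n, :n]
    Cnt = C_all[n:, :n]
    Cinv = np.linalg.inv(Ctt)
    one = np.ones(n)
    w = Cinv @ one / (one @ Cinv @ one)      # GLS root-mean weights
    A = Cnt @ Cinv
    M_int = A + np.outer(1.0 - A @ one, w)
    return np.vstack([np.eye(n), M_int])


def ancestral_states_bm(tree: Phylo, tip_matrix: np.ndarray) -> np.ndarray:
    """ML-under-BM states for every node, (n_nodes x k); rows 0..n_tips-1
    are the observed tips."""
    X = np.atleast_2d(np.asarray(tip_matrix, float))
    if X.shape[0] != tree.n_tips:
        raise ValueError("tip matrix rows must match tree tips")
    return ancestral_linear_map(tree) @ X


def pic_rate_matrix(tree: Phylo, tip_matrix: np.ndarray) -> np.ndarray:
    """BM rate matrix from phylogenetically independent contrasts."""
    tree = _safe_tree(tree)
    X = np.atleast_2d(np.asarray(tip_matrix, float))
    k = X.shape[1]
    vals = np.zeros((tree.n_nodes, k))
    vals[: tree.n_tips] = X
    # blen[v] = v's branch length plus the pruning correction from below
    blen = tree.edge_len.astype(float).copy()
    contrasts = []
    for v in tree.postorder:
        kids = tree.children[v]
        if not kids:
            continue
        # fold children in pairwise (handles multifurcations)
        val, b = vals[kids[0]], blen[kids[0]]
        for c in kids[1:]:
            contrasts.append((val - vals[c]) / np.sqrt(b + blen[c]))
            val = (val / b + vals[c] / blen[c]) / (1.0 / b + 1.0 / blen[c])
            b = b * blen[c] / (b + blen[c])
        vals[v] = val
        blen[v] = tree.edge_len[v] + b
    U = np.array(contrasts)
    R = U.T @ U / len(U)
    # nearest-PD repair if estimation returned a non-PD matrix
    w, V = np.linalg.eigh((R + R.T) / 2)
    if w.min() <= 0:
        warnings.warn("non-positive-definite rate estimate repaired", stacklevel=2)
        w = np.clip(w, 1e-10 * max(w.max(), 1e-10), None)
        R = V @ np.diag(w) @ V.T
    return R


def simulate_bm_tips(tree: Phylo, R: np.ndarray, n_sims: int,
                     rng: np.random.Generator) -> np.ndarray:
    """(n_sims, n_tips, k) Brownian-motion tip values, root at the origin."""
    C = _safe_tree(tree).vcv()
    Lc = np.linalg.cholesky(C + 1e-12 * np.eye(len(C)) * max(tree.height, 1.0))
    Lr = np.linalg.cholesky(R + 1e-12 * np.trace(R) / len(R) * np.eye(len(R)))
    Z = rng.standard_normal((n_sims, tree.n_tips, R.shape[0]))
    return np.einsum("ij,sjk,lk->sil", Lc, Z, Lr)


# -- C1-C4 ----------------------------------------------------------------

class _FocalPaths:
    """Precomputed path/clade index structure for a focal tip set."""

    def __init__(self, tree: Phylo, focal_idx: np.ndarray,
                 pair_idx: list | None = None):
        if pair_idx is None:
            pair_idx = [(int(focal_idx[i]), int(focal_idx[j]))
                        for i in range(len(focal_idx))
                        for j in range(i + 1, len(focal_idx))]
        self.pairs = []
        for s, t in pair_idx:
                m = tree.mrca(s, t)
                path_s = self._down_path(tree, m, s)
                path_t = self._down_path(tree, m, t)
                clade = tree.clade_nodes(m)
                clade_child = np.array([v for v in clade if v != m], dtype=int)
                clade_parent = tree.parent[clade_child]
                lin_child = np.array(path_s[1:] + path_t[1:], dtype=int)
                lin_parent = tree.parent[lin_child]
                self.pairs.append({
                    "s": s, "t": t, "mrca": m,
                    "path_s": np.array(path_s, dtype=int),
                    "path_t": np.array(path_t, dtype=int),
                    "lin_child": lin_child, "lin_parent": lin_parent,
                    "clade_child": clade_child, "clade_parent": clade_parent,
                })

    @staticmethod
    def _down_path(tree: Phylo, top: int, tip: int) -> list[int]:
        path = []
        v = tip
        while v != top:
            path.append(v)
            v = tree.parent[v]
        path.append(top)
        return path[::-1]

    def metrics(self, states: np.ndarray) -> tuple[dict, list[dict]]:
        """C1-C4 averaged over focal pairs for one (n_nodes x k) state set."""
        per_pair = []
        for pr in self.pairs:
            dtip = float(np.linalg.norm(states[pr["s"]] - states[pr["t"]]))
            A = states[pr["path_s"]]
            B = states[pr["path_t"]]
            diff = A[:, None, :] - B[None, :, :]
            dmax = float(np.sqrt((diff ** 2).sum(-1)).max())
            rec = {"tip_a": pr["s"], "tip_b": pr["t"],
                   "Dtip": dtip, "Dmax": dmax}
            if dmax <= 0:
                warnings.warn("Dmax = 0: C indices undefined for a pair",
                              stacklevel=3)
                rec.update({c: np.nan for c in C_NAMES})
                per_pair.append(rec)
                continue
            c2 = dmax - dtip
            lin_change = float(np.linalg.norm(
                states[pr["lin_child"]] - states[pr["lin_parent"]], axis=1).sum())
            clade_change = float(np.linalg.norm(
                states[pr["clade_child"]] - states[pr["clade_parent"]], axis=1).sum())
            rec["C1"] = 1.0 - dtip / dmax
            rec["C2"] = c2
            rec["C3"] = c2 / lin_change if lin_change > 0 else np.nan
            rec["C4"] = c2 / clade_change if clade_change > 0 else np.nan
            per_pair.append(rec)
        avg = {c: float(np.nanmean([r[c] for r in per_pair])) for c in C_NAMES}
        return avg, per_pair


def _pair_idx(tree: Phylo, pairs) -> list | None:
    if pairs is None:
        return None
    lut = {lab: i for i, lab in enumerate(tree.labels)}
    return [(lut[a], lut[b]) for a, b in pairs]


def c_metrics(tree: Phylo, tip_matrix: np.ndarray, focal: list[str],
              pairs: list | None = None) -> ConvergenceResult:
    """Distance-based convergence indices for a focal tip set.

    ``pairs`` optionally restricts the evaluated focal pairs (e.g. to
    cross-partition pairs only); default is all unordered pairs.
    """
    if len(focal) < 2:
        raise ValueError("focal set needs >= 2 tips")
    idx = tree.tip_index(focal)
    states = ancestral_states_bm(tree, tip_matrix)
    paths = _FocalPaths(tree, idx, _pair_idx(tree, pairs))
    avg, per_pair = paths.metrics(states)
    pairs = pd.DataFrame(per_pair)
    if not pairs.empty:
        pairs["tip_a"] = [tree.labels[i] for i in pairs["tip_a"]]
        pairs["tip_b"] = [tree.labels[i] for i in pairs["tip_b"]]
    return ConvergenceResult(avg, {}, pairs, tuple(focal))


def c_significance(
    tree: Phylo,
    tip_matrix: np.ndarray,
    focal: list[str],
    n_sims: int = 300,
    seed: int = 0,
    pairs: list | None = None,
) -> ConvergenceResult:
    """C1-C4 with Brownian-motion null p-values.

    The BM rate matrix is estimated from the observed tips by independent
    contrasts; ``n_sims`` datasets are simulated on the tree and each index's
    p-value is the proportion of simulations reaching the observed value.
    """
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    res = c_metrics(tree, tip_matrix, focal, pairs)
    idx = tree.tip_index(focal)
    paths = _FocalPaths(tree, idx, _pair_idx(tree, pairs))
    R = pic_rate_matrix(tree, tip_matrix)
    rng = np.random.default_rng(seed)
    sims = simulate_bm_tips(tree, R, n_sims, rng)
    M = ancestral_linear_map(tree)
    all_states = np.einsum("Nn,snk->sNk", M, sims)
    counts = {c: 0 for c in C_NAMES}
    for s in range(n_sims):
        avg, _ = paths.metrics(all_states[s])
        for c in C_NAMES:
            if not np.isnan(avg[c]) and avg[c] >= res.C[c] - 1e-12:
                counts[c] += 1
    res.p = {c: counts[c] / n_sims for c in C_NAMES}
    res.n_sims = n_sims
    res.seed = seed
    return res


# -- angle-based convergence ----------------------------------------------

def angle_state_convergence(
    tree: Phylo,
    tip_matrix: np.ndarray,
    states: dict,
    state: str,
    partitions: dict | None = None,
    n_null: int = 300,
    seed: int = 0,
    all_pairs: bool = False,
    center: np.ndarray | None = None,
) -> AngleConvergenceResult:
    """Mean angle between phenotype vectors of species sharing a state.

    Vectors are measured from ``center`` (default: the grand mean of the tip
    matrix, i.e. the origin of allometric space). With ``partitions`` given
    and ``all_pairs`` False, only cross-partition pairs are compared — the
    convergence question between the two sides of the tree. The null permutes
    state labels across tips; small mean angles indicate convergence, so p is
    the fraction of null means at or below the observed mean.
    """
    X = np.atleast_2d(np.asarray(tip_matrix, float))
    labels = tree.labels
    if center is None:
        center = X.mean(axis=0)
    V = X - center
    state_arr = np.array([states[lab] for lab in labels])
    part_arr = (np.array([partitions[lab] for lab in labels])
                if partitions is not None else None)
    patr = tree.patristic()

    def pair_indices(st: np.ndarray) -> list[tuple[int, int]]:
        members = np.flatnonzero(st == state)
        out = []
        for ii in range(len(members)):
            for jj in range(ii + 1, len(members)):
                a, b = int(members[ii]), int(members[jj])
                if (all_pairs or part_arr is None
                        or part_arr[a] != part_arr[b]):
                    out.append((a, b))
        return out

    def angles(prs: list[tuple[int, int]]):
        th, tht, keep = [], [], []
        for a, b in prs:
            na, nb = np.linalg.norm(V[a]), np.linalg.norm(V[b])
            if na == 0 or nb == 0:
                warnings.warn("zero-norm phenotype vector: pair skipped",
                              stacklevel=3)
                continue
            cosang = np.clip(V[a] @ V[b] / (na * nb), -1.0, 1.0)
            t = float(np.degrees(np.arccos(cosang)))
            th.append(t)
            tht.append(t / patr[a, b])
            keep.append((a, b))
        return th, tht, keep

    obs_pairs = pair_indices(state_arr)
    if not obs_pairs:
        raise ValueError(f"no valid pairs for state {state!r}")
    th, tht, keep = angles(obs_pairs)
    if not th:
        raise ValueError(f"no usable pairs for state {state!r}")
    ang = float(np.mean(th))
    ang_t = float(np.mean(tht))

    rng = np.random.default_rng(seed)
    hits = hits_t = valid = 0
    for _ in range(n_null):
        perm = rng.permutation(len(labels))
        th0, tht0, _ = angles(pair_indices(state_arr[perm]))
        if not th0:
            continue
        valid += 1
        if np.mean(th0) <= ang + 1e-12:
            hits += 1
        if np.mean(tht0) <= ang_t + 1e-12:
            hits_t += 1
    p = (1 + hits) / (1 + valid) if valid else np.nan
    p_t = (1 + hits_t) / (1 + valid) if valid else np.nan
    pairs = pd.DataFrame(
        [{"tip_a": labels[a], "tip_b": labels[b], "angle_deg": t,
          "angle_per_myr": tt, "patristic_myr": patr[a, b]}
         for (a, b), t, tt in zip(keep, th, tht)])
    return AngleConvergenceResult(state, ang, ang_t, p, p_t, pairs,
                                  n_null=valid, seed=seed)
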
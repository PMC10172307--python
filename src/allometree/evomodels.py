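"""Multivariate trait-evolution model fitting on allometric-space scores.

Twelve competing models are fitted to the species x k score matrix on a
time-calibrated ultrametric tree and ranked by small-sample-corrected AIC:

* ``EB`` — early burst: Brownian motion whose rate decays as exp(r t), r <= 0;
* ``BM1`` — single-rate Brownian motion;
* ``BMMs``/``BMMd``/``BMMsd`` — multi-rate BM with regime-specific rate
  matrices painted by partition, diet, or their interaction;
* ``BMMsm``/``BMMdm``/``BMMsdm`` — BM with regime-specific expected tip
  values ("multiple ancestral states") for the same three paintings;
* ``OU1``/``OUs``/``OUd``/``OUsd`` — Ornstein-Uhlenbeck with per-trait
  attraction strengths alpha and one set of optima, or regime-specific
  optima for the three paintings.

Conventions (documented in the methods note): multi-rate matrices are
proportional, R_regime = s_regime * R, which keeps the covariance
Kronecker-factorable so the base rate matrix profiles out analytically;
OU uses a diagonal attraction matrix (one alpha per trait) with a full
rate matrix R, a fixed root equal to the root regime's optimum, and optima
estimated by GLS; regime histories come from stochastic character mapping
under an equal-rates Markov model, and regime-model likelihoods are
averaged over ``n_maps`` sampled histories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .tree import Phylo

__all__ = ["RegimePainting", "EvoModelFit", "paint_regimes", "model_loglik",
           "fit_all_models", "MODEL_NAMES", "n_parameters", "aicc"]

MODEL_NAMES = ("EB", "BM1", "BMMs", "BMMd", "BMMsd", "BMMsm", "BMMdm",
               "BMMsdm", "OU1", "OUs", "OUd", "OUsd")

_LOG2PI = np.log(2 * np.pi)


# ---------------------------------------------------------------------------
# regime paintings
# ---------------------------------------------------------------------------

@dataclass
class RegimePainting:
    """Branch-wise regime history.

    ``segments[v]`` lists (state_index, duration) pairs for the branch above
    node ``v``, ordered from the parent end to the child end; durations sum
    to the branch length. ``root_state`` is the regime at the root point.
    """

    states: tuple[str, ...]
    segments: list[list[tuple[int, float]]]
    root_state: int
    source: str = "simmap"
    seed: int | None = None

    @property
    def n_states(self) -> int:
        return len(self.states)

    def tip_state(self, v: int) -> int:
        return self.segments[v][-1][0]

    def used_states(self) -> list[int]:
        """Regime indices that actually occur (positive painted time or the
        root state); product paintings can leave some combinations unused."""
        used = {self.root_state}
        for segs in self.segments:
            for s, d in segs:
                if d > 0:
                    used.add(s)
        return sorted(used)

    def regime_times(self, tree: Phylo) -> np.ndarray:
        """(n_nodes x m) cumulative time spent in each regime on the path
        from the root down to each node."""
        acc = np.zeros((tree.n_nodes, self.n_states))
        for v in tree.preorder:
            p = tree.parent[v]
            if p < 0:
                continue
            acc[v] = acc[p]
            for s, d in self.segments[v]:
                acc[v, s] += d
        return acc

    def flat_segments(self, tree: Phylo) -> tuple[np.ndarray, ...]:
        """Per-tip expansion of root-to-tip segment times, flattened for the
        Hansen weight computation: arrays (tip, state, t0, t1) where t0/t1
        are depths of the segment's ends."""
        tips, sts, t0s, t1s = [], [], [], []
        for i in range(tree.n_tips):
            path = []
            v = i
            while tree.parent[v] >= 0:
                path.append(v)
                v = tree.parent[v]
            for v in path[::-1]:
                t = tree.depth[tree.parent[v]]
                for s, d in self.segments[v]:
                    tips.append(i)
                    sts.append(s)
                    t0s.append(t)
                    t1s.append(t + d)
                    t += d
        return (np.array(tips, int), np.array(sts, int),
                np.array(t0s, float), np.array(t1s, float))


def _er_transition(m: int, q: float, t: np.ndarray | float) -> tuple:
    """Equal-rates Mk transition probabilities: returns (p_same, p_diff)."""
    e = np.exp(-m * q * t)
    return 1.0 / m + (1 - 1.0 / m) * e, (1.0 - e) / m


def _mk_er_loglik(tree: Phylo, tip_idx: np.ndarray, m: int, q: float) -> float:
    L = np.zeros((tree.n_nodes, m))
    L[np.arange(tree.n_tips), tip_idx] = 1.0
    for v in tree.postorder:
        if v < tree.n_tips:
            continue
        acc = np.ones(m)
        for c in tree.children[v]:
            ps, pd_ = _er_transition(m, q, tree.edge_len[c])
            # P @ L[c] for ER: pd*sum + (ps-pd)*L[c]
            acc *= pd_ * L[c].sum() + (ps - pd_) * L[c]
        L[v] = acc
    root = L[tree.root]
    tot = root.mean()  # uniform root prior
    return float(np.log(max(tot, 1e-300)))


def paint_regimes(
    tree: Phylo,
    states: dict,
    n_maps: int = 10,
    seed: int = 0,
) -> list[RegimePainting]:
    """Stochastic character maps under an ML equal-rates Mk model.

    Node states are sampled from their conditional distributions
    (Nielsen/Bollback scheme); branch histories conditional on endpoint
    states are drawn by rejection sampling of forward trajectories.
    Deterministic given ``seed``.
    """
    labels = tuple(sorted(set(states.values())))
    m = len(labels)
    lut = {s: i for i, s in enumerate(labels)}
    tip_idx = np.array([lut[states[lab]] for lab in tree.labels])
    counts = np.bincount(tip_idx, minlength=m)
    if (counts == 1).any():
        warnings.warn("a regime state has a single tip: weakly estimable",
                      stacklevel=2)
    if m == 1:
        seg = [[(0, float(tree.edge_len[v]))] for v in range(tree.n_nodes)]
        return [RegimePainting(labels, seg, 0, "simmap", seed)
                for _ in range(n_maps)]

    height = max(tree.height, 1e-9)
    res = optimize.minimize_scalar(
        lambda lq: -_mk_er_loglik(tree, tip_idx, m, np.exp(lq)),
        bounds=(np.log(1e-4 / height), np.log(200.0 / height)),
        method="bounded")
    q = float(np.exp(res.x))

    # conditional (partial) likelihoods, reused across maps
    L = np.zeros((tree.n_nodes, m))
    L[np.arange(tree.n_tips), tip_idx] = 1.0
    for v in tree.postorder:
        if v < tree.n_tips:
            continue
        acc = np.ones(m)
        for c in tree.children[v]:
            ps, pd_ = _er_transition(m, q, tree.edge_len[c])
            acc *= pd_ * L[c].sum() + (ps - pd_) * L[c]
        L[v] = acc

    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_maps):
        node_state = np.empty(tree.n_nodes, dtype=int)
        w = L[tree.root]
        node_state[tree.root] = rng.choice(m, p=w / w.sum())
        for v in tree.preorder:
            p = tree.parent[v]
            if p < 0:
                continue
            ps, pd_ = _er_transition(m, q, tree.edge_len[v])
            trans = np.full(m, pd_)
            trans[node_state[p]] = ps
            w = trans * L[v]
            node_state[v] = rng.choice(m, p=w / w.sum())
        segments: list[list[tuple[int, float]]] = [[] for _ in range(tree.n_nodes)]
        for v in range(tree.n_nodes):
            if tree.parent[v] < 0:
                segments[v] = []
                continue
            segments[v] = _branch_history(
                int(node_state[tree.parent[v]]), int(node_state[v]),
                float(tree.edge_len[v]), m, q, rng)
        out.append(RegimePainting(labels, segments, int(node_state[tree.root]),
                                  "simmap", seed))
    return out


def _branch_history(a: int, b: int, t: float, m: int, q: float,
                    rng: np.random.Generator, max_tries: int = 500):
    """Sample an ER-Mk path on [0, t] conditional on endpoint states."""
    if t <= 0:
        return [(b, 0.0)]
    rate = (m - 1) * q
    for _ in range(max_tries):
        segs, s, pos = [], a, 0.0
        while True:
            wait = rng.exponential(1.0 / rate) if rate > 0 else np.inf
            if pos + wait >= t:
                segs.append((s, t - pos))
                break
            segs.append((s, wait))
            pos += wait
            s = int((s + 1 + rng.integers(m - 1)) % m)
        if segs[-1][0] == b:
            # merge zero-length bookkeeping and adjacent same-state runs
            merged: list[tuple[int, float]] = []
            for st, d in segs:
                if merged and merged[-1][0] == st:
                    merged[-1] = (st, merged[-1][1] + d)
                else:
                    merged.append((st, d))
            return merged
    # rejection failed (very unlikely unless endpoints conflict with rate):
    if a == b:
        return [(a, t)]
    u = float(rng.uniform(0.05, 0.95)) * t
    return [(a, u), (b, t - u)]


def combine_paintings(tree: Phylo, pa: RegimePainting, pb: RegimePainting
                      ) -> RegimePainting:
    """Product painting: regime = (state_a, state_b), segment-wise."""
    labels = tuple(f"{sa}|{sb}" for sa in pa.states for sb in pb.states)
    mb = pb.n_states

    def join(i, j):
        return i * mb + j

    segments: list[list[tuple[int, float]]] = [[] for _ in range(tree.n_nodes)]
    for v in range(tree.n_nodes):
        if tree.parent[v] < 0:
            continue
        # walk both segment lists, splitting at every boundary
        ia = ib = 0
        ra, da = pa.segments[v][0]
        rb, db = pb.segments[v][0]
        out = []
        while True:
            d = min(da, db)
            if d > 0:
                out.append((join(ra, rb), d))
            da -= d
            db -= d
            if da <= 1e-13:
                ia += 1
                if ia < len(pa.segments[v]):
                    ra, da = pa.segments[v][ia]
                else:
                    break
            if db <= 1e-13:
                ib += 1
                if ib < len(pb.segments[v]):
                    rb, db = pb.segments[v][ib]
                else:
                    break
        segments[v] = out if out else [(join(ra, rb), 0.0)]
    return RegimePainting(labels, segments, join(pa.root_state, pb.root_state),
                          "simmap", pa.seed)


# ---------------------------------------------------------------------------
# likelihoods
# ---------------------------------------------------------------------------

@dataclass
class EvoModelFit:
    model: str
    loglik: float
    n_params: int
    aicc: float
    params: dict = field(default_factory=dict)
    converged: bool = True


def aicc(loglik: float, p: int, n_eff: int) -> float:
    if n_eff - p - 1 <= 0:
        return np.inf
    return -2 * loglik + 2 * p + 2 * p * (p + 1) / (n_eff - p - 1)


def n_parameters(model: str, k: int, m: int = 1) -> int:
    """Free-parameter audit used for AICc (k traits, m regimes)."""
    half = k * (k + 1) // 2
    if model == "BM1":
        return half + k
    if model == "EB":
        return half + k + 1
    if model in ("BMMs", "BMMd", "BMMsd"):
        return half * m + k
    if model in ("BMMsm", "BMMdm", "BMMsdm"):
        return half + k * m
    if model == "OU1":
        return half + k + k
    if model in ("OUs", "OUd", "OUsd"):
        return half + k + k * m
    raise ValueError(f"unknown model {model!r}")


def _gauss_loglik_kron(V: np.ndarray, Y: np.ndarray, X: np.ndarray):
    """Profiled Gaussian log-likelihood for cov = V (x) R with the mean
    design X shared across traits: both the mean coefficients and R are
    maximised analytically."""
    n, k = Y.shape
    if not np.all(np.isfinite(V)):
        return -np.inf, None, None
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return -np.inf, None, None
    Yw = solve_triangular(L, Y, lower=True)
    Xw = solve_triangular(L, X, lower=True)
    beta, *_ = np.linalg.lstsq(Xw, Yw, rcond=None)
    Res = Yw - Xw @ beta
    Rhat = Res.T @ Res / n
    sign, logdet_R = np.linalg.slogdet(Rhat)
    if sign <= 0:
        return -np.inf, None, None
    logdet_V = 2 * np.log(np.diag(L)).sum()
    ll = -0.5 * (n * k * _LOG2PI + k * logdet_V + n * logdet_R + n * k)
    return float(ll), beta, Rhat


def _gauss_loglik_dense(C: np.ndarray, y: np.ndarray, X: np.ndarray):
    """Gaussian log-likelihood with GLS-profiled mean for a dense covariance
    C over the trait-major stacked observation vector y."""
    if not np.all(np.isfinite(C)):
        return -np.inf, None
    try:
        cf = cho_factor(C, lower=True)
    except (np.linalg.LinAlgError, ValueError):
        return -np.inf, None
    Ci_X = cho_solve(cf, X)
    XtCiX = X.T @ Ci_X
    try:
        beta = np.linalg.solve(XtCiX, Ci_X.T @ y)
    except np.linalg.LinAlgError:
        return -np.inf, None
    r = y - X @ beta
    quad = float(r @ cho_solve(cf, r))
    logdet = 2 * np.log(np.diag(cf[0])).sum()
    ll = -0.5 * (len(y) * _LOG2PI + logdet + quad)
    return float(ll), beta


def _ou_cov(Ta: np.ndarray, T: float, alpha: np.ndarray, R: np.ndarray
            ) -> np.ndarray:
    """Fixed-root OU tip covariance, trait-major blocks.

    Block (t, u) has entries R_tu / (a_t + a_u) *
    (exp(-(a_t+a_u)(T - Ta)) - exp(-(a_t+a_u) T)); for t = u this is the
    familiar (sigma^2 / 2a)(1 - e^{-2a t_a}) e^{-a d}.
    """
    k = len(alpha)
    n = Ta.shape[0]
    C = np.empty((n * k, n * k))
    for t in range(k):
        for u in range(t, k):
            s = alpha[t] + alpha[u]
            B = (np.exp(-s * (T - Ta)) - np.exp(-s * T)) / s
            C[t * n:(t + 1) * n, u * n:(u + 1) * n] = R[t, u] * B
            if u != t:
                C[u * n:(u + 1) * n, t * n:(t + 1) * n] = R[t, u] * B
    return C


def _hansen_design(tree: Phylo, painting: RegimePainting, alpha: np.ndarray
                   ) -> np.ndarray:
    """Trait-major block-diagonal design (nk x k*m) of Hansen regime weights;
    the root weight e^{-a T} is folded into the root regime's column."""
    n, m, k = tree.n_tips, painting.n_states, len(alpha)
    tips, sts, t0, t1 = painting.flat_segments(tree)
    Tt = tree.depth[:n]
    X = np.zeros((n * k, k * m))
    for t in range(k):
        a = alpha[t]
        w = np.exp(-a * (Tt[tips] - t1)) - np.exp(-a * (Tt[tips] - t0))
        W = np.zeros((n, m))
        np.add.at(W, (tips, sts), w)
        W[:, painting.root_state] += np.exp(-a * Tt)
        X[t * n:(t + 1) * n, t * m:(t + 1) * m] = W
    return X


def _state_indicator(tree: Phylo, painting: RegimePainting) -> np.ndarray:
    n, m = tree.n_tips, painting.n_states
    X = np.zeros((n, m))
    X[np.arange(n), [painting.tip_state(i) for i in range(n)]] = 1.0
    return X


def _eb_v(Ta: np.ndarray, r: float) -> np.ndarray:
    if abs(r) < 1e-14:
        return Ta.copy()
    return np.expm1(r * Ta) / r


def model_loglik(tree: Phylo, scores: np.ndarray, painting: RegimePainting | None,
                 model: str, params: dict) -> float:
    """Log-likelihood of ``scores`` under one model at explicit parameters.

    ``params`` keys by model: BM1/EB — ``R`` (k x k), ``root`` (k,) and for
    EB ``r``; BMMs/d/sd — ``R_list`` (per-regime rate matrices) and ``root``;
    BMMsm/dm/sdm — ``R`` and ``means`` (m x k); OU* — ``alpha`` (k,), ``R``
    and ``theta`` (m x k, one row for OU1).
    """
    Y = np.atleast_2d(np.asarray(scores, float))
    n, k = Y.shape
    Ta = tree.vcv()
    y = Y.T.reshape(-1)  # trait-major stacking

    if model in ("BM1", "EB", "BMMsm", "BMMdm", "BMMsdm"):
        V = Ta if model != "EB" else _eb_v(Ta, float(params["r"]))
        R = np.asarray(params["R"], float)
        C = np.kron(R, V)
        if model in ("BMMsm", "BMMdm", "BMMsdm"):
            means = np.asarray(params["means"], float)  # m x k
            ind = _state_indicator(tree, painting)
            mu = (ind @ means).T.reshape(-1)
        else:
            root = np.asarray(params["root"], float)
            mu = np.repeat(root, n)
    elif model in ("BMMs", "BMMd", "BMMsd"):
        times = painting.regime_times(tree)
        mrca = _mrca_matrix(tree)
        C = np.zeros((n * k, n * k))
        for r_i, Rr in enumerate(params["R_list"]):
            Vr = times[mrca, r_i]
            C += np.kron(np.asarray(Rr, float), Vr)
        root = np.asarray(params["root"], float)
        mu = np.repeat(root, n)
    elif model in ("OU1", "OUs", "OUd", "OUsd"):
        alpha = np.asarray(params["alpha"], float)
        R = np.asarray(params["R"], float)
        theta = np.atleast_2d(np.asarray(params["theta"], float))  # m x k
        if painting is None:
            seg = [[(0, float(tree.edge_len[v]))] for v in range(tree.n_nodes)]
            painting = RegimePainting(("state",), seg, 0, "user")
        T = tree.height
        C = _ou_cov(Ta, T, alpha, R)
        X = _hansen_design(tree, painting, alpha)
        mu = X @ theta.T.reshape(-1)
    else:
        raise ValueError(f"unknown model {model!r}")

    try:
        cf = cho_factor(C, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"non-positive-definite covariance for {model}: "
                         f"{params.keys()}") from exc
    r_ = y - mu
    quad = float(r_ @ cho_solve(cf, r_))
    logdet = 2 * np.log(np.diag(cf[0])).sum()
    return float(-0.5 * (n * k * _LOG2PI + logdet + quad))


def _mrca_matrix(tree: Phylo) -> np.ndarray:
    n = tree.n_tips
    paths = [tree.root_path(i) for i in range(n)]
    sets = [set(p) for p in paths]
    out = np.zeros((n, n), dtype=int)
    for i in range(n):
        out[i, i] = i
        for j in range(i + 1, n):
            common = sets[i] & sets[j]
            v = max(common, key=lambda u: tree.depth[u])
            out[i, j] = out[j, i] = v
    return out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _chol_pack(L: np.ndarray) -> np.ndarray:
    """Lower-triangular Cholesky factor -> flat vector, log on the diagonal
    (keeps R positive semi-definite under unconstrained optimisation)."""
    k = L.shape[0]
    out = []
    for i in range(k):
        for j in range(i + 1):
            out.append(np.log(max(L[i, j], 1e-12)) if i == j else L[i, j])
    return np.array(out)


def _chol_unpack(v: np.ndarray, k: int) -> np.ndarray:
    L = np.zeros((k, k))
    t = 0
    for i in range(k):
        for j in range(i + 1):
            L[i, j] = np.exp(v[t]) if i == j else v[t]
            t += 1
    return L


class _Fitter:
    """Shared context for one dataset (tree + scores)."""

    def __init__(self, tree: Phylo, scores: np.ndarray):
        self.tree = tree
        self.Y = np.atleast_2d(np.asarray(scores, float))
        self.n, self.k = self.Y.shape
        self.Ta = tree.vcv()
        self.T = tree.height
        self.ones = np.ones((self.n, 1))
        self.n_eff = self.n * self.k
        self.y = self.Y.T.reshape(-1)
        self.mrca = None

    def _mrca_mat(self):
        if self.mrca is None:
            self.mrca = _mrca_matrix(self.tree)
        return self.mrca

    # ---- closed-form / 1-d models

    def fit_bm1(self) -> EvoModelFit:
        ll, beta, Rhat = _gauss_loglik_kron(self.Ta, self.Y, self.ones)
        p = n_parameters("BM1", self.k)
        return EvoModelFit("BM1", ll, p, aicc(ll, p, self.n_eff),
                           {"R": Rhat, "root": beta[0]})

    def fit_eb(self) -> EvoModelFit:
        lo = -20.0 / self.T

        def nll(r):
            return -_gauss_loglik_kron(_eb_v(self.Ta, r), self.Y, self.ones)[0]

        best = None
        for a, b in [(lo, lo / 2), (lo / 2, lo / 50), (lo / 50, -1e-12)]:
            res = optimize.minimize_scalar(nll, bounds=(a, b), method="bounded",
                                           options={"xatol": 1e-10})
            if best is None or res.fun < best.fun:
                best = res
        r = float(best.x)
        ll, beta, Rhat = _gauss_loglik_kron(_eb_v(self.Ta, r), self.Y, self.ones)
        p = n_parameters("EB", self.k)
        return EvoModelFit("EB", ll, p, aicc(ll, p, self.n_eff),
                           {"R": Rhat, "root": beta[0], "r": r})

    def fit_bm_means(self, model: str, painting: RegimePainting) -> EvoModelFit:
        X = _state_indicator(self.tree, painting)
        used = X.sum(axis=0) > 0
        ll, beta, Rhat = _gauss_loglik_kron(self.Ta, self.Y, X[:, used])
        m = painting.n_states
        p = n_parameters(model, self.k, int(used.sum()))
        means = np.zeros((m, self.k))
        means[used] = beta
        return EvoModelFit(model, ll, p, aicc(ll, p, self.n_eff),
                           {"R": Rhat, "means": means})

    # ---- multi-rate BM (full per-regime rate matrices)

    def _bmm_proportional_init(self, Ms: list[np.ndarray], n_starts: int):
        """Proportional-rate profile (R_r = s_r R), used to seed the full
        per-regime optimisation: with a scalar per regime the covariance is
        Kronecker-factorable and R profiles out analytically."""
        m = len(Ms)

        def nll(u):
            s = np.concatenate([[1.0], np.exp(u)])
            V = sum(si * Mi for si, Mi in zip(s, Ms))
            return -_gauss_loglik_kron(V, self.Y, self.ones)[0]

        starts = [np.zeros(m - 1), np.full(m - 1, 1.0), np.full(m - 1, -1.0)]
        best = None
        for x0 in starts[:max(n_starts, 1)]:
            res = optimize.minimize(nll, x0, method="L-BFGS-B",
                                    bounds=[(-12, 12)] * (m - 1))
            if best is None or res.fun < best.fun:
                best = res
        s = np.concatenate([[1.0], np.exp(best.x)])
        V = sum(si * Mi for si, Mi in zip(s, Ms))
        _, _, Rhat = _gauss_loglik_kron(V, self.Y, self.ones)
        return s, Rhat

    def fit_bmm(self, model: str, painting: RegimePainting,
                n_starts: int = 3) -> EvoModelFit:
        times = painting.regime_times(self.tree)
        mrca = self._mrca_mat()
        used = painting.used_states()
        m = len(used)
        k = self.k
        Ms = [times[mrca, r] for r in used]
        X = np.kron(np.eye(k), self.ones)
        nh = k * (k + 1) // 2

        def unpack_L(v):
            return [_chol_unpack(v[i * nh:(i + 1) * nh], k) for i in range(m)]

        def unpack(v):
            return [L @ L.T for L in unpack_L(v)]

        tri = np.tril_indices(k)
        n = self.n

        def nll_grad(v):
            """Negative profiled log-likelihood and its analytic gradient.

            With the mean GLS-profiled, the envelope theorem gives
            d(-ll)/dv = 0.5 * sum(dR_v * (S_r - Q_r)) with
            S_r[t,u] = tr(Cinv_block[t,u] M_r) and Q_r = W M_r W^T, W the
            whitened-residual matrix; for a Cholesky entry the chain rule
            collapses to (D_r @ L_r) at that entry.
            """
            L_list = unpack_L(v)
            C = np.zeros((n * k, n * k))
            for L_r, Mr in zip(L_list, Ms):
                C += np.kron(L_r @ L_r.T, Mr)
            C[np.diag_indices_from(C)] += 1e-10 * max(np.trace(C), 1e-12) / len(C)
            if not np.all(np.isfinite(C)):
                return 1e10, np.zeros_like(v)
            try:
                cf = cho_factor(C, lower=True)
            except (np.linalg.LinAlgError, ValueError):
                return 1e10, np.zeros_like(v)
            Ci_X = cho_solve(cf, X)
            beta = np.linalg.solve(X.T @ Ci_X, Ci_X.T @ self.y)
            r = self.y - X @ beta
            w = cho_solve(cf, r)
            quad = float(r @ w)
            logdet = 2 * np.log(np.diag(cf[0])).sum()
            ll = -0.5 * (n * k * _LOG2PI + logdet + quad)
            Cinv = cho_solve(cf, np.eye(n * k))
            Cinv4 = Cinv.reshape(k, n, k, n)
            W = w.reshape(k, n)
            grad = np.empty_like(v)
            for ri, (L_r, Mr) in enumerate(zip(L_list, Ms)):
                S = np.einsum("tiuj,ji->tu", Cinv4, Mr, optimize=True)
                Q = W @ Mr @ W.T
                G = ((S - Q) @ L_r)  # d(-ll)/dL entries (times 2*0.5)
                g = G[tri]
                # log-diagonal parameterisation
                dpos = np.cumsum(np.arange(1, k + 1)) - 1
                g[dpos] *= np.diag(L_r)
                grad[ri * nh:(ri + 1) * nh] = g
            return -ll, grad

        s, Rhat = self._bmm_proportional_init(Ms, n_starts)
        Rhat = Rhat + 1e-10 * np.trace(Rhat) / k * np.eye(k)
        L0 = np.linalg.cholesky(Rhat)
        v_prop = np.concatenate([_chol_pack(np.sqrt(si) * L0) for si in s])
        v_flat = np.concatenate([_chol_pack(L0)] * m)
        starts = [v_prop, v_flat, v_prop + 0.3]
        bounds = [(-20, 15)] * (m * nh)
        best = None
        for x0 in starts[:max(n_starts, 1)]:
            res = optimize.minimize(nll_grad, x0, jac=True, method="L-BFGS-B",
                                    bounds=bounds,
                                    options={"maxiter": 200, "ftol": 1e-10})
            if best is None or res.fun < best.fun:
                best = res
        R_list = unpack(best.x)
        C = np.zeros((self.n * k, self.n * k))
        for Rr, Mr in zip(R_list, Ms):
            C += np.kron(Rr, Mr)
        C[np.diag_indices_from(C)] += 1e-10 * max(np.trace(C), 1e-12) / len(C)
        ll, beta = _gauss_loglik_dense(C, self.y, X)
        p = n_parameters(model, k, m)
        return EvoModelFit(model, ll, p, aicc(ll, p, self.n_eff),
                           {"R_list": R_list,
                            "states": [painting.states[i] for i in used],
                            "root": np.asarray(beta).ravel()},
                           converged=bool(best.success) and np.isfinite(ll))

    # ---- OU family

    def fit_ou(self, model: str, painting: RegimePainting | None,
               n_starts: int = 3) -> EvoModelFit:
        k = self.k
        if painting is None:
            seg = [[(0, float(self.tree.edge_len[v]))]
                   for v in range(self.tree.n_nodes)]
            painting = RegimePainting(("state",), seg, 0, "user")
        used = painting.used_states()
        m = len(used)
        pos = {s: i for i, s in enumerate(used)}
        flat = painting.flat_segments(self.tree)
        n = self.n
        Tt = self.tree.depth[:n]
        tips, sts, t0, t1 = flat
        sts = np.array([pos[s] for s in sts], dtype=int)
        root_col = pos[painting.root_state]

        def design(alpha):
            X = np.zeros((n * k, k * m))
            for t in range(k):
                a = alpha[t]
                w = np.exp(-a * (Tt[tips] - t1)) - np.exp(-a * (Tt[tips] - t0))
                W = np.zeros((n, m))
                np.add.at(W, (tips, sts), w)
                W[:, root_col] += np.exp(-a * Tt)
                X[t * n:(t + 1) * n, t * m:(t + 1) * m] = W
            return X

        def unpack(v):
            alpha = np.exp(v[:k])
            L = _chol_unpack(v[k:], k)
            return alpha, L @ L.T

        def nll(v):
            alpha, R = unpack(v)
            C = _ou_cov(self.Ta, self.T, alpha, R)
            C[np.diag_indices_from(C)] += 1e-10 * np.trace(C) / len(C)
            ll, _ = _gauss_loglik_dense(C, self.y, design(alpha))
            return -ll if np.isfinite(ll) else 1e10

        S = np.cov(self.Y.T) if self.k > 1 else np.atleast_2d(np.var(self.Y))
        S = S + 1e-8 * np.trace(S) / self.k * np.eye(self.k)
        la_lo, la_hi = np.log(1e-5 / self.T), np.log(500.0 / self.T)
        bounds = [(la_lo, la_hi)] * k + [(-20, 15)] * (k * (k + 1) // 2)
        alpha0s = [0.1 / self.T, 1.0 / self.T, 5.0 / self.T]
        best = None
        for a0 in alpha0s[:max(n_starts, 1)]:
            R0 = 2 * a0 * S
            v0 = np.concatenate([np.full(k, np.log(a0)),
                                 _chol_pack(np.linalg.cholesky(R0))])
            res = optimize.minimize(nll, v0, method="L-BFGS-B", bounds=bounds,
                                    options={"maxiter": 100, "ftol": 1e-9})
            if best is None or res.fun < best.fun:
                best = res
        alpha, R = unpack(best.x)
        C = _ou_cov(self.Ta, self.T, alpha, R)
        C[np.diag_indices_from(C)] += 1e-10 * np.trace(C) / len(C)
        ll, beta = _gauss_loglik_dense(C, self.y, design(alpha))
        theta = beta.reshape(k, m).T if beta is not None else None
        p = n_parameters(model, k, m)
        return EvoModelFit(model, ll, p, aicc(ll, p, self.n_eff),
                           {"alpha": alpha, "R": R, "theta": theta,
                            "theta_states": [painting.states[i] for i in used]},
                           converged=bool(best.success) and np.isfinite(ll))


def fit_all_models(
    tree: Phylo,
    scores: np.ndarray,
    partition_states: dict,
    diet_states: dict,
    n_maps: int = 10,
    seed: int = 0,
    models: tuple[str, ...] = MODEL_NAMES,
    n_starts: int = 3,
) -> tuple[pd.DataFrame, dict]:
    """Fit the requested models and rank them by AICc.

    Regime-dependent models are fitted on each of ``n_maps`` stochastic
    character maps and their log-likelihood/AICc averaged. Returns the
    ranked model table (model, logL, n_params, AICc, dAICc) and a dict of
    per-model parameter estimates (from the last painting for regime
    models).
    """
    if not tree.is_ultrametric(1e-6):
        warnings.warn("tree is not ultrametric within tolerance; OU/EB "
                      "covariances assume a common tip depth", stacklevel=2)
    fitter = _Fitter(tree, scores)
    rng = np.random.SeedSequence(seed)
    s_part, s_diet = (int(s.generate_state(1)[0] % (2 ** 31)) for s in rng.spawn(2))
    maps_part = paint_regimes(tree, partition_states, n_maps, s_part)
    maps_diet = paint_regimes(tree, diet_states, n_maps, s_diet)
    maps_combo = [combine_paintings(tree, a, b)
                  for a, b in zip(maps_part, maps_diet)]
    painting_for = {"BMMs": maps_part, "BMMd": maps_diet, "BMMsd": maps_combo,
                    "BMMsm": maps_part, "BMMdm": maps_diet, "BMMsdm": maps_combo,
                    "OUs": maps_part, "OUd": maps_diet, "OUsd": maps_combo}

    rows, all_params = [], {}
    for model in models:
        try:
            if model == "BM1":
                fits = [fitter.fit_bm1()]
            elif model == "EB":
                fits = [fitter.fit_eb()]
            elif model == "OU1":
                fits = [fitter.fit_ou("OU1", None, n_starts)]
            elif model in ("BMMs", "BMMd", "BMMsd"):
                fits = [fitter.fit_bmm(model, pt, n_starts)
                        for pt in painting_for[model]]
            elif model in ("BMMsm", "BMMdm", "BMMsdm"):
                fits = [fitter.fit_bm_means(model, pt)
                        for pt in painting_for[model]]
            elif model in ("OUs", "OUd", "OUsd"):
                first = fitter.fit_ou(model, painting_for[model][0], n_starts)
                fits = [first]
                for pt in painting_for[model][1:]:
                    fits.append(fitter.fit_ou(model, pt, 1))
            else:
                raise ValueError(f"unknown model {model!r}")
        except Exception as exc:  # noqa: BLE001 - report failed model
            warnings.warn(f"model {model} failed: {exc}", stacklevel=2)
            continue
        lls = [f.loglik for f in fits if np.isfinite(f.loglik)]
        if not lls:
            warnings.warn(f"model {model} did not converge; excluded",
                          stacklevel=2)
            continue
        ll = float(np.mean(lls))
        p = fits[0].n_params
        rows.append({"model": model, "logL": ll, "n_params": p,
                     "AICc": aicc(ll, p, fitter.n_eff),
                     "n_maps": len(lls),
                     "converged": all(f.converged for f in fits)})
        all_params[model] = fits[-1].params
    table = pd.DataFrame(rows).sort_values("AICc").reset_index(drop=True)
    table["dAICc"] = table["AICc"] - table["AICc"].min()
    return table, all_params
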
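"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the structure of a museum ontogenetic-series
compilation: a pure-birth time-calibrated tree, a discrete diet character
evolving along it, species-level allometric slope vectors evolving under a
chosen trait model (BM / OU / EB, optionally with regime paintings and
forced convergence of a focal tip set), and specimen-level measurement
tables built from those slopes with log-normal measurement noise.

The measurement model is log-linear growth: for specimen i of species s,
ln m_ij = c_j + (1 + beta_sj) x_i + eps_ij with x_i the specimen's latent
log size, drawn uniformly over the species' growth range. Because the
slope deviations beta_s sum to zero across traits, the specimen's log
geometric mean is x_i plus a constant (plus mean noise), so the pipeline's
fitted log-shape-ratio slopes recover beta_s exactly in the noise-free
case.

The default ``survey_scale`` preset produces 62 species of which 50 carry at
least 15 specimens (~2000 specimens in total), slope vectors evolving
under a single-optimum OU process, and a four-state diet character — the
sampling structure the real analyses face.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evomodels import RegimePainting
from .io import (DEFAULT_TRAITS, ORDER_TO_PARTITION, SpeciesMeta,
                 SpecimenTable)
from .tree import Phylo

__all__ = ["SyntheticTruth", "simulate_tree", "simulate_discrete_states",
           "simulate_coefficients", "generate_specimens", "survey_scale"]


@dataclass
class SyntheticTruth:
    """Ground truth behind a synthetic dataset (test oracle)."""

    tree: Phylo
    beta: dict                      # species -> slope-deviation vector
    model: str
    params: dict
    traits: tuple[str, ...]
    n_specimens: dict               # species -> specimen count
    x_range: dict                   # species -> (x_lo, x_hi)
    sigma_meas: float
    seed: int
    baseline: np.ndarray | None = None
    convergent_set: tuple[str, ...] = ()
    painting: RegimePainting | None = None
    extras: dict = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        obj = {
            "model": self.model,
            "traits": list(self.traits),
            "sigma_meas": self.sigma_meas,
            "seed": self.seed,
            "convergent_set": list(self.convergent_set),
            "n_specimens": {k: int(v) for k, v in self.n_specimens.items()},
            "beta": {k: list(map(float, v)) for k, v in self.beta.items()},
            "newick": self.tree.to_newick(),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)


def simulate_tree(n_tips: int, birth_rate: float = 0.1, seed: int = 0,
                  height: float = 70.0, min_root_split: int = 0) -> Phylo:
    """Pure-birth (Yule) ultrametric tree rescaled to a fixed height.

    The default 70 Myr height spans the divergence depth of the clades this
    pipeline targets. ``min_root_split`` conditions the tree on its root
    split having at least that many tips on the smaller side (the two-
    partition structure of the emulated clade is 14:48, not 1:61); trees
    are redrawn deterministically from sub-seeds until the condition holds.
    Deterministic given ``seed``.
    """
    if n_tips < 3:
        raise ValueError("need >= 3 tips")
    if min_root_split > 0:
        for sub in np.random.SeedSequence(seed).spawn(1000):
            t = simulate_tree(n_tips, birth_rate,
                              int(sub.generate_state(1)[0] % (2 ** 31)),
                              height)
            smaller = min(len(t.subtree_tips(c))
                          for c in t.children[t.root])
            if smaller >= min_root_split:
                return t
        raise RuntimeError("could not satisfy min_root_split")
    rng = np.random.default_rng(seed)
    # nodes: grow a list of (parent, birth_time); active = open lineages
    parent = [-1, 0, 0]
    btime = [0.0, 0.0, 0.0]
    t = 0.0
    active = [1, 2]
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = int(rng.integers(len(active)))
        v = active.pop(i)
        for _ in range(2):
            parent.append(v)
            btime.append(t)
            active.append(len(parent) - 1)
    t_end = t + rng.exponential(1.0 / (birth_rate * len(active)))
    # assemble arrays: tips are the active lineages (ending at t_end)
    n_nodes = len(parent)
    is_tip = np.zeros(n_nodes, bool)
    is_tip[active] = True
    order = list(active) + [v for v in range(n_nodes) if not is_tip[v]]
    remap = {old: new for new, old in enumerate(order)}
    par = np.array([remap[parent[v]] if parent[v] >= 0 else -1 for v in order])
    bt = np.array([btime[v] for v in order])
    end = np.where(np.arange(n_nodes) < len(active), t_end, 0.0)
    # a node's branch ends where the node itself was born... invert:
    # edge above node v runs from btime[v] (its birth) to the birth of its
    # children (internal) or t_end (tip); edge length = own start handled
    # below via depths.
    edge = np.zeros(n_nodes)
    for v in range(n_nodes):
        if par[v] < 0:
            continue
        start = bt[v]
        stop = t_end if v < len(active) else _first_child_time(par, bt, v)
        edge[v] = stop - start
    labels = [f"sp{str(i + 1).zfill(2)}" for i in range(len(active))]
    tree = Phylo(labels, par, edge)
    scale = height / tree.height
    return Phylo(labels, par, edge * scale)


def _first_child_time(par: np.ndarray, bt: np.ndarray, v: int) -> float:
    kids = np.flatnonzero(par == v)
    return float(bt[kids[0]])


def simulate_discrete_states(tree: Phylo, states: tuple[str, ...],
                             rate: float, seed: int = 0) -> tuple[dict, RegimePainting]:
    """Equal-rates Markov character simulated forward along the tree;
    returns tip states and the true branch painting."""
    m = len(states)
    rng = np.random.default_rng(seed)
    node_state = np.zeros(tree.n_nodes, dtype=int)
    node_state[tree.root] = rng.integers(m)
    segments: list[list[tuple[int, float]]] = [[] for _ in range(tree.n_nodes)]
    for v in tree.preorder:
        p = tree.parent[v]
        if p < 0:
            continue
        s = int(node_state[p])
        t, L, segs = 0.0, float(tree.edge_len[v]), []
        total = (m - 1) * rate
        while True:
            wait = rng.exponential(1.0 / total) if total > 0 else np.inf
            if t + wait >= L:
                segs.append((s, L - t))
                break
            segs.append((s, wait))
            t += wait
            s = int((s + 1 + rng.integers(m - 1)) % m)
        segments[v] = segs if segs else [(s, 0.0)]
        node_state[v] = s
    tips = {tree.labels[i]: states[node_state[i]] for i in range(tree.n_tips)}
    painting = RegimePainting(states, segments, int(node_state[tree.root]),
                              "user", seed)
    return tips, painting


def _psd_sqrt(S: np.ndarray) -> np.ndarray:
    """Symmetric square root with negative eigenvalues clipped; exact for
    the zero matrix (no jitter)."""
    w, V = np.linalg.eigh((S + S.T) / 2)
    return V * np.sqrt(np.clip(w, 0.0, None))


def _segment_step(x, model, seg_dur, seg_state, params, rng, k):
    """Advance one branch segment; exact transition per model."""
    d = seg_dur
    if d <= 0:
        return x
    if model in ("BM1", "BMM"):
        R = params["R"] if model == "BM1" else params["R_list"][seg_state]
        return x + _psd_sqrt(np.asarray(R) * d) @ rng.standard_normal(k)
    if model in ("OU1", "OUM"):
        alpha = np.asarray(params["alpha"], float)
        theta = (np.asarray(params["theta"], float)
                 if model == "OU1" else np.asarray(params["theta"])[seg_state])
        R = np.asarray(params["R"], float)
        decay = np.exp(-alpha * d)
        ssum = alpha[:, None] + alpha[None, :]
        S = R * (1 - np.exp(-ssum * d)) / ssum
        return theta + (x - theta) * decay + _psd_sqrt(S) @ rng.standard_normal(k)
    if model == "EB":
        # rate R * exp(r t); segment start time in params["_t0"]
        r = params["r"]
        t0 = params["_t0"]
        scale = (np.exp(r * (t0 + d)) - np.exp(r * t0)) / r if abs(r) > 1e-14 else d
        return x + _psd_sqrt(np.asarray(params["R"], float) * scale) @ \
            rng.standard_normal(k)
    raise ValueError(f"unknown simulation model {model!r}")


def simulate_coefficients(
    tree: Phylo,
    model: str,
    params: dict,
    regimes: RegimePainting | None = None,
    convergent_set: tuple[str, ...] = (),
    seed: int = 0,
    zero_sum: bool = True,
) -> dict:
    """Species-level trait vectors simulated branch-by-branch.

    ``model`` in {BM1, BMM, OU1, OUM, EB}. ``params``: ``R`` (k x k) and
    ``root`` (k,); plus ``alpha``/``theta`` for OU, ``R_list`` for BMM, ``r``
    (<= 0) for EB. ``convergent_set`` tips have their terminal branch
    re-simulated as an OU pull toward ``params["conv_theta"]`` with strength
    ``params["conv_alpha"]``, creating true convergence. With ``zero_sum``
    the tip vectors are projected to the zero-sum subspace trajectory slopes
    live in.
    """
    if model not in ("BM1", "BMM", "OU1", "OUM", "EB"):
        raise ValueError(f"unknown model {model!r}")
    if model in ("BMM", "OUM") and regimes is None:
        raise ValueError(f"{model} requires a regime painting")
    root = np.asarray(params.get("root", np.zeros(len(params["R"]))), float)
    k = len(root)
    rng = np.random.default_rng(seed)
    conv = set(convergent_set)
    vals = np.zeros((tree.n_nodes, k))
    vals[tree.root] = root
    for v in tree.preorder:
        p = tree.parent[v]
        if p < 0:
            continue
        x = vals[p].copy()
        segs = (regimes.segments[v] if regimes is not None
                else [(0, float(tree.edge_len[v]))])
        t0 = tree.depth[p]
        is_conv_tip = v < tree.n_tips and tree.labels[v] in conv
        if is_conv_tip:
            d = float(tree.edge_len[v])
            ca = np.asarray(params["conv_alpha"], float) * np.ones(k)
            ct = np.asarray(params["conv_theta"], float)
            x = _segment_step(x, "OU1", d, 0,
                              {"alpha": ca, "theta": ct, "R": params["R"]},
                              rng, k)
        else:
            for s, d in segs:
                params["_t0"] = t0
                x = _segment_step(x, model, float(d), int(s), params, rng, k)
                t0 += d
        vals[v] = x
    params.pop("_t0", None)
    tips = vals[: tree.n_tips]
    if zero_sum:
        tips = tips - tips.mean(axis=1, keepdims=True)
    return {tree.labels[i]: tips[i] for i in range(tree.n_tips)}


def generate_specimens(truth: SyntheticTruth) -> SpecimenTable:
    """Specimen-level measurement table from species-level ground truth."""
    rng = np.random.default_rng(truth.seed)
    p = len(truth.traits)
    # per-trait offsets around the geometric mean: measurements span about
    # an e-fold ratio range around GM (realistic for cranial dimensions)
    c = (truth.baseline if truth.baseline is not None
         else np.linspace(-0.5, 0.5, p))
    rows = []
    for sp in sorted(truth.beta):
        beta = np.asarray(truth.beta[sp], float)
        if abs(beta.sum()) > 1e-8:
            raise ValueError(f"beta for {sp} is not zero-sum")
        n_s = int(truth.n_specimens[sp])
        lo, hi = truth.x_range[sp]
        x = rng.uniform(lo, hi, size=n_s)
        eps = rng.normal(0.0, truth.sigma_meas, size=(n_s, p))
        logm = c[None, :] + (1.0 + beta)[None, :] * x[:, None] + eps
        for i in range(n_s):
            row = {"specimen_id": f"{sp}_{i + 1:03d}", "species": sp}
            row.update({t: float(np.exp(logm[i, j]))
                        for j, t in enumerate(truth.traits)})
            rows.append(row)
    return SpecimenTable(pd.DataFrame(rows), truth.traits)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _assign_orders(tree: Phylo) -> tuple[dict, dict]:
    """Partition tips by the root split (smaller side plays the American
    partition) and carve each side into clades standing in for the orders."""
    kids = tree.children[tree.root]
    sides = sorted((tree.subtree_tips(c) for c in kids), key=len)
    amer = sides[0]
    aust = [t for s in sides[1:] for t in s]
    part = {}
    for i in amer:
        part[tree.labels[i]] = "Ameridelphia"
    for i in aust:
        part[tree.labels[i]] = "Australidelphia"
    amer_orders = [o for o, pt in ORDER_TO_PARTITION.items() if pt == "Ameridelphia"]
    aust_orders = [o for o, pt in ORDER_TO_PARTITION.items() if pt == "Australidelphia"]

    def carve(tip_set: list[int], n_groups: int) -> list[list[int]]:
        # repeatedly split the largest group at its shallowest internal node
        groups = [sorted(tip_set)]
        while len(groups) < n_groups:
            groups.sort(key=len, reverse=True)
            g = groups.pop(0)
            if len(g) == 1:
                groups.append(g)
                break
            sub = _mrca_of(tree, g)
            parts = [sorted(set(tree.subtree_tips(c)) & set(g))
                     for c in tree.children[sub]]
            parts = [p_ for p_ in parts if p_]
            if len(parts) < 2:
                groups.append(g)
                break
            groups.extend(parts)
        return groups

    order = {}
    for names, tipset in ((sorted(amer_orders), amer), (sorted(aust_orders), aust)):
        groups = carve(tipset, len(names))
        groups.sort(key=len, reverse=True)
        for name, g in zip(names, groups):
            for i in g:
                order[tree.labels[i]] = name
        # leftover groups (if carve overshot) join the largest order
        for g in groups[len(names):]:
            for i in g:
                order[tree.labels[i]] = names[0]
    return part, order


def _mrca_of(tree: Phylo, tips: list[int]) -> int:
    v = tips[0]
    rest = set(tips[1:])
    while True:
        below = set(tree.subtree_tips(v))
        if rest <= below:
            return v
        v = tree.parent[v]


def survey_scale(
    seed: int = 0,
    n_species: int = 62,
    min_big: int = 50,
    sigma_meas: float = 0.04,
    force_convergence: bool = True,
    traits: tuple[str, ...] = DEFAULT_TRAITS,
) -> tuple[SpecimenTable, SpeciesMeta, Phylo, SyntheticTruth]:
    """Full-pipeline synthetic dataset at the scale of the real compilation.

    62 species on a 70-Myr pure-birth tree; 50 species carry >= 15 specimens
    (the rest 5-14, exercising the pruning rule; ~2000 specimens in total);
    slope vectors evolve under single-optimum OU; a four-state diet evolves
    under an equal-rates Markov process. With ``force_convergence`` the
    animalivorous tips are additionally pulled toward a shared optimum on
    their terminal branches, planting a true convergence signal.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(7)]
    tree = simulate_tree(n_species, birth_rate=0.12, seed=seeds[0],
                         height=70.0,
                         min_root_split=max(3, round(0.18 * n_species)))
    part, order = _assign_orders(tree)
    # dietary evolution is conserved: a handful of transitions per tree
    diets, diet_painting = simulate_discrete_states(
        tree, ("animalivory", "herbivory", "mycophagy", "omnivory"),
        rate=0.004, seed=seeds[1])

    p = len(traits)
    height = tree.height
    alpha = np.full(p, np.log(2) / (height / 2))       # half-life = T/2
    sd_st = 0.12                                       # stationary per-trait sd
    # Structured stationary covariance inside the zero-sum subspace: a
    # dominant first axis and a decaying tail, the spectrum shape real
    # trajectory covariances show.
    rng_R = np.random.default_rng(seeds[2])
    A = rng_R.standard_normal((p, p - 1))
    A -= A.mean(axis=0, keepdims=True)                 # orthogonal to ones
    Q, _ = np.linalg.qr(A)
    head = np.array([0.44, 0.175, 0.135, 0.11])
    tail = 0.6 ** np.arange(p - 1 - len(head))
    lam = np.concatenate([head, (1 - head.sum()) * tail / tail.sum()])
    Sigma_st = (p * sd_st ** 2) * Q @ np.diag(lam) @ Q.T
    R = 2 * alpha[0] * Sigma_st
    params = {"R": R, "root": np.zeros(p), "alpha": alpha,
              "theta": np.zeros(p)}
    conv: tuple[str, ...] = ()
    if force_convergence:
        rng0 = np.random.default_rng(seeds[6])
        conv_theta = rng0.normal(0, sd_st, p)
        conv_theta -= conv_theta.mean()
        conv = tuple(sorted(s for s, d in diets.items() if d == "animalivory"))
        params["conv_theta"] = conv_theta
        params["conv_alpha"] = np.log(2) / (height / 20)
    beta = simulate_coefficients(tree, "OU1", params, convergent_set=conv,
                                 seed=seeds[3])

    rng = np.random.default_rng(seeds[4])
    species = sorted(beta)
    n_small = n_species - min_big
    small = set(rng.choice(species, size=n_small, replace=False))
    n_spec, x_range, mass = {}, {}, {}
    for sp in species:
        n_spec[sp] = int(rng.integers(5, 15) if sp in small
                         else rng.integers(15, 65))
        x0 = float(rng.uniform(2.3, 4.3))
        x_range[sp] = (x0, x0 + np.log(3.0))
        mass[sp] = float(np.exp(rng.normal(3.0 * x0 - 4.0, 0.5)))

    truth = SyntheticTruth(
        tree=tree, beta=beta, model="OU1", params=params, traits=traits,
        n_specimens=n_spec, x_range=x_range, sigma_meas=sigma_meas,
        seed=seeds[5], convergent_set=conv, painting=diet_painting,
        extras={"partition": part, "order": order, "diet": diets},
    )
    table = generate_specimens(truth)
    meta = SpeciesMeta(pd.DataFrame({
        "species": species,
        "partition": [part[s] for s in species],
        "order": [order[s] for s in species],
        "diet": [diets[s] for s in species],
        "body_mass": [mass[s] for s in species],
    }))
    return table, meta, tree, truth
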
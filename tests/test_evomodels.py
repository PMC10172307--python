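import numpy as np
import pytest
from scipy.stats import multivariate_normal

import allometree as at
from allometree.evomodels import (EvoModelFit, RegimePainting, _Fitter, aicc,
                                  combine_paintings, model_loglik,
                                  n_parameters, paint_regimes)
from allometree.simulate import simulate_discrete_states, simulate_tree


def _dense_cov(tree, model, params, painting=None):
    """Independent covariance/mean assembly (explicit loops over trait and
    tip pairs) for the dense multivariate-normal oracle."""
    n = tree.n_tips
    Ta = tree.vcv()
    T = tree.height
    if model in ("BM1", "BMMsm"):
        C = np.kron(np.asarray(params["R"]), Ta)
    elif model == "EB":
        r = params["r"]
        V = (np.exp(r * Ta) - 1) / r if abs(r) > 1e-14 else Ta
        C = np.kron(np.asarray(params["R"]), V)
    elif model == "BMMs":
        times = painting.regime_times(tree)
        C = 0
        for ri, Rr in enumerate(params["R_list"]):
            Vr = np.zeros((n, n))
            for i in range(n):
                for j in range(n):
                    m = tree.mrca(i, j)
                    Vr[i, j] = times[m, ri]
            C = C + np.kron(np.asarray(Rr), Vr)
    elif model.startswith("OU"):
        alpha = np.asarray(params["alpha"])
        R = np.asarray(params["R"])
        k = len(alpha)
        C = np.zeros((n * k, n * k))
        for t in range(k):
            for u in range(k):
                s = alpha[t] + alpha[u]
                for i in range(n):
                    for j in range(n):
                        C[t * n + i, u * n + j] = (
                            R[t, u] / s
                            * (np.exp(-s * (T - Ta[i, j])) - np.exp(-s * T)))
    else:
        raise ValueError(model)
    return C


def _ou_mean_oracle(tree, painting, alpha, theta):
    """Hansen weights by explicit per-tip segment walking."""
    n, k = tree.n_tips, len(alpha)
    theta = np.atleast_2d(theta)
    mu = np.zeros((k, n))
    for i in range(n):
        path = []
        v = i
        while tree.parent[v] >= 0:
            path.append(v)
            v = tree.parent[v]
        T = tree.depth[i]
        for t in range(k):
            a = alpha[t]
            tot = np.exp(-a * T) * theta[painting.root_state, t]
            s0 = 0.0
            for b in path[::-1]:
                for st, d in painting.segments[b]:
                    w = np.exp(-a * (T - (s0 + d))) - np.exp(-a * (T - s0))
                    tot += w * theta[st, t]
                    s0 += d
            mu[t, i] = tot
    return mu.reshape(-1)


@pytest.fixture(scope="module")
def tree8():
    return simulate_tree(8, seed=21, height=70)


@pytest.fixture(scope="module")
def scores8():
    return np.random.default_rng(8).normal(0, 0.4, (8, 3))


@pytest.fixture(scope="module")
def painting8(tree8):
    states = {lab: ("A" if i < 4 else "B")
              for i, lab in enumerate(tree8.labels)}
    return paint_regimes(tree8, states, n_maps=1, seed=13)[0]


def test_bm1_matches_dense_kronecker_oracle(tree8, scores8):
    R = np.array([[0.04, 0.01, 0.0], [0.01, 0.03, 0.005], [0.0, 0.005, 0.02]])
    root = np.array([0.1, -0.1, 0.0])
    C = _dense_cov(tree8, "BM1", {"R": R})
    mu = np.repeat(root, 8)
    oracle = multivariate_normal.logpdf(scores8.T.reshape(-1), mu, C)
    mine = model_loglik(tree8, scores8, None, "BM1", {"R": R, "root": root})
    assert mine == pytest.approx(oracle, abs=1e-8)


@pytest.mark.parametrize("model", ["EB", "BMMs", "BMMsm", "OU1", "OUs"])
def test_models_match_dense_oracle(model, tree8, scores8, painting8):
    R = np.array([[0.05, 0.01, 0.0], [0.01, 0.04, 0.01], [0.0, 0.01, 0.03]])
    params = {"R": R}
    painting = painting8 if model in ("BMMs", "BMMsm", "OUs") else None
    if model == "EB":
        params.update(root=np.array([0.2, 0.0, -0.1]), r=-0.02)
        mu = np.repeat(params["root"], 8)
    elif model == "BMMs":
        params = {"R_list": [R, 2.5 * R], "root": np.array([0.2, 0.0, -0.1])}
        mu = np.repeat(params["root"], 8)
    elif model == "BMMsm":
        params.update(means=np.array([[0.3, 0.0, -0.2], [-0.1, 0.2, 0.1]]))
        ind = np.array([painting8.tip_state(i) for i in range(8)])
        mu = (params["means"][ind]).T.reshape(-1)
    elif model == "OU1":
        params.update(alpha=np.array([0.05, 0.02, 0.08]),
                      theta=np.array([[0.1, -0.2, 0.3]]))
        seg = [[(0, float(tree8.edge_len[v]))] for v in range(tree8.n_nodes)]
        pt = RegimePainting(("s",), seg, 0, "user")
        mu = _ou_mean_oracle(tree8, pt, params["alpha"], params["theta"])
    elif model == "OUs":
        params.update(alpha=np.array([0.05, 0.02, 0.08]),
                      theta=np.array([[0.1, -0.2, 0.3], [-0.3, 0.1, 0.0]]))
        mu = _ou_mean_oracle(tree8, painting8, params["alpha"],
                             params["theta"])
    C = _dense_cov(tree8, model, params, painting)
    oracle = multivariate_normal.logpdf(scores8.T.reshape(-1), mu, C)
    mine = model_loglik(tree8, scores8, painting, model, params)
    assert mine == pytest.approx(oracle, abs=1e-6)


def test_eb_limit_equals_bm1(tree8, scores8):
    R = 0.03 * np.eye(3)
    root = np.zeros(3)
    bm = model_loglik(tree8, scores8, None, "BM1", {"R": R, "root": root})
    eb = model_loglik(tree8, scores8, None, "EB",
                      {"R": R, "root": root, "r": -1e-12})
    assert eb == pytest.approx(bm, abs=1e-6)


def test_ou_limit_approaches_bm1(tree8, scores8):
    R = 0.03 * np.eye(3)
    root = np.zeros(3)
    bm = model_loglik(tree8, scores8, None, "BM1", {"R": R, "root": root})
    ou = model_loglik(tree8, scores8, None, "OU1",
                      {"alpha": np.full(3, 1e-8), "R": R,
                       "theta": root[None, :]})
    assert ou == pytest.approx(bm, abs=1e-4)


def test_painting_deterministic_and_tip_consistent(tree8):
    states = {lab: ("A" if i % 2 else "B")
              for i, lab in enumerate(tree8.labels)}
    p1 = paint_regimes(tree8, states, n_maps=3, seed=99)
    p2 = paint_regimes(tree8, states, n_maps=3, seed=99)
    for a, b in zip(p1, p2):
        assert a.segments == b.segments
    lut = {s: i for i, s in enumerate(p1[0].states)}
    for pt in p1:
        for i, lab in enumerate(tree8.labels):
            assert pt.tip_state(i) == lut[states[lab]]
        for v in range(tree8.n_nodes):
            if tree8.parent[v] >= 0:
                assert sum(d for _, d in pt.segments[v]) == pytest.approx(
                    tree8.edge_len[v], rel=1e-9)


def test_single_state_painting_trivial(tree8):
    states = {lab: "only" for lab in tree8.labels}
    pts = paint_regimes(tree8, states, n_maps=2, seed=1)
    for pt in pts:
        assert pt.n_states == 1
        for v in range(tree8.n_nodes):
            assert all(s == 0 for s, _ in pt.segments[v])


def test_two_clade_painting_places_transition_on_stem():
    """Two clean clades separated by long internal branches: the MRCA of
    each clade should be painted in that clade's state in nearly all maps."""
    tree = at.Phylo.from_newick(
        "((A:5,B:5):45,(C:5,D:5):45);")
    states = {"A": "x", "B": "x", "C": "y", "D": "y"}
    hits = 0
    n = 40
    maps = paint_regimes(tree, states, n_maps=n, seed=5)
    lut = {s: i for i, s in enumerate(maps[0].states)}
    for pt in maps:
        mab = tree.mrca(0, 1)   # tips sorted A,B,C,D
        mcd = tree.mrca(2, 3)
        # state at clade MRCA = state at the child end of its stem branch
        st_ab = pt.segments[mab][-1][0]
        st_cd = pt.segments[mcd][-1][0]
        hits += (st_ab == lut["x"]) and (st_cd == lut["y"])
    assert hits >= 0.95 * n


def test_combined_painting_durations(tree8, painting8):
    states = {lab: ("p" if i < 3 else "q")
              for i, lab in enumerate(tree8.labels)}
    other = paint_regimes(tree8, states, n_maps=1, seed=3)[0]
    combo = combine_paintings(tree8, painting8, other)
    assert combo.n_states == 4
    for v in range(tree8.n_nodes):
        if tree8.parent[v] >= 0:
            assert sum(d for _, d in combo.segments[v]) == pytest.approx(
                tree8.edge_len[v], rel=1e-6)


def test_parameter_count_audit():
    k = 4
    half = k * (k + 1) // 2
    assert n_parameters("BM1", k) == half + k
    assert n_parameters("EB", k) == half + k + 1
    assert n_parameters("BMMs", k, 2) == 2 * half + k
    assert n_parameters("BMMsd", k, 8) == 8 * half + k
    assert n_parameters("BMMsm", k, 2) == half + 2 * k
    assert n_parameters("OU1", k, 1) == half + k + k
    assert n_parameters("OUd", k, 4) == half + k + 4 * k   # k optima per diet


def test_aicc_formula():
    assert aicc(-100.0, 5, 50) == pytest.approx(
        200 + 10 + 2 * 5 * 6 / (50 - 6), rel=1e-12)


def test_nested_models_never_lose_loglik_and_ranking_trait_invariant():
    tree = simulate_tree(20, seed=31, height=70)
    rng = np.random.default_rng(2)
    Z = rng.normal(0, 0.3, (20, 3))
    parts = {lab: ("P1" if i < 10 else "P2")
             for i, lab in enumerate(tree.labels)}
    diets, _ = simulate_discrete_states(tree, ("a", "o"), 2 / 70, seed=4)
    models = ("BM1", "EB", "BMMs", "BMMsm", "OU1")
    tab, _ = at.fit_all_models(tree, Z, parts, diets, n_maps=1, seed=6,
                               models=models)
    ll = dict(zip(tab["model"], tab["logL"]))
    assert ll["EB"] >= ll["BM1"] - 1e-6        # EB nests BM1 at r=0
    assert ll["BMMs"] >= ll["BM1"] - 1e-4      # extra rate matrix
    assert ll["BMMsm"] >= ll["BM1"] - 1e-6     # extra mean vectors
    # trait-order permutation leaves the AICc ranking unchanged
    perm = [2, 0, 1]
    tab2, _ = at.fit_all_models(tree, Z[:, perm], parts, diets, n_maps=1,
                                seed=6, models=models)
    assert list(tab["model"]) == list(tab2["model"])
    np.testing.assert_allclose(tab["AICc"], tab2["AICc"], atol=0.15)
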
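import numpy as np
import pytest
from scipy.stats import ortho_group

from allometree.convergence import (ancestral_states_bm,
                                    angle_state_convergence, c_metrics,
                                    c_significance, pic_rate_matrix)
from allometree.tree import Phylo


def _dense_gls_ancestors(tree, X):
    """Independent oracle: ML-under-BM states from the joint covariance,
    conditioning internal nodes on tips explicitly."""
    n = tree.n_tips
    C = tree.vcv_all()
    Ctt = C[:n, :n]
    Cnt = C[n:, :n]
    Cinv = np.linalg.inv(Ctt)
    one = np.ones(n)
    mu = (one @ Cinv @ X) / (one @ Cinv @ one)
    cond = mu + Cnt @ Cinv @ (X - mu)
    return np.vstack([X, cond])


def test_two_tip_root_is_midpoint():
    tree = Phylo.from_newick("(A:1,B:1);")
    st = ancestral_states_bm(tree, np.array([[1.0], [3.0]]))
    assert st[-1, 0] == pytest.approx(2.0, rel=1e-12)


def test_star_tree_root_is_tip_mean():
    tree = Phylo.from_newick("(A:2,B:2,C:2,D:2,E:2);")
    vals = np.array([[1.0], [2.0], [3.0], [4.0], [10.0]])
    st = ancestral_states_bm(tree, vals)
    assert st[-1, 0] == pytest.approx(vals.mean(), rel=1e-12)


def test_ancestral_states_match_dense_gls(rng):
    from allometree.simulate import simulate_tree
    tree = simulate_tree(8, seed=17, height=40)
    X = rng.normal(0, 1, (8, 3))
    mine = ancestral_states_bm(tree, X)
    oracle = _dense_gls_ancestors(tree, X)
    np.testing.assert_allclose(mine, oracle, atol=1e-8)


def test_c1_is_one_for_identical_focal_tips(balanced6):
    X = np.zeros((6, 2))
    X[2:] = np.array([[2.0, 0], [3.0, 1.0], [1.0, 2.0], [0.5, -1.0]])
    res = c_metrics(balanced6, X, ["A", "B"])  # A and B identical at origin
    assert res.C["C1"] == pytest.approx(1.0)
    assert res.C["C2"] > 0


def test_c1_zero_for_sisters_that_never_converged():
    # Two sister tips diverging monotonically: Dmax is attained at the tips
    tree = Phylo.from_newick("((A:1,B:1):1,C:2);")
    X = np.array([[1.0], [-1.0], [0.0]])
    res = c_metrics(tree, X, ["A", "B"])
    assert res.C["C1"] == pytest.approx(0.0, abs=1e-12)
    assert res.C["C2"] == pytest.approx(0.0, abs=1e-12)


def _brute_force_c(tree, X, focal):
    """Path-enumeration oracle for C1-C4 (average over focal pairs)."""
    states = _dense_gls_ancestors(tree, X)
    idx = {lab: i for i, lab in enumerate(tree.labels)}

    def up_path(v, top):
        out = [v]
        while v != top:
            v = tree.parent[v]
            out.append(v)
        return out

    def mrca(a, b):
        anc = set(up_path(a, tree.root))
        v = b
        while v not in anc:
            v = tree.parent[v]
        return v

    vals = {c: [] for c in ("C1", "C2", "C3", "C4")}
    focal_i = [idx[f] for f in focal]
    for i, s in enumerate(focal_i):
        for t in focal_i[i + 1:]:
            m = mrca(s, t)
            ps, pt = up_path(s, m), up_path(t, m)
            dtip = np.linalg.norm(states[s] - states[t])
            dmax = max(np.linalg.norm(states[u] - states[v])
                       for u in ps for v in pt)
            c2 = dmax - dtip
            lin = sum(np.linalg.norm(states[v] - states[tree.parent[v]])
                      for v in ps[:-1] + pt[:-1])
            clade_nodes = [v for v in range(tree.n_nodes)
                           if m in up_path(v, tree.root) and v != m]
            clade = sum(np.linalg.norm(states[v] - states[tree.parent[v]])
                        for v in clade_nodes)
            vals["C1"].append(1 - dtip / dmax)
            vals["C2"].append(c2)
            vals["C3"].append(c2 / lin)
            vals["C4"].append(c2 / clade)
    return {k: float(np.mean(v)) for k, v in vals.items()}


def test_c_metrics_match_brute_force_oracle(balanced6, rng):
    X = rng.normal(0, 1, (6, 3))
    focal = ["A", "C", "E"]
    mine = c_metrics(balanced6, X, focal)
    oracle = _brute_force_c(balanced6, X, focal)
    for k in ("C1", "C2", "C3", "C4"):
        assert mine.C[k] == pytest.approx(oracle[k], abs=1e-10)


def test_c_metrics_rigid_motion_invariance(balanced6, rng):
    X = rng.normal(0, 1, (6, 3))
    focal = ["B", "D", "F"]
    base = c_metrics(balanced6, X, focal)
    Q = ortho_group.rvs(3, random_state=3)
    moved = c_metrics(balanced6, X @ Q + np.array([5.0, -2.0, 1.0]), focal)
    for k in ("C1", "C2", "C3", "C4"):
        assert moved.C[k] == pytest.approx(base.C[k], rel=1e-9, abs=1e-12)


def test_c_significance_deterministic_under_seed(balanced6, rng):
    X = rng.normal(0, 1, (6, 2))
    r1 = c_significance(balanced6, X, ["A", "C"], n_sims=120, seed=5)
    r2 = c_significance(balanced6, X, ["A", "C"], n_sims=120, seed=5)
    assert r1.p == r2.p


def test_pic_rate_matrix_recovers_bm_rate():
    from allometree.simulate import simulate_coefficients, simulate_tree
    tree = simulate_tree(150, seed=23, height=50)
    R = np.array([[0.04, 0.01], [0.01, 0.02]])
    d = simulate_coefficients(tree, "BM1", {"R": R, "root": np.zeros(2)},
                              seed=9, zero_sum=False)
    Z = np.array([d[lab] for lab in tree.labels])
    Rhat = pic_rate_matrix(tree, Z)
    np.testing.assert_allclose(Rhat, R, rtol=0.35, atol=0.01)


def test_angle_hand_values():
    tree = Phylo.from_newick("(A:1,(B:0.5,C:0.5):0.5);")
    V = np.array([[1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    states = {"A": "s", "B": "s", "C": "s"}
    res = angle_state_convergence(tree, V, states, "s", n_null=50, seed=0,
                                  center=np.zeros(2))
    # pairs: (A,B)=45, (A,C)=90, (B,C)=45 -> mean 60
    assert res.ang_state == pytest.approx(60.0, abs=1e-9)
    assert res.ang_state_time >= 0


def test_angle_scale_invariance(balanced6, rng):
    V = rng.normal(0, 1, (6, 3))
    states = dict(zip(balanced6.labels, ["s", "s", "x", "s", "x", "s"]))
    a1 = angle_state_convergence(balanced6, V, states, "s", n_null=60, seed=2,
                                 center=np.zeros(3))
    a2 = angle_state_convergence(balanced6, 7.5 * V, states, "s", n_null=60,
                                 seed=2, center=np.zeros(3))
    assert a2.ang_state == pytest.approx(a1.ang_state, rel=1e-10)


def test_angle_cross_partition_pairing(balanced6):
    V = np.array([[1.0, 0], [0, 1.0], [1, 1.0], [-1, 0.0], [0, -1.0],
                  [1, 0.5]])
    states = dict(zip(balanced6.labels, ["s"] * 6))
    parts = dict(zip(balanced6.labels, ["P1", "P1", "P1", "P2", "P2", "P2"]))
    res = angle_state_convergence(balanced6, V, states, "s", partitions=parts,
                                  n_null=50, seed=1, center=np.zeros(2))
    assert len(res.pairs) == 9  # 3 x 3 cross-partition pairs only
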
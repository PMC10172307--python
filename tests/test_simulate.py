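import numpy as np
import pytest

import allometree as at
from allometree.evomodels import RegimePainting
from allometree.io import prune_by_sample_size
from allometree.simulate import (generate_specimens, survey_scale,
                                 simulate_coefficients,
                                 simulate_discrete_states, simulate_tree)


def test_tree_minimal_and_ultrametric():
    tree = simulate_tree(3, seed=0)
    assert tree.n_tips == 3
    assert tree.n_nodes == 5            # 3 tips + 2 internal nodes
    assert tree.is_ultrametric(1e-9)
    assert tree.height == pytest.approx(70.0, rel=1e-9)


def test_tree_deterministic_under_seed():
    assert simulate_tree(12, seed=42).to_newick() == \
        simulate_tree(12, seed=42).to_newick()
    assert simulate_tree(12, seed=42).to_newick() != \
        simulate_tree(12, seed=43).to_newick()


def test_yule_waiting_times_scale_inversely_with_lineages():
    """Under a pure-birth process the expected waiting time between the
    k-lineage and (k+1)-lineage stage is 1/(k*lambda): successive
    inter-split gaps, averaged over replicates, should shrink like 1/k."""
    gaps = []
    for seed in range(300):
        tree = simulate_tree(10, seed=seed, height=1.0)
        splits = np.sort(tree.depth[tree.n_tips:])
        gaps.append(np.diff(splits))
    mean_gaps = np.mean(gaps, axis=0)          # stage k = 2..9
    k = np.arange(2, 10)
    scaled = mean_gaps * k                      # should be ~constant
    assert scaled.std() / scaled.mean() < 0.25


def test_bm_zero_rate_keeps_root_state():
    tree = simulate_tree(6, seed=1)
    root = np.array([0.3, -0.3])
    out = simulate_coefficients(tree, "BM1",
                                {"R": np.zeros((2, 2)), "root": root},
                                seed=0, zero_sum=False)
    for v in out.values():
        np.testing.assert_allclose(v, root, atol=1e-14)


def test_ou_huge_alpha_pins_tips_to_optimum():
    tree = simulate_tree(6, seed=2)
    theta = np.array([1.0, -2.0])
    out = simulate_coefficients(
        tree, "OU1",
        {"R": 1e-6 * np.eye(2), "root": np.zeros(2),
         "alpha": np.array([50.0, 50.0]), "theta": theta},
        seed=3, zero_sum=False)
    for v in out.values():
        np.testing.assert_allclose(v, theta, atol=1e-2)


def test_bm_tip_covariance_matches_shared_times():
    tree = simulate_tree(8, seed=9, height=10)
    R = np.array([[0.05]])
    reps = 1500
    tips = np.array([
        [simulate_coefficients(tree, "BM1", {"R": R, "root": np.zeros(1)},
                               seed=i, zero_sum=False)[lab][0]
         for lab in tree.labels]
        for i in range(reps)])
    emp = np.cov(tips.T)
    theo = tree.vcv() * 0.05
    assert np.abs(emp - theo).max() < 0.12 * theo.max()


def test_discrete_states_painting_consistent():
    tree = simulate_tree(25, seed=5)
    tips, painting = simulate_discrete_states(tree, ("a", "b", "c"),
                                              rate=0.03, seed=7)
    lut = {s: i for i, s in enumerate(painting.states)}
    for i, lab in enumerate(tree.labels):
        assert painting.tip_state(i) == lut[tips[lab]]
    for v in range(tree.n_nodes):
        if tree.parent[v] >= 0:
            assert sum(d for _, d in painting.segments[v]) == pytest.approx(
                tree.edge_len[v], rel=1e-9)


def test_simulated_coefficients_zero_sum_by_default():
    tree = simulate_tree(10, seed=4)
    out = simulate_coefficients(tree, "BM1",
                                {"R": 0.01 * np.eye(5),
                                 "root": np.zeros(5)}, seed=6)
    for v in out.values():
        assert abs(v.sum()) < 1e-12


def test_noise_free_specimens_recover_beta_exactly():
    table, meta, tree, truth = survey_scale(seed=11, n_species=8, min_big=8,
                                           sigma_meas=0.0)
    shape = at.to_shape_ratios(table)
    for coeff in at.fit_all_trajectories(shape):
        np.testing.assert_allclose(coeff.b, truth.beta[coeff.species],
                                   atol=1e-10)


def test_noisy_recovery_mean_absolute_error():
    """sigma = 0.02, 30 specimens: slope error stays below the noise scale."""
    table, meta, tree, truth = survey_scale(seed=13, n_species=10, min_big=10,
                                           sigma_meas=0.02)
    truth.n_specimens = {sp: 30 for sp in truth.beta}
    table = generate_specimens(truth)
    errs = []
    for coeff in at.fit_all_trajectories(at.to_shape_ratios(table)):
        errs.append(np.abs(coeff.b - truth.beta[coeff.species]).mean())
    assert np.mean(errs) < 0.02


def test_survey_scale_preset_structure():
    table, meta, tree, truth = survey_scale(seed=1)
    assert len(table.species) == 62
    assert tree.n_tips == 62
    assert 1700 <= table.n_specimens <= 2400
    pruned = prune_by_sample_size(table, 15)
    assert len(pruned.species) == 50
    # metadata is complete and internally consistent
    assert set(meta.df["species"]) == set(table.species)
    assert set(meta.df["diet"]) <= {"animalivory", "herbivory", "mycophagy",
                                    "omnivory"}
    parts = meta.df["partition"].value_counts()
    assert set(parts.index) == {"Ameridelphia", "Australidelphia"}
    # determinism
    t2, m2, tr2, _ = survey_scale(seed=1)
    assert t2.df.equals(table.df)
    assert tr2.to_newick() == tree.to_newick()
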
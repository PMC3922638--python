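"""Tree-structured stick-breaking: weights, forward sampling, Gibbs kernels."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

from clonetree.model import SampleSet, SnvObservation, default_genotype_config
from clonetree.tssb import (
    CloneTree,
    cull_tree,
    forward_sample_tree,
    gibbs_assignments,
    gibbs_sticks_and_hypers,
    node_weight,
    reattach_moves,
)


def build_tree(rng=None, **kw):
    return CloneTree(1, rng=rng or np.random.default_rng(0), **kw)


class TestNodeWeight:
    def test_root_takes_everything(self):
        tree = build_tree()
        tree.root.nu = 1.0
        assert node_weight(tree, tree.root) == pytest.approx(1.0)

    def test_root_weight_is_nu(self):
        tree = build_tree()
        tree.root.nu = 0.37
        assert node_weight(tree, tree.root) == pytest.approx(0.37)

    def test_hand_evaluated_child(self):
        rng = np.random.default_rng(0)
        tree = build_tree(rng)
        tree.root.nu = 0.5
        child = tree._spawn_child(tree.root, rng)
        tree.root.psi[0] = 1.0
        child.nu = 0.5
        assert node_weight(tree, tree.root) == pytest.approx(0.5)
        assert node_weight(tree, child) == pytest.approx(0.25)

    def test_mass_partition_sums_to_one(self):
        rng = np.random.default_rng(3)
        tree = build_tree(rng, alpha0=10.0, gamma=2.0, lam=0.5)
        for _ in range(30):  # instantiate a random tree
            tree.find_node(rng.uniform(), rng)
        nodes, omega, residual = tree.mass_partition()
        assert omega.sum() + residual.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(omega >= 0) and np.all(residual >= 0)
        for k, node in enumerate(nodes):
            assert omega[k] == pytest.approx(node_weight(tree, node), rel=1e-12)


class TestForwardSampling:
    def test_vanishing_concentration_collapses_to_root(self):
        paths = forward_sample_tree(50, alpha0=1e-9, gamma=1.0, lam=1.0, seed=0)
        assert all(p == () for p in paths)

    def test_cluster_count_monotone_in_alpha0(self):
        rng = np.random.default_rng(5)
        means = {}
        for alpha0 in (1.0, 50.0):
            counts = [
                len(set(forward_sample_tree(50, alpha0, 1.0, 1.0, rng)))
                for _ in range(500)
            ]
            means[alpha0] = np.mean(counts)
        assert means[50.0] > means[1.0]

    def test_deterministic_given_seed(self):
        a = forward_sample_tree(30, 5.0, 1.0, 0.5, seed=42)
        b = forward_sample_tree(30, 5.0, 1.0, 0.5, seed=42)
        assert a == b

    def test_depth_decreases_with_lambda(self):
        rng = np.random.default_rng(9)
        mean_depth = {}
        for lam in (0.25, 1.0):
            depths = [
                np.mean([len(p) for p in forward_sample_tree(30, 10.0, 1.0, lam, rng)])
                for _ in range(200)
            ]
            mean_depth[lam] = np.mean(depths)
        assert mean_depth[0.25] < mean_depth[1.0]


def two_cluster_dataset(depth=10000):
    geno = default_genotype_config(2, "heterozygous", 0.001)
    rng = np.random.default_rng(17)
    snvs = []
    for k, phi in enumerate((0.9, 0.1)):
        p_var = 1 - ((1 - phi) * 0.999 + phi * 0.5)
        for j in range(5):
            b = int(rng.binomial(depth, p_var))
            snvs.append(SnvObservation(f"c{k}_{j}", (b,), (depth,), geno))
    return SampleSet(snvs)


class TestGibbsKernels:
    def test_well_separated_clusters_cocluster(self):
        data = two_cluster_dataset()
        rng = np.random.default_rng(1)
        tree = CloneTree(1, alpha0=5.0, gamma=1.0, lam=0.5, rng=rng)
        for i in range(data.n_snvs):
            tree.root.snvs.add(i)
            tree.assignments[i] = tree.root
        tree.update_phis()
        from clonetree.freqs import multisample_mh_step

        hits = 0
        total = 0
        for sweep in range(100):
            gibbs_assignments(tree, data, rng)
            gibbs_sticks_and_hypers(tree, rng, n_hyper_steps=0)
            cull_tree(tree)
            multisample_mh_step(tree, data, sigma=100, n_iters=20, rng=rng)
            if sweep >= 20:
                z = [id(tree.assignments[i]) for i in range(10)]
                same_a = sum(z[j] == z[0] for j in range(5))
                same_b = sum(z[5 + j] == z[5] for j in range(5))
                hits += same_a + same_b
                total += 10
        assert hits / total > 0.95

    def test_hypers_stay_on_grid(self, zero_depth_dataset):
        rng = np.random.default_rng(2)
        tree = CloneTree(1, alpha0=4.0, gamma=2.0, lam=0.5, rng=rng)
        for i in range(zero_depth_dataset.n_snvs):
            tree.root.snvs.add(i)
            tree.assignments[i] = tree.root
        tree.update_phis()
        for _ in range(50):
            gibbs_assignments(tree, zero_depth_dataset, rng)
            gibbs_sticks_and_hypers(tree, rng)
            cull_tree(tree)
        assert tree.alpha0 in tree.hyperparam_ranges["alpha0"]
        assert tree.gamma in tree.hyperparam_ranges["gamma"]
        assert tree.lam in tree.hyperparam_ranges["lam"]

    def test_occupied_nu_shrinks_with_descendant_mass(self):
        """A node with all data below it and none at it concentrates nu
        below the prior mean."""
        rng = np.random.default_rng(3)
        tree = CloneTree(1, alpha0=2.0, gamma=1.0, lam=1.0, rng=rng)
        child = tree._spawn_child(tree.root, rng)
        for i in range(30):
            child.snvs.add(i)
            tree.assignments[i] = child
        draws = []
        for _ in range(300):
            gibbs_sticks_and_hypers(tree, rng, n_hyper_steps=0)
            draws.append(tree.root.nu)
        prior_mean = 1.0 / (1.0 + tree.alpha0)
        assert np.mean(draws) < prior_mean / 3


class TestCull:
    def test_single_occupied_root_unchanged(self):
        rng = np.random.default_rng(0)
        tree = CloneTree(1, rng=rng)
        tree.root.snvs.add(0)
        cull_tree(tree)
        assert tree.n_nodes() == 1

    def test_empty_tail_removed_and_mass_returned(self):
        rng = np.random.default_rng(0)
        tree = CloneTree(1, rng=rng)
        a = tree._spawn_child(tree.root, rng)
        b = tree._spawn_child(a, rng)
        a.snvs.add(0)
        tree.assignments[0] = a
        eta_a, eta_b = a.eta.copy(), b.eta.copy()
        cull_tree(tree)
        assert b not in a.children
        assert a.eta == pytest.approx(eta_a + eta_b)

    def test_eta_conserved(self):
        rng = np.random.default_rng(4)
        tree = CloneTree(2, rng=rng)
        for _ in range(20):
            tree.find_node(rng.uniform(), rng)
        total_before = sum(n.eta for n in tree.nodes())
        cull_tree(tree)
        total_after = sum(n.eta for n in tree.nodes())
        np.testing.assert_allclose(total_before, np.ones(2), atol=1e-9)
        np.testing.assert_allclose(total_after, np.ones(2), atol=1e-9)


class TestPriorEquivalence:
    def test_full_kernel_matches_forward_sampling(self, zero_depth_dataset):
        """With no reads the Gibbs kernel must sample the TSSB prior: the
        occupied-cluster-count distribution matches forward draws."""
        from clonetree.mcmc import McmcConfig, run_mcmc

        cfg = McmcConfig(
            n_iters=3000, burn_in=500, mh_iters=2, seed=11,
            fixed_hypers=(5.0, 1.0, 0.5),
        )
        trace = run_mcmc(zero_depth_dataset, cfg)
        gibbs_counts = np.array([len(set(s.z)) for s in trace.snapshots])[::10]
        rng = np.random.default_rng(12)
        fwd_counts = np.array(
            [len(set(forward_sample_tree(8, 5.0, 1.0, 0.5, rng))) for _ in range(3000)]
        )
        assert ks_2samp(gibbs_counts, fwd_counts).pvalue > 0.01

    def test_two_snv_coclustering_matches_closed_form(self, zero_depth_dataset):
        """P(two prior draws share a node) = E[sum omega^2], computable by a
        depth recursion over the stick moments."""
        alpha0, gamma, lam = 5.0, 1.0, 0.5
        s = 1.0
        for d in reversed(range(300)):
            a = (lam**d) * alpha0
            e_nu2 = 2.0 / ((1 + a) * (2 + a))
            e_1mnu2 = 1 - 2.0 / (1 + a) + e_nu2
            s = e_nu2 + e_1mnu2 * (1.0 / (gamma + 1)) * s
        rng = np.random.default_rng(13)
        co = np.mean(
            [len(set(forward_sample_tree(2, alpha0, gamma, lam, rng))) == 1
             for _ in range(20000)]
        )
        assert co == pytest.approx(s, abs=0.01)
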
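"""Auxiliary-weight frequency sampler: prior draws, phi recursion, MH."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

from clonetree.freqs import (
    WeightVector,
    draw_frequencies,
    log_eta_prior,
    mh_update_weights,
    multisample_mh_step,
    phi_from_eta,
)
from clonetree.model import SampleSet, SnvObservation, default_genotype_config
from clonetree.tssb import CloneTree


def chain_tree(n_nodes, n_samples=1, seed=0):
    """root -> a -> b ... with fresh prior sticks."""
    rng = np.random.default_rng(seed)
    tree = CloneTree(n_samples, rng=rng)
    node = tree.root
    for _ in range(n_nodes - 1):
        node = tree._spawn_child(node, rng)
    tree.update_phis()
    return tree


def star_tree(n_children, n_samples=1, seed=0):
    rng = np.random.default_rng(seed)
    tree = CloneTree(n_samples, rng=rng)
    for _ in range(n_children):
        tree._spawn_child(tree.root, rng)
    tree.update_phis()
    return tree


class TestPhiFromEta:
    def test_leaf_phi_equals_eta(self):
        tree = chain_tree(2)
        phi = phi_from_eta(tree, {(): 0.7, (0,): 0.3})
        assert phi[(0,)] == pytest.approx(0.3)

    def test_star_hand_example(self):
        tree = star_tree(2)
        phi = phi_from_eta(tree, {(): 0.5, (0,): 0.3, (1,): 0.2})
        assert phi[()] == pytest.approx(1.0)
        assert phi[(0,)] == pytest.approx(0.3)
        assert phi[(1,)] == pytest.approx(0.2)

    def test_chain_hand_example(self):
        tree = chain_tree(3)
        phi = phi_from_eta(tree, {(): 0.2, (0,): 0.3, (0, 0): 0.5})
        assert phi[()] == pytest.approx(1.0)
        assert phi[(0,)] == pytest.approx(0.8)
        assert phi[(0, 0)] == pytest.approx(0.5)

    def test_missing_weight_errors(self):
        tree = chain_tree(2)
        with pytest.raises(KeyError):
            phi_from_eta(tree, {(): 1.0})


class TestWeightVector:
    def test_must_sum_to_one(self):
        with pytest.raises(ValueError):
            WeightVector({(): 0.5, (0,): 0.2})


class TestDrawFrequencies:
    def test_single_node(self):
        tree = chain_tree(1)
        draw_frequencies(tree, np.random.default_rng(0))
        assert tree.root.eta[0] == pytest.approx(1.0)
        assert tree.root.phi[0] == pytest.approx(1.0)

    def test_constraints_hold_over_many_draws(self):
        tree = chain_tree(3)
        rng = np.random.default_rng(1)
        for _ in range(10000):
            draw_frequencies(tree, rng)
            etas = np.array([n.eta[0] for n in tree.nodes()])
            assert etas.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(etas >= 0)
            for node in tree.nodes():
                child_sum = sum(c.phi[0] for c in node.children)
                assert node.phi[0] >= child_sum - 1e-12

    def test_multi_sample_independent(self):
        tree = star_tree(2, n_samples=3)
        rng = np.random.default_rng(2)
        draw_frequencies(tree, rng)
        total = sum(n.eta for n in tree.nodes())
        np.testing.assert_allclose(total, np.ones(3), atol=1e-12)


class TestMhUpdateWeights:
    def test_flat_likelihood_recovers_prior(self):
        """With no reads, the MH chain's stationary law is the breadth-first
        uniform-split prior (per-coordinate KS against direct draws)."""
        tree = chain_tree(3, seed=3)
        rng = np.random.default_rng(4)
        samples = []
        # the sigma=100 Dirichlet walk is heavily autocorrelated on the
        # prior; thin far past the integrated autocorrelation time (~230
        # iterations) so the KS comparison sees near-independent draws
        mh_update_weights(
            tree, None, 0, sigma=100.0, n_iters=200000, rng=rng,
            trace_out=samples, trace_every=250,
        )
        mh_eta = np.array([s[:, 0] for s in samples])  # [T, K]
        direct = []
        tree2 = chain_tree(3, seed=3)
        rng2 = np.random.default_rng(5)
        for _ in range(2000):
            draw_frequencies(tree2, rng2)
            direct.append([n.eta[0] for n in tree2.nodes()])
        direct = np.array(direct)
        for k in range(3):
            assert ks_2samp(mh_eta[:, k], direct[:, k]).pvalue > 0.01

    def test_posterior_mean_matches_grid_integration(self):
        """Two-node chain with one SNV at the child: the MH posterior mean of
        phi_child matches numerical integration of binomial x uniform."""
        geno = default_genotype_config(2, "heterozygous", 0.001)
        data = SampleSet([SnvObservation("v", (2500,), (10000,), geno)])
        tree = chain_tree(2, seed=6)
        child = tree.root.children[0]
        child.snvs.add(0)
        tree.assignments[0] = child
        rng = np.random.default_rng(7)
        samples = []
        mh_update_weights(
            tree, data, 0, sigma=100.0, n_iters=30000, rng=rng,
            trace_out=samples, trace_every=10,
        )
        phis = np.array([s[1, 0] for s in samples])  # child eta == child phi
        # grid integration: posterior prop. to Binom(b; d, 1-p_ref(phi)) times
        # the uniform prior of the child weight on [0, 1]
        from scipy.stats import binom

        grid = np.linspace(1e-6, 1 - 1e-6, 20001)
        p_ref = (1 - grid) * 0.999 + grid * 0.5
        like = binom.pmf(2500, 10000, 1 - p_ref)
        post_mean = float((grid * like).sum() / like.sum())
        mc_se = phis.std() / np.sqrt(len(phis) / 20)  # generous ESS discount
        assert post_mean == pytest.approx(0.5, abs=0.02)
        assert abs(phis.mean() - post_mean) < max(3 * mc_se, 0.02)

    def test_accept_identity_proposal(self):
        # proposing the current state must be accepted: ratio is exactly 1
        tree = chain_tree(2, seed=8)
        rng = np.random.default_rng(9)
        wv = mh_update_weights(tree, None, 0, sigma=100.0, n_iters=1, rng=rng)
        assert sum(wv.eta.values()) == pytest.approx(1.0, abs=1e-9)


class TestMultisample:
    def test_single_sample_reduces_to_mh_update(self):
        tree_a = chain_tree(3, seed=10)
        tree_b = chain_tree(3, seed=10)
        rng_a = np.random.default_rng(11)
        rng_b = np.random.default_rng(11)
        mh_update_weights(tree_a, None, 0, sigma=50.0, n_iters=200, rng=rng_a)
        multisample_mh_step(tree_b, None, sigma=50.0, n_iters=200, rng=rng_b)
        for na, nb in zip(tree_a.nodes(), tree_b.nodes()):
            np.testing.assert_allclose(na.eta, nb.eta, atol=1e-12)

    def test_symmetric_samples_agree(self):
        geno = default_genotype_config(2, "heterozygous", 0.001)
        data = SampleSet(
            [SnvObservation("v", (300, 300), (1000, 1000), geno)]
        )
        tree = chain_tree(2, n_samples=2, seed=12)
        child = tree.root.children[0]
        child.snvs.add(0)
        tree.assignments[0] = child
        rng = np.random.default_rng(13)
        acc = np.zeros(2)
        n_keep = 0
        for _ in range(300):
            eta = multisample_mh_step(tree, data, sigma=100.0, n_iters=20, rng=rng)
            acc += eta[1]
            n_keep += 1
        means = acc / n_keep
        assert abs(means[0] - means[1]) < 0.05

    def test_crossing_frequencies_tracked(self):
        """Fixed branching tree, two samples with crossed cluster
        frequencies: the per-sample phi estimates follow the truth."""
        geno = default_genotype_config(2, "heterozygous", 0.001)
        rng = np.random.default_rng(14)
        truth = {"b": (0.4, 0.2), "c": (0.2, 0.4)}
        snvs = []
        for name, phis in truth.items():
            for j in range(3):
                bs, ds = [], []
                for phi in phis:
                    d = 10000
                    p_var = 1 - ((1 - phi) * 0.999 + phi * 0.5)
                    bs.append(int(rng.binomial(d, p_var)))
                    ds.append(d)
                snvs.append(SnvObservation(f"{name}{j}", tuple(bs), tuple(ds), geno))
        data = SampleSet(snvs)
        tree = star_tree(2, n_samples=2, seed=15)
        for i in range(3):
            tree.root.children[0].snvs.add(i)
            tree.assignments[i] = tree.root.children[0]
        for i in range(3, 6):
            tree.root.children[1].snvs.add(i)
            tree.assignments[i] = tree.root.children[1]
        tree.update_phis()
        from clonetree.freqs import freq_jump_moves

        acc = np.zeros((2, 2))
        for sweep in range(400):
            multisample_mh_step(tree, data, sigma=100.0, n_iters=10, rng=rng)
            freq_jump_moves(tree, data, rng)
            if sweep >= 100:
                acc[0] += tree.root.children[0].phi
                acc[1] += tree.root.children[1].phi
        est = acc / 300
        np.testing.assert_allclose(est[0], truth["b"], atol=0.05)
        np.testing.assert_allclose(est[1], truth["c"], atol=0.05)

    def test_conservation_and_ordering_every_step(self):
        geno = default_genotype_config(2, "heterozygous", 0.001)
        data = SampleSet([SnvObservation("v", (100, 50), (400, 400), geno)])
        tree = chain_tree(3, n_samples=2, seed=16)
        node = tree.root.children[0]
        node.snvs.add(0)
        tree.assignments[0] = node
        rng = np.random.default_rng(17)
        for _ in range(50):
            multisample_mh_step(tree, data, sigma=100.0, n_iters=5, rng=rng)
            total = sum(n.eta for n in tree.nodes())
            np.testing.assert_allclose(total, np.ones(2), atol=1e-9)
            for n in tree.nodes():
                child_sum = sum(c.phi for c in n.children)
                assert np.all(n.phi >= child_sum - 1e-9)
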
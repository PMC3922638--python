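"""Posterior sampling over lineage trees.

One Gibbs sweep resamples, in order: SNV-node assignments (slice sampling on
the stick-breaking measure), all sticks and the three stick-breaking
hyperparameters, then — after culling empty leaves — the per-sample
auxiliary weights via Metropolis-Hastings.  The recorded trace stores a
compact snapshot of every post-burn-in sweep together with the complete-data
log likelihood (read-count likelihood plus the log assignment-prior mass
log omega_{z_i}), which is what ranks tree snapshots when a single best tree
is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.tsa.stattools import acf as _acf

from .model import SampleSet
from .tssb import (
    DEFAULT_HYPERPARAM_RANGES,
    CloneTree,
    cull_tree,
    gibbs_assignments,
    gibbs_sticks_and_hypers,
    node_weight,
    reattach_moves,
)
from .freqs import freq_jump_moves, multisample_mh_step

__all__ = [
    "McmcConfig",
    "TreeSnapshot",
    "McmcTrace",
    "run_mcmc",
    "complete_data_log_likelihood",
    "best_tree",
    "trace_diagnostics",
]


class ConfigurationError(ValueError):
    """Invalid MCMC configuration."""


@dataclass(frozen=True)
class McmcConfig:
    """Settings for one MCMC run.

    Defaults follow the reference protocol for targeted deep-sequencing
    panels: 5,000 Gibbs sweeps with a burn-in of 100, 5,000 inner
    Metropolis-Hastings iterations per sweep for the auxiliary weights, and a
    Dirichlet proposal scale sigma = 100.  `fixed_hypers`, when given as
    (alpha0, gamma, lam), pins the stick-breaking hyperparameters instead of
    sampling them over `hyperparam_ranges`.
    """

    n_iters: int = 5000
    burn_in: int = 100
    mh_iters: int = 5000
    sigma: float = 100.0
    seed: int = 0
    hyperparam_ranges: dict = field(
        default_factory=lambda: dict(DEFAULT_HYPERPARAM_RANGES)
    )
    fixed_hypers: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iters:
            raise ConfigurationError("burn_in must be < n_iters")
        if self.n_iters < 1 or self.mh_iters < 1:
            raise ConfigurationError("n_iters and mh_iters must be >= 1")
        if self.sigma <= 0:
            raise ConfigurationError("sigma must be > 0")


@dataclass(frozen=True)
class TreeSnapshot:
    """One recorded posterior tree sample, as flat arrays in BFS node order."""

    parents: np.ndarray  # [K] parent index, -1 for root
    z: np.ndarray  # [N] node index of each SNV
    phi: np.ndarray  # [K, S]
    eta: np.ndarray  # [K, S]
    log_weights: np.ndarray  # [K] log omega of each node
    hypers: tuple[float, float, float]
    loglik_data: float
    loglik_complete: float

    @property
    def n_nodes(self) -> int:
        return len(self.parents)

    def node_genotypes(self, snv_ids: list[str]) -> list[frozenset]:
        """Cumulative genotype (SNVs on the root path) of every node."""
        own: list[set[str]] = [set() for _ in range(self.n_nodes)]
        for i, k in enumerate(self.z):
            own[k].add(snv_ids[i])
        out: list[frozenset] = []
        for k in range(self.n_nodes):
            geno, node = set(), k
            while node != -1:
                geno |= own[node]
                node = self.parents[node]
            out.append(frozenset(geno))
        return out


@dataclass
class McmcTrace:
    """Post-burn-in tree snapshots plus their complete-data log likelihoods."""

    snapshots: list[TreeSnapshot]
    snv_ids: list[str]
    sample_labels: list[str]
    config: McmcConfig

    @property
    def n_samples_recorded(self) -> int:
        return len(self.snapshots)

    @property
    def log_likelihoods(self) -> np.ndarray:
        return np.array([s.loglik_complete for s in self.snapshots])

    def posterior_mean_phi(self) -> np.ndarray:
        """Posterior mean population frequency of each SNV, [N, S]."""
        n = len(self.snv_ids)
        s = len(self.sample_labels)
        acc = np.zeros((n, s))
        for snap in self.snapshots:
            acc += snap.phi[snap.z, :]
        return acc / len(self.snapshots)


def _snapshot(tree: CloneTree, data: SampleSet) -> TreeSnapshot:
    flat = tree.flat()
    phi = np.stack([n.phi for n in flat.nodes])
    logw = np.log(
        np.maximum([node_weight(tree, n) for n in flat.nodes], 1e-300)
    )
    ll_data = float(
        sum(
            data.log_likelihood_snv(i, flat.nodes[flat.z_idx[i]].phi)
            for i in range(data.n_snvs)
        )
    )
    ll_complete = ll_data + float(logw[flat.z_idx].sum())
    return TreeSnapshot(
        parents=flat.parent_idx.copy(),
        z=flat.z_idx.copy(),
        phi=phi,
        eta=flat.eta.copy(),
        log_weights=logw,
        hypers=(tree.alpha0, tree.gamma, tree.lam),
        loglik_data=ll_data,
        loglik_complete=ll_complete,
    )


def complete_data_log_likelihood(
    tree: CloneTree, data: SampleSet
) -> tuple[float, float]:
    """(complete, data-only) log likelihood of the current tree state.

    complete = sum_i sum_t log p(b_i^t | phi_{z_i}^t) + sum_i log omega_{z_i};
    the second element omits the assignment-prior term.
    """
    ll_data = 0.0
    ll_prior = 0.0
    for i, node in tree.assignments.items():
        ll_data += data.log_likelihood_snv(i, node.phi)
        ll_prior += np.log(max(node_weight(tree, node), 1e-300))
    return ll_data + ll_prior, ll_data


def run_mcmc(data: SampleSet, config: McmcConfig) -> McmcTrace:
    """Run the full Gibbs sampler and return the post-burn-in trace."""
    if not isinstance(config, McmcConfig):
        raise ConfigurationError("config must be an McmcConfig")
    rng = np.random.default_rng(config.seed)
    tree = _initial_tree(data, config, rng)
    snapshots: list[TreeSnapshot] = []
    for sweep in range(config.n_iters):
        gibbs_assignments(tree, data, rng)
        gibbs_sticks_and_hypers(
            tree, rng, n_hyper_steps=0 if config.fixed_hypers else 5
        )
        cull_tree(tree)
        reattach_moves(tree, rng)
        multisample_mh_step(
            tree, data, sigma=config.sigma, n_iters=config.mh_iters, rng=rng
        )
        freq_jump_moves(tree, data, rng)
        if sweep >= config.burn_in:
            snapshots.append(_snapshot(tree, data))
    return McmcTrace(snapshots, data.snv_ids, data.sample_labels, config)


def _initial_tree(
    data: SampleSet, config: McmcConfig, rng: np.random.Generator
) -> CloneTree:
    if config.fixed_hypers is not None:
        alpha0, gamma, lam = config.fixed_hypers
    else:
        grid = config.hyperparam_ranges
        alpha0 = float(grid["alpha0"][rng.integers(len(grid["alpha0"]))])
        gamma = float(grid["gamma"][rng.integers(len(grid["gamma"]))])
        lam = float(grid["lam"][rng.integers(len(grid["lam"]))])
    tree = CloneTree(
        data.n_samples,
        alpha0=alpha0,
        gamma=gamma,
        lam=lam,
        hyperparam_ranges=config.hyperparam_ranges,
        rng=rng,
    )
    # Initial state: a frequency-ordered chain with one node per provisional
    # frequency cluster, with auxiliary weights matching the
    # allele-frequency-implied phi.  New nodes can only be born as leaves, so
    # a sampler started from a state that violates the frequency ordering can
    # freeze with high-frequency SNVs trapped above the nodes they belong
    # below; the constraint-consistent chain start avoids that and lets the
    # sweeps merge, split and re-branch from there.  Clusters are cut at 2
    # standard errors of separation — a deliberately coarse seed the sampler
    # is free to rearrange.
    w = np.exp(np.where(np.isneginf(data.log_w), -np.inf, data.log_w))
    mu_v_mean = np.where(w.sum(1) > 0, (w * data.mu_v).sum(1), 0.5)
    af = data.b / np.maximum(data.d, 1.0)  # [N, S]
    denom = np.maximum(data.mu_r - mu_v_mean, 1e-6)
    phi_hat = np.clip((af - (1.0 - data.mu_r[:, None])) / denom[:, None], 0.0, 1.0)
    af_se = np.sqrt(np.maximum(af * (1.0 - af), 1e-9) / np.maximum(data.d, 1.0))
    phi_se = (af_se / denom[:, None]).mean(axis=1) / np.sqrt(data.n_samples)
    order = np.argsort(-phi_hat.mean(axis=1), kind="stable")

    clusters: list[list[int]] = [[int(order[0])]]
    for prev, i in zip(order[:-1], order[1:]):
        gap = phi_hat[prev].mean() - phi_hat[i].mean()
        if gap > 2.0 * np.hypot(phi_se[prev], phi_se[i]):
            clusters.append([])
        clusters[-1].append(int(i))

    chain: list = []
    parent = tree.root
    for members in clusters:
        node = tree._spawn_child(parent, rng)
        for i in members:
            node.snvs.add(i)
            tree.assignments[i] = node
        chain.append(node)
        parent = node
    # project per-sample cluster-mean phi onto the chain's monotone cone and
    # convert to eta (phi differences along the chain)
    phi_cluster = np.stack([phi_hat[m].mean(axis=0) for m in clusters])  # [K, S]
    phi_target = np.minimum.accumulate(phi_cluster, axis=0)
    tree.root.eta = 1.0 - phi_target[0]
    for k, node in enumerate(chain):
        below = phi_target[k + 1] if k + 1 < len(chain) else np.zeros(data.n_samples)
        node.eta = phi_target[k] - below
    tree.update_phis()
    return tree


def best_tree(trace: McmcTrace) -> TreeSnapshot:
    """Snapshot with the highest complete-data log likelihood (earliest wins
    ties)."""
    if not trace.snapshots:
        raise ValueError("empty trace")
    lls = trace.log_likelihoods
    return trace.snapshots[int(np.argmax(lls))]


def trace_diagnostics(trace: McmcTrace | np.ndarray, n_lags: int = 50) -> dict:
    """Normalized autocorrelation function and summary of the likelihood trace.

    For a constant trace the ACF is undefined beyond lag 0 and reported as
    NaN there.
    """
    series = (
        trace.log_likelihoods if isinstance(trace, McmcTrace) else np.asarray(trace)
    )
    if len(series) < 10:
        raise ValueError("need at least 10 post-burn-in samples")
    n_lags = min(n_lags, len(series) - 1)
    if np.ptp(series) == 0:
        acf_vals = np.full(n_lags + 1, np.nan)
        acf_vals[0] = 1.0
    else:
        acf_vals = _acf(series, nlags=n_lags, fft=True)
    return {
        "acf": acf_vals,
        "mean": float(series.mean()),
        "std": float(series.std()),
        "n": int(len(series)),
    }
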
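"""Sampling SNV population frequencies under the clonal ordering constraint.

The infinite sites assumption forces phi_parent >= sum of children's phi in
every sample.  Rather than sampling the frequencies directly on that awkward
constrained set, each node v gets an auxiliary weight eta_v >= 0 with
sum_v eta_v = 1 per sample, and

    phi_v = eta_v + sum_{w in descendants(v)} eta_w

so the constraint holds by construction and the root always has phi = 1.
The prior on eta is generative: the root starts with the full unit mass and,
in breadth-first order, every child draws Uniform(0, eta_parent) and
decrements its parent.  The posterior over eta (read-count likelihood at
phi(eta) times that prior) is sampled with Metropolis-Hastings using an
asymmetric Dirichlet proposal centered on the current weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .model import SampleSet
from .tssb import CloneTree, TreeNode

__all__ = [
    "WeightVector",
    "draw_frequencies",
    "phi_from_eta",
    "log_eta_prior",
    "mh_update_weights",
    "multisample_mh_step",
]

#: Pseudo-floor added to sigma * eta so the Dirichlet proposal stays proper
#: when some weights approach zero.  The acceptance ratio accounts for it.
PROPOSAL_FLOOR = 1e-4

_ETA_TINY = 1e-12  # clamp for proposal draws that underflow to 0


@dataclass(frozen=True)
class WeightVector:
    """Auxiliary weights for one sample, keyed by node path."""

    eta: dict[tuple[int, ...], float]

    def __post_init__(self) -> None:
        total = sum(self.eta.values())
        if abs(total - 1.0) > 1e-9 or any(v < 0 for v in self.eta.values()):
            raise ValueError(f"weights must be >= 0 and sum to 1, got sum {total}")


def phi_from_eta(
    tree: CloneTree, weights: WeightVector | dict[tuple[int, ...], float]
) -> dict[tuple[int, ...], float]:
    """Compute phi_v = eta_v + sum of all descendants' eta for every node."""
    eta = weights.eta if isinstance(weights, WeightVector) else weights
    phi: dict[tuple[int, ...], float] = {}

    def _walk(node: TreeNode) -> float:
        path = node.path()
        if path not in eta:
            raise KeyError(f"missing weight for node {path}")
        total = eta[path] + sum(_walk(c) for c in node.children)
        phi[path] = total
        return total

    _walk(tree.root)
    return phi


def draw_frequencies(tree: CloneTree, rng: np.random.Generator) -> CloneTree:
    """Draw fresh (eta, phi) for every node and sample from the prior.

    Breadth-first: the root starts with the unit mass; each child draws
    Uniform(0, eta_parent) and the parent is decremented, independently per
    sample.
    """
    nodes = tree.nodes()  # BFS order
    for node in nodes:
        node.eta = (
            np.ones(tree.n_samples) if node.parent is None else np.zeros(tree.n_samples)
        )
    for node in nodes:
        for child in node.children:
            draw = rng.uniform(0.0, node.eta)
            child.eta = draw
            node.eta = node.eta - draw
    tree.update_phis()
    return tree


def _phi_arrays(children_idx: list[list[int]], eta: np.ndarray) -> np.ndarray:
    """phi[K, S] from eta[K, S] given children lists in BFS order."""
    phi = eta.copy()
    for k in reversed(range(len(children_idx))):
        for c in children_idx[k]:
            phi[k] += phi[c]
    return phi


def log_eta_prior(children_idx: list[list[int]], eta: np.ndarray) -> float:
    """Log density of eta under the breadth-first Uniform(0, eta_parent) scheme.

    When child j of node v draws, the parent's remaining mass is
    eta_v + sum_{l >= j} phi_{w_l} (each child's draw equals its final
    subtree mass), so the density is the product of 1/remaining over all
    (node, child) pairs and samples.
    """
    phi = _phi_arrays(children_idx, eta)
    logp = 0.0
    for k, kids in enumerate(children_idx):
        if not kids:
            continue
        remaining = eta[k].copy()
        for c in reversed(kids):
            remaining = remaining + phi[c]
            logp -= np.log(np.maximum(remaining, 1e-300)).sum()
    return float(logp)


def _dirichlet_logpdf(x: np.ndarray, alpha: np.ndarray) -> float:
    x = np.maximum(x, _ETA_TINY)
    return float(
        gammaln(alpha.sum())
        - gammaln(alpha).sum()
        + ((alpha - 1.0) * np.log(x)).sum()
    )


def _mh_eta(
    tree: CloneTree,
    data: SampleSet | None,
    sample_indices: list[int],
    sigma: float,
    n_iters: int,
    rng: np.random.Generator,
    floor: float = PROPOSAL_FLOOR,
    trace_out: list | None = None,
    trace_every: int = 1,
) -> np.ndarray:
    """Shared MH core over the auxiliary-weight simplices of the given samples.

    One joint accept/reject per iteration on the product of the per-sample
    posteriors.  Returns the final eta[K, S] and writes it back to the tree.
    """
    if sigma <= 0 or n_iters < 1:
        raise ValueError("need sigma > 0 and n_iters >= 1")
    flat = tree.flat()
    children_idx, z = flat.children_idx, flat.z_idx
    eta = flat.eta.copy()
    observed = z >= 0

    def log_target(eta_mat: np.ndarray) -> float:
        phi = _phi_arrays(children_idx, eta_mat)
        total = 0.0
        for t in sample_indices:
            if data is not None and observed.any():
                total += _loglik_masked(data, t, z, observed, phi)
            total += _log_eta_prior_sample(children_idx, eta_mat[:, t])
        return total

    cur = log_target(eta)
    for it in range(n_iters):
        prop = eta.copy()
        logq_fwd = logq_rev = 0.0
        for t in sample_indices:
            alpha_f = sigma * eta[:, t] + floor
            draw = np.maximum(rng.dirichlet(alpha_f), _ETA_TINY)
            draw = draw / draw.sum()
            prop[:, t] = draw
            alpha_r = sigma * draw + floor
            logq_fwd += _dirichlet_logpdf(draw, alpha_f)
            logq_rev += _dirichlet_logpdf(eta[:, t], alpha_r)
        cand = log_target(prop)
        if np.log(rng.uniform()) < cand - cur + logq_rev - logq_fwd:
            eta, cur = prop, cand
        if trace_out is not None and (it + 1) % trace_every == 0:
            trace_out.append(eta.copy())
    for k, node in enumerate(flat.nodes):
        node.eta = eta[k].copy()
    tree.update_phis()
    return eta


def _log_eta_prior_sample(children_idx: list[list[int]], eta_col: np.ndarray) -> float:
    phi = eta_col.copy()
    for k in reversed(range(len(children_idx))):
        for c in children_idx[k]:
            phi[k] += phi[c]
    logp = 0.0
    for k, kids in enumerate(children_idx):
        remaining = eta_col[k]
        for c in reversed(kids):
            remaining = remaining + phi[c]
            logp -= np.log(max(remaining, 1e-300))
    return logp


def _loglik_masked(
    data: SampleSet, t: int, z: np.ndarray, observed: np.ndarray, phi: np.ndarray
) -> float:
    phi_snv = np.zeros(data.n_snvs)
    phi_snv[observed] = phi[z[observed], t]
    ll = data.log_likelihood_sample(t, phi_snv)
    return float(ll[observed].sum())


def mh_update_weights(
    tree: CloneTree,
    data: SampleSet | None,
    sample_index: int,
    sigma: float = 100.0,
    n_iters: int = 5000,
    rng: np.random.Generator | None = None,
    floor: float = PROPOSAL_FLOOR,
    trace_out: list | None = None,
    trace_every: int = 1,
) -> WeightVector:
    """MH over one sample's auxiliary weights; returns the final state.

    The stationary distribution is the product over SNVs of the
    genotype-marginalized binomial likelihood at phi(eta) of each SNV's node,
    times the breadth-first Uniform prior on eta.  With no data the chain
    samples the prior.
    """
    rng = rng or np.random.default_rng()
    _mh_eta(
        tree, data, [sample_index], sigma, n_iters, rng, floor, trace_out, trace_every
    )
    return WeightVector(
        {node.path(): float(node.eta[sample_index]) for node in tree.nodes()}
    )


def freq_jump_moves(
    tree: CloneTree,
    data: SampleSet,
    rng: np.random.Generator,
    window_broad_weight: float = 0.2,
) -> int:
    """Independence-style MH moves that jump a node's frequency between the
    modes implied by its SNVs' candidate genotypes.

    With genotype marginalization the per-node frequency posterior can be
    multimodal (a heterozygous reading at phi = 2*AF versus a homozygous one
    at phi = AF), and the modes are separated by likelihood barriers far too
    high for the Dirichlet random walk at deep coverage.  The move exchanges
    mass between the node's auxiliary weight and its parent's (every other
    node's phi is untouched), proposing from a mixture of narrow windows
    around each genotype-implied frequency plus a broad uniform component
    that keeps the chain irreducible.  Returns the number of accepted moves.
    """
    tree.update_phis()
    accepted = 0
    nodes = [
        n for n in tree.nodes() if n.parent is not None and n.snvs
    ]
    for v in nodes:
        parent = v.parent
        child_sum = sum((c.phi for c in v.children), np.zeros(tree.n_samples))
        lo = child_sum
        hi = child_sum + v.eta + parent.eta  # take everything the parent holds
        if np.any(hi - lo < 1e-12):
            continue
        # genotype-implied frequency centers and windows, per sample
        centers, widths = [], []
        for i in v.snvs:
            af = data.b[i] / np.maximum(data.d[i], 1.0)  # [S]
            se = np.sqrt(np.maximum(af * (1 - af), 1e-9) / np.maximum(data.d[i], 1.0))
            for g in range(data.mu_v.shape[1]):
                if np.isneginf(data.log_w[i, g]):
                    continue
                denom = max(data.mu_r[i] - data.mu_v[i, g], 1e-6)
                centers.append(np.clip((af - (1 - data.mu_r[i])) / denom, 0, 1))
                widths.append(np.maximum(4.0 * se / denom, 0.01))
        centers = np.stack(centers)  # [M, S]
        widths = np.stack(widths)

        def log_q(phi: np.ndarray) -> float:
            # density of the two-level draw: one shared window index across
            # samples, or the broad uniform in every sample
            inside = np.abs(phi[None, :] - centers) < widths  # [M, S]
            per_window = np.where(inside, 1.0 / (2.0 * widths), 0.0).prod(axis=1)
            narrow = per_window.mean()
            broad = float(np.prod(1.0 / (hi - lo)))
            q = (1 - window_broad_weight) * narrow + window_broad_weight * broad
            return float(np.log(max(q, 1e-300)))

        # draw the proposal
        phi_prop = np.empty(tree.n_samples)
        if rng.uniform() < window_broad_weight:
            phi_prop = rng.uniform(lo, hi)
        else:
            m = rng.integers(len(centers))
            phi_prop = centers[m] + rng.uniform(-widths[m], widths[m])
        if np.any(phi_prop < lo) or np.any(phi_prop > hi):
            continue
        snv_idx = sorted(v.snvs)
        ll_cur = sum(data.log_likelihood_snv(i, v.phi) for i in snv_idx)
        ll_prop = sum(data.log_likelihood_snv(i, phi_prop) for i in snv_idx)
        flat = tree.flat()
        prior_cur = sum(
            _log_eta_prior_sample(flat.children_idx, flat.eta[:, t])
            for t in range(tree.n_samples)
        )
        delta = phi_prop - v.phi
        v.eta = v.eta + delta
        parent.eta = parent.eta - delta
        flat2 = tree.flat()
        prior_prop = sum(
            _log_eta_prior_sample(flat2.children_idx, flat2.eta[:, t])
            for t in range(tree.n_samples)
        )
        log_ratio = (
            ll_prop - ll_cur + prior_prop - prior_cur + log_q(v.phi) - log_q(phi_prop)
        )
        if np.log(rng.uniform()) < log_ratio:
            accepted += 1
            tree.update_phis()
        else:
            v.eta = v.eta - delta
            parent.eta = parent.eta + delta
    return accepted


def multisample_mh_step(
    tree: CloneTree,
    data: SampleSet | None,
    sigma: float = 100.0,
    n_iters: int = 5000,
    rng: np.random.Generator | None = None,
    floor: float = PROPOSAL_FLOOR,
) -> np.ndarray:
    """Joint MH over the auxiliary weights of all samples.

    Proposes every sample's eta from its own Dirichlet and accepts or rejects
    once using the product of per-sample posteriors; for a single sample this
    is exactly `mh_update_weights`.
    """
    rng = rng or np.random.default_rng()
    return _mh_eta(tree, data, list(range(tree.n_samples)), sigma, n_iters, rng, floor)
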
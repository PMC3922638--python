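"""Tree-structured stick-breaking (TSSB) prior over lineage trees.

Two interleaved stick-breaking processes place probability mass on the nodes
of an infinitely deep, infinitely wide rooted tree.  Each node epsilon holds a
depth stick nu_eps ~ Beta(1, alpha(|eps|)) deciding how much of the mass
reaching it stays there versus flowing to descendants, and a sequence of
branch sticks psi ~ Beta(1, gamma) splitting the descendant mass among
children.  The node weights are

    omega_root = nu_root
    omega_eps  = nu_eps * prod_{eps' < eps} (1 - nu_eps') * (psi-branch factors)

and sum to one over the infinite tree.  The depth-dependent concentration
alpha(j) = lambda**j * alpha0 (lambda in (0, 1]) lets deeper nodes hold less
mass, controlling tree height; gamma controls width.  Unlike agglomerative
clusterings, data live at internal nodes too — which is what lets a parental
lineage keep its own SNVs while children add more.

Only the finitely many nodes touched by data or by the samplers are
instantiated; sticks for new regions are drawn lazily on demand.
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np

from .model import SampleSet

__all__ = [
    "TreeNode",
    "CloneTree",
    "DEFAULT_HYPERPARAM_RANGES",
    "node_weight",
    "forward_sample_tree",
    "gibbs_assignments",
    "gibbs_sticks_and_hypers",
    "cull_tree",
]

#: Uniform prior support for the stick-breaking hyperparameters: the
#: log-spaced settings grid the simulations were calibrated over.
DEFAULT_HYPERPARAM_RANGES = {
    "alpha0": (1.0, 2.0, 4.0, 10.0, 20.0, 50.0),
    "gamma": (1.0, 2.0, 4.0, 6.0, 8.0),
    "lam": (0.25, 0.5, 1.0),
}

_MAX_DEPTH = 60  # hard safety bound for lazy descent


class TreeNode:
    """One instantiated node of the lineage tree."""

    __slots__ = ("parent", "children", "psi", "nu", "eta", "phi", "snvs")

    def __init__(self, parent: "TreeNode | None", nu: float, n_samples: int) -> None:
        self.parent = parent
        self.children: list[TreeNode] = []
        self.psi: list[float] = []  # branch stick of children[k]
        self.nu = nu
        self.eta = np.zeros(n_samples)
        self.phi = np.zeros(n_samples)
        self.snvs: set[int] = set()

    def path(self) -> tuple[int, ...]:
        """Index sequence from the root (root = empty tuple)."""
        out: list[int] = []
        node = self
        while node.parent is not None:
            out.append(node.parent.children.index(node))
            node = node.parent
        return tuple(reversed(out))

    @property
    def depth(self) -> int:
        d, node = 0, self
        while node.parent is not None:
            d, node = d + 1, node.parent
        return d


class FlatTree(NamedTuple):
    """Array view of the instantiated tree, in BFS order."""

    nodes: list[TreeNode]
    parent_idx: np.ndarray  # [K], -1 for root
    children_idx: list[list[int]]
    z_idx: np.ndarray  # [N] node position of each SNV (-1 if no data)
    eta: np.ndarray  # [K, S]


class CloneTree:
    """Rooted lineage tree with sticks, weights, frequencies and assignments."""

    def __init__(
        self,
        n_samples: int,
        alpha0: float = 10.0,
        gamma: float = 1.0,
        lam: float = 0.75,
        hyperparam_ranges: dict | None = None,
        rng: np.random.Generator | None = None,
    ) -> None:
        self.n_samples = n_samples
        self.alpha0 = float(alpha0)
        self.gamma = float(gamma)
        self.lam = float(lam)
        self.hyperparam_ranges = dict(hyperparam_ranges or DEFAULT_HYPERPARAM_RANGES)
        rng = rng or np.random.default_rng()
        self.root = TreeNode(None, float(rng.beta(1.0, self.alpha0)), n_samples)
        self.root.eta[:] = 1.0
        self.root.phi[:] = 1.0
        self.assignments: dict[int, TreeNode] = {}  # SNV index -> node

    # ------------------------------------------------------------------ basic
    def alpha(self, depth: int) -> float:
        return (self.lam**depth) * self.alpha0

    def nodes(self) -> list[TreeNode]:
        """All instantiated nodes in BFS order."""
        out, queue = [], [self.root]
        while queue:
            node = queue.pop(0)
            out.append(node)
            queue.extend(node.children)
        return out

    def n_nodes(self) -> int:
        return len(self.nodes())

    def occupied_nodes(self) -> list[TreeNode]:
        return [n for n in self.nodes() if n.snvs]

    def flat(self) -> FlatTree:
        nodes = self.nodes()
        pos = {id(n): k for k, n in enumerate(nodes)}
        parent_idx = np.array(
            [-1 if n.parent is None else pos[id(n.parent)] for n in nodes], dtype=int
        )
        children_idx = [[pos[id(c)] for c in n.children] for n in nodes]
        n_data = max(self.assignments, default=-1) + 1
        z_idx = np.full(n_data, -1, dtype=int)
        for i, node in self.assignments.items():
            z_idx[i] = pos[id(node)]
        eta = np.stack([n.eta for n in nodes]) if nodes else np.zeros((0, self.n_samples))
        return FlatTree(nodes, parent_idx, children_idx, z_idx, eta)

    def update_phis(self) -> None:
        """Recompute phi = eta + sum of descendant eta for every node."""
        nodes = self.nodes()
        for node in reversed(nodes):
            node.phi = node.eta.copy()
            for child in node.children:
                node.phi += child.phi

    # ------------------------------------------------------ lazy instantiation
    def _spawn_child(self, parent: TreeNode, rng: np.random.Generator) -> TreeNode:
        """Instantiate the next child of `parent`, drawing sticks from the
        prior and auxiliary weights eta_w ~ Uniform(0, eta_parent) with the
        parent decremented so that sum(eta) stays 1."""
        parent.psi.append(float(rng.beta(1.0, self.gamma)))
        child = TreeNode(
            parent, float(rng.beta(1.0, self.alpha(parent.depth + 1))), self.n_samples
        )
        for t in range(self.n_samples):
            draw = rng.uniform(0.0, parent.eta[t])
            child.eta[t] = draw
            parent.eta[t] -= draw
        child.phi = child.eta.copy()
        parent.children.append(child)
        return child

    def restore_empty_mass(self) -> None:
        """Return the auxiliary eta of every all-empty subtree to its parent.

        The eta of nodes with no data anywhere below them is conditioned on
        by nothing except the ordering scheme, so it can be redrawn from the
        generative prior at any time; pooling it back first means fresh
        candidate nodes draw from the full mass actually available.
        """
        nodes = self.nodes()
        empty: dict[int, bool] = {}
        for node in reversed(nodes):
            empty[id(node)] = (not node.snvs) and all(
                empty[id(c)] for c in node.children
            )
            if empty[id(node)] and node.parent is not None:
                node.parent.eta += node.eta
                node.eta = np.zeros(self.n_samples)
        self.update_phis()

    def mass_partition(self) -> tuple[list[TreeNode], np.ndarray, np.ndarray]:
        """Instantiated nodes (BFS) with their weights omega and the residual
        prior mass hanging off each node's uninstantiated children.

        sum(omega) + sum(residual) = 1 exactly.
        """
        nodes = self.nodes()
        pos = {id(n): k for k, n in enumerate(nodes)}
        omega = np.zeros(len(nodes))
        residual = np.zeros(len(nodes))
        mass = {id(self.root): 1.0}
        for node in nodes:  # BFS guarantees parents first
            m = mass[id(node)]
            omega[pos[id(node)]] = m * node.nu
            rest = m * (1.0 - node.nu)
            for child, psi in zip(node.children, node.psi):
                mass[id(child)] = rest * psi
                rest *= 1.0 - psi
            residual[pos[id(node)]] = rest
        return nodes, omega, residual

    def sample_open_region(
        self, start: TreeNode, rng: np.random.Generator
    ) -> TreeNode:
        """Draw one node from the TSSB prior restricted to the open stick
        region below `start` (its uninstantiated further children), spawning
        sticks and auxiliary weights lazily along the way."""
        node = start
        for _ in range(_MAX_DEPTH):
            child = self._spawn_child(node, rng)
            if rng.uniform() >= node.psi[-1]:
                continue  # region belongs to a later sibling; spawn the next
            # inside the new child's subtree: stop here with prob nu
            if rng.uniform() < child.nu:
                return child
            node = child  # descend into the child's (fully open) region
        return child

    def find_node(self, u: float, rng: np.random.Generator) -> TreeNode:
        """Map u in [0, 1) to a node through the stick-breaking measure,
        instantiating sticks and nodes lazily along the way."""
        node = self.root
        for _ in range(_MAX_DEPTH):
            if u < node.nu or 1.0 - node.nu < 1e-14:
                return node
            u = (u - node.nu) / (1.0 - node.nu)
            k = 0
            while True:
                if k == len(node.children):
                    self._spawn_child(node, rng)
                psi = node.psi[k]
                if u < psi or 1.0 - psi < 1e-14:
                    node = node.children[k]
                    u = u / psi
                    break
                u = (u - psi) / (1.0 - psi)
                k += 1
        return node

    # ------------------------------------------------------------- weights
    def node_weight(self, node: TreeNode) -> float:
        return node_weight(self, node)

    def instantiated_mass(self) -> tuple[float, float]:
        """(sum of omega over instantiated nodes, residual mass in open sticks).

        The two add to 1 exactly: residual collects the mass flowing past the
        last instantiated child of every node.
        """
        total, residual = 0.0, 0.0
        stack = [(self.root, 1.0)]  # (node, mass reaching its subtree)
        while stack:
            node, mass = stack.pop()
            total += mass * node.nu
            rest = mass * (1.0 - node.nu)
            for child, psi in zip(node.children, node.psi):
                stack.append((child, rest * psi))
                rest *= 1.0 - psi
            residual += rest
        return total, residual


def node_weight(tree: CloneTree, node: TreeNode) -> float:
    """Stick-breaking weight omega of an instantiated node.

    omega = nu_node * prod over ancestors a of (1 - nu_a) * branch factor,
    where the branch factor into child k is psi_k * prod_{j<k}(1 - psi_j).
    """
    weight = node.nu
    child = node
    while child.parent is not None:
        parent = child.parent
        k = parent.children.index(child)
        branch = parent.psi[k]
        for j in range(k):
            branch *= 1.0 - parent.psi[j]
        weight *= (1.0 - parent.nu) * branch
        child = parent
    return weight


def forward_sample_tree(
    n_draws: int,
    alpha0: float,
    gamma: float,
    lam: float,
    seed: int | np.random.Generator = 0,
) -> list[tuple[int, ...]]:
    """Draw node assignments from the TSSB prior by lazy stick instantiation.

    Returns the node index path of each draw; serves as the generative oracle
    for the Gibbs kernels.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tree = CloneTree(1, alpha0=alpha0, gamma=gamma, lam=lam, rng=rng)
    return [tree.find_node(rng.uniform(), rng).path() for _ in range(n_draws)]


# ---------------------------------------------------------------- Gibbs kernels


#: Fresh candidate nodes drawn from the residual prior mass per Gibbs update.
N_AUX_CANDIDATES = 3


def gibbs_assignments(
    tree: CloneTree,
    data: SampleSet,
    rng: np.random.Generator,
    n_aux: int = N_AUX_CANDIDATES,
) -> CloneTree:
    """Resample every SNV's node assignment from its full conditional.

    Each SNV lands on node eps with probability proportional to omega_eps
    times the product over samples of its read-count likelihood at phi_eps.
    The infinitely many uninstantiated nodes are represented by `n_aux`
    auxiliary candidates drawn from the prior restricted to the residual
    stick mass (each carrying fresh sticks and auxiliary weights), which
    together stand for the total unrepresented weight; unused candidates are
    culled immediately.
    """
    if data.n_snvs == 0:
        return tree
    for i in range(data.n_snvs):
        # pool unoccupied mass so fresh candidates draw from what is free;
        # done before unassigning SNV i so that a singleton's own node keeps
        # its weights and stays a live candidate (as the kept auxiliary)
        tree.restore_empty_mass()
        current = tree.assignments.get(i)
        if current is not None:
            current.snvs.discard(i)
        nodes, omega, residual = tree.mass_partition()
        resid_total = float(residual.sum())
        aux: list[TreeNode] = []
        if resid_total > 1e-12:
            for _ in range(n_aux):
                start_idx = rng.choice(len(nodes), p=residual / resid_total)
                aux.append(tree.sample_open_region(nodes[start_idx], rng))
        cands = nodes + aux
        log_prior = np.concatenate(
            [
                np.log(np.maximum(omega, 1e-300)),
                np.full(len(aux), np.log(max(resid_total, 1e-300) / max(len(aux), 1))),
            ]
        )
        phis = np.stack([n.phi for n in cands])
        logp = log_prior + data.log_likelihood_snv_multi(i, phis)
        logp -= logp.max()
        p = np.exp(logp)
        choice = int(rng.choice(len(cands), p=p / p.sum()))
        chosen = cands[choice]
        chosen.snvs.add(i)
        tree.assignments[i] = chosen
        cull_tree(tree)
    return tree


def gibbs_sticks_and_hypers(
    tree: CloneTree,
    rng: np.random.Generator,
    n_hyper_steps: int = 5,
) -> CloneTree:
    """Resample all sticks from their Beta conditionals, then take Metropolis
    steps on (alpha0, gamma, lambda) under a uniform prior over the
    configured settings grid."""
    _resample_sticks(tree, rng)
    _resample_hypers(tree, rng, n_hyper_steps)
    return tree


def _subtree_counts(node: TreeNode, out: dict) -> int:
    total = len(node.snvs)
    for child in node.children:
        total += _subtree_counts(child, out)
    out[id(node)] = total
    return total


def _resample_sticks(tree: CloneTree, rng: np.random.Generator) -> None:
    counts: dict[int, int] = {}
    _subtree_counts(tree.root, counts)
    for node in tree.nodes():
        n_here = len(node.snvs)
        n_desc = counts[id(node)] - n_here
        node.nu = float(rng.beta(1.0 + n_here, tree.alpha(node.depth) + n_desc))
        child_tot = [counts[id(c)] for c in node.children]
        for k in range(len(node.children)):
            below = sum(child_tot[k + 1 :])
            node.psi[k] = float(rng.beta(1.0 + child_tot[k], tree.gamma + below))


def _stick_log_likelihood(tree: CloneTree, alpha0: float, gamma: float, lam: float) -> float:
    """Log density of all instantiated sticks under Beta(1, alpha(depth)) and
    Beta(1, gamma)."""
    ll = 0.0
    for node in tree.nodes():
        a = (lam**node.depth) * alpha0
        ll += math.log(a) + (a - 1.0) * math.log(max(1.0 - node.nu, 1e-300))
        for psi in node.psi:
            ll += math.log(gamma) + (gamma - 1.0) * math.log(max(1.0 - psi, 1e-300))
    return ll


def _resample_hypers(tree: CloneTree, rng: np.random.Generator, n_steps: int) -> None:
    grid = tree.hyperparam_ranges
    for _ in range(n_steps):
        for name in ("alpha0", "gamma", "lam"):
            values = grid[name]
            prop = float(values[rng.integers(len(values))])
            trial = {
                "alpha0": tree.alpha0,
                "gamma": tree.gamma,
                "lam": tree.lam,
            }
            trial[name] = prop
            # independence proposal, uniform prior on the grid: the
            # acceptance ratio is the stick-density ratio
            delta = _stick_log_likelihood(
                tree, trial["alpha0"], trial["gamma"], trial["lam"]
            ) - _stick_log_likelihood(tree, tree.alpha0, tree.gamma, tree.lam)
            if math.log(rng.uniform()) < delta:
                setattr(tree, name, float(prop))


def _beta1_logpdf(x: float, b: float) -> float:
    return math.log(b) + (b - 1.0) * math.log(max(1.0 - x, 1e-300))


def _structure_log_score(tree: CloneTree) -> float:
    """Log score of the parts of the posterior that a phi-preserving
    reattachment changes: assignment prior sum(log omega_{z_i}), stick
    priors, and the auxiliary-weight prior."""
    from .freqs import _log_eta_prior_sample  # local import: avoid cycle

    nodes, omega, _ = tree.mass_partition()
    pos = {id(n): k for k, n in enumerate(nodes)}
    score = sum(
        math.log(max(omega[pos[id(node)]], 1e-300))
        for node in tree.assignments.values()
    )
    score += _stick_log_likelihood(tree, tree.alpha0, tree.gamma, tree.lam)
    children_idx = [[pos[id(c)] for c in n.children] for n in nodes]
    eta = np.stack([n.eta for n in nodes])
    for t in range(tree.n_samples):
        score += _log_eta_prior_sample(children_idx, eta[:, t])
    return score


def reattach_moves(
    tree: CloneTree, rng: np.random.Generator, n_attempts: int | None = None
) -> int:
    """Metropolis moves that prune a subtree and reattach it elsewhere while
    leaving every node's phi unchanged.

    The pruned subtree's total mass phi_v is credited to the old parent's
    auxiliary weight and debited from the new parent's, so all population
    frequencies — and hence the read-count likelihood — are untouched; the
    acceptance ratio involves only the assignment prior (node weights omega),
    the stick priors, and the auxiliary-weight prior.  This is what lets the
    chain hop between chain-like and branching explanations when the read
    depth pins the frequencies too sharply for a relocated node ever to
    redraw a fitting phi.  Returns the number of accepted moves.
    """
    tree.update_phis()
    accepted = 0
    if n_attempts is None:
        n_attempts = max(5, len(tree.occupied_nodes()))
    for _ in range(n_attempts):
        nodes = tree.nodes()
        movable = [
            n for n in nodes if n.parent is not None and _subtree_has_data(n)
        ]
        if not movable:
            return accepted
        n_movable_fwd = len(movable)
        v = movable[rng.integers(len(movable))]
        in_subtree = set()
        stack = [v]
        while stack:
            n = stack.pop()
            in_subtree.add(id(n))
            stack.extend(n.children)
        candidates = [n for n in nodes if id(n) not in in_subtree]
        p = candidates[rng.integers(len(candidates))]
        old_p = v.parent
        if p is not old_p and np.any(p.eta < v.phi):
            continue  # new parent cannot cover the subtree's mass
        score_before = _structure_log_score(tree)
        k = old_p.children.index(v)
        psi_old = old_p.psi[k]
        # detach, crediting the subtree mass to the old parent
        del old_p.children[k]
        del old_p.psi[k]
        old_p.eta = old_p.eta + v.phi
        slots_rev = len(old_p.children) + 1
        slots_fwd = len(p.children) + 1
        j = int(rng.integers(slots_fwd))
        psi_new = float(rng.beta(1.0, tree.gamma))
        p.children.insert(j, v)
        p.psi.insert(j, psi_new)
        v.parent = p
        p.eta = p.eta - v.phi
        tree.update_phis()
        score_after = _structure_log_score(tree)
        # the set of movable nodes can change (the old parent may stop
        # having data below it, the new one may start), so the pick
        # probabilities do not cancel
        n_movable_rev = sum(
            1 for n in tree.nodes() if n.parent is not None and _subtree_has_data(n)
        )
        log_ratio = (
            score_after
            - score_before
            + math.log(slots_fwd)
            - math.log(slots_rev)
            + math.log(n_movable_fwd)
            - math.log(n_movable_rev)
            + _beta1_logpdf(psi_old, tree.gamma)
            - _beta1_logpdf(psi_new, tree.gamma)
        )
        if math.log(rng.uniform()) < log_ratio:
            accepted += 1
        else:  # undo
            del p.children[j]
            del p.psi[j]
            p.eta = p.eta + v.phi
            old_p.children.insert(k, v)
            old_p.psi.insert(k, psi_old)
            v.parent = old_p
            old_p.eta = old_p.eta - v.phi
            tree.update_phis()
    return accepted


def _subtree_has_data(node: TreeNode) -> bool:
    if node.snvs:
        return True
    return any(_subtree_has_data(c) for c in node.children)


def cull_tree(tree: CloneTree) -> CloneTree:
    """Forget trailing unoccupied leaves (recursively), returning their eta
    mass to the parent so that sum(eta) = 1 is preserved.

    Only *trailing* children may be dropped: deleting a middle sibling would
    re-index the later ones and silently multiply their stick weights by
    1/(1 - psi_k), pushing the deleted region's mass onto occupied nodes
    instead of back into the open residual.  A trailing empty leaf's sticks
    are conditioned on by nothing, so forgetting them just returns the
    region to the uninstantiated part of the measure.  Empty middle siblings
    linger until the children after them are gone.  The root is never
    removed.
    """

    def _cull(node: TreeNode) -> None:
        for child in list(node.children):
            _cull(child)
        while node.children:
            child = node.children[-1]
            if child.snvs or child.children:
                break
            node.eta += child.eta
            node.children.pop()
            node.psi.pop()

    _cull(tree.root)
    tree.update_phis()
    return tree
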
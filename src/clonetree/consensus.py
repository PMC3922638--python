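"""Posterior summaries: co-clustering, correlation clustering, partial order.

The MCMC trace is a bag of trees.  Three SNV-level summaries condense it:

* a co-clustering matrix C, where C_ij is the number of posterior samples
  placing SNVs i and j in the same node minus the number separating them;
* a hard consensus clustering of C by correlation clustering (maximize the
  within-cluster sum of C over all partitions) — a coloring aid only, it
  does not represent the posterior uncertainty;
* the partial order: a weighted digraph whose edge P -> Q carries the
  fraction of posterior samples in which P's node is the direct parent of
  Q's node.  Rendered as Graphviz DOT with thin/thick edges by weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .mcmc import McmcTrace

__all__ = [
    "CoclusterMatrix",
    "PartialOrder",
    "coclustering_matrix",
    "correlation_cluster",
    "edge_frequencies",
    "genotype_posterior",
    "write_dot",
]


@dataclass(frozen=True)
class CoclusterMatrix:
    """Symmetric co-clustering tally over posterior samples."""

    C: np.ndarray
    snv_ids: tuple[str, ...]
    n_samples: int  # number of posterior samples tallied

    def __post_init__(self) -> None:
        if self.C.shape != (len(self.snv_ids), len(self.snv_ids)):
            raise ValueError("C must be N x N")


@dataclass
class PartialOrder:
    """SNV-level parent-edge graph with consensus cluster labels."""

    snv_ids: list[str]
    edges: list[tuple[str, str, float]]  # (parent SNV, child SNV, weight)
    cluster_labels: dict[str, int]


def coclustering_matrix(trace: McmcTrace) -> CoclusterMatrix:
    """C_ij = (#samples with i, j co-clustered) - (#samples with them apart)."""
    if not trace.snapshots:
        raise ValueError("empty trace")
    n = len(trace.snv_ids)
    c = np.zeros((n, n), dtype=int)
    for snap in trace.snapshots:
        same = snap.z[:, None] == snap.z[None, :]
        c += np.where(same, 1, -1)
    return CoclusterMatrix(c, tuple(trace.snv_ids), len(trace.snapshots))


def _partition_objective(c: np.ndarray, labels: np.ndarray) -> int:
    iu = np.triu_indices(c.shape[0], k=1)
    same = (labels[:, None] == labels[None, :])[iu]
    return int(c[iu][same].sum())


def correlation_cluster(
    cocluster: CoclusterMatrix | np.ndarray,
    n_restarts: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Cluster labels maximizing sum_{i<j} C_ij over co-assigned pairs.

    Correlation clustering is NP-hard; this uses greedy agglomeration
    followed by single-move local search, with random restarts.  Labels are
    canonicalized by first appearance; ties in the search break toward the
    lowest SNV index.
    """
    c = cocluster.C if isinstance(cocluster, CoclusterMatrix) else np.asarray(cocluster)
    n = c.shape[0]
    rng = np.random.default_rng(seed)
    best_labels, best_obj = np.arange(n), _partition_objective(c, np.arange(n))
    for restart in range(n_restarts):
        if restart == 0:
            labels = _greedy_agglomerate(c)
        else:
            labels = rng.integers(0, max(2, n // 2), size=n)
        labels = _local_search(c, labels)
        obj = _partition_objective(c, labels)
        if obj > best_obj:
            best_labels, best_obj = labels, obj
    return _canonicalize(best_labels)


def _greedy_agglomerate(c: np.ndarray) -> np.ndarray:
    n = c.shape[0]
    labels = np.arange(n)
    improved = True
    while improved:
        improved = False
        groups = [np.nonzero(labels == g)[0] for g in np.unique(labels)]
        best_gain, best_pair = 0, None
        for (ia, a), (ib, b) in combinations(enumerate(groups), 2):
            gain = int(c[np.ix_(a, b)].sum())
            if gain > best_gain:
                best_gain, best_pair = gain, (ia, ib)
        if best_pair is not None:
            ia, ib = best_pair
            labels[np.isin(labels, labels[groups[ib]])] = labels[groups[ia][0]]
            improved = True
    return labels


def _local_search(c: np.ndarray, labels: np.ndarray) -> np.ndarray:
    n = c.shape[0]
    labels = labels.copy()
    improved = True
    while improved:
        improved = False
        for i in range(n):
            current = labels[i]
            cands = list(np.unique(labels)) + [labels.max() + 1]  # incl. singleton
            gains = []
            for g in cands:
                members = (labels == g) & (np.arange(n) != i)
                gains.append(int(c[i, members].sum()))
            own = (labels == current) & (np.arange(n) != i)
            cur_gain = int(c[i, own].sum())
            best = int(np.argmax(gains))
            if gains[best] > cur_gain:
                labels[i] = cands[best]
                improved = True
    return labels


def _canonicalize(labels: np.ndarray) -> np.ndarray:
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, g in enumerate(labels):
        if g not in mapping:
            mapping[g] = len(mapping)
        out[i] = mapping[g]
    return out


def edge_frequencies(trace: McmcTrace) -> PartialOrder:
    """Fraction of posterior samples in which P's node directly parents Q's.

    SNVs sharing a node contribute no edge between each other.
    """
    if not trace.snapshots:
        raise ValueError("empty trace")
    n = len(trace.snv_ids)
    counts = np.zeros((n, n))
    for snap in trace.snapshots:
        parent_of_node = snap.parents
        z = snap.z
        parent_node_of_snv = parent_of_node[z]  # [N]
        counts += z[:, None] == parent_node_of_snv[None, :]
    weights = counts / len(trace.snapshots)
    cc = correlation_cluster(coclustering_matrix(trace))
    labels = {sid: int(cc[i]) for i, sid in enumerate(trace.snv_ids)}
    edges = [
        (trace.snv_ids[i], trace.snv_ids[j], float(weights[i, j]))
        for i in range(n)
        for j in range(n)
        if i != j and weights[i, j] > 0
    ]
    return PartialOrder(list(trace.snv_ids), edges, labels)


def genotype_posterior(trace: McmcTrace, genotype: frozenset | set) -> float:
    """Posterior probability that some lineage's cumulative genotype equals
    the given SNV set (fraction of samples containing such a node)."""
    if not trace.snapshots:
        raise ValueError("empty trace")
    query = frozenset(genotype)
    hits = sum(
        query in set(snap.node_genotypes(trace.snv_ids)) for snap in trace.snapshots
    )
    return hits / len(trace.snapshots)


def canonical_structure(snap, snv_ids: list[str]) -> tuple:
    """Canonical key of a snapshot's occupied-node tree.

    Unoccupied nodes are contracted away; each occupied node is labelled by
    its SNV set and linked to its nearest occupied ancestor (None at the
    top).  Two snapshots with the same key describe the same clustering and
    the same lineage tree over the clusters.
    """
    own: dict[int, set[str]] = {}
    for i, k in enumerate(snap.z):
        own.setdefault(int(k), set()).add(snv_ids[i])

    def occupied_ancestor(k: int) -> frozenset | None:
        p = snap.parents[k]
        while p != -1:
            if own.get(int(p)):
                return frozenset(own[int(p)])
            p = snap.parents[p]
        return None

    return tuple(
        sorted(
            (tuple(sorted(snvs)), tuple(sorted(occupied_ancestor(k) or ())) or None)
            for k, snvs in own.items()
        )
    )


def modal_structure(trace: McmcTrace) -> tuple[tuple, float]:
    """Most frequent occupied-tree structure and its posterior frequency."""
    from collections import Counter

    keys = Counter(canonical_structure(s, trace.snv_ids) for s in trace.snapshots)
    key, n = keys.most_common(1)[0]
    return key, n / len(trace.snapshots)


_PALETTE = [
    "black", "red", "blue", "forestgreen", "darkorange",
    "purple", "brown", "deeppink", "teal", "goldenrod",
]


def write_dot(po: PartialOrder, edge_threshold: float = 0.1) -> str:
    """Serialize a partial order as deterministic Graphviz DOT.

    Edges below `edge_threshold` are dropped; pen width scales with weight;
    node border color encodes the consensus cluster.
    """
    lines = ["digraph partial_order {", "  rankdir=TB;"]
    for sid in sorted(po.snv_ids):
        color = _PALETTE[po.cluster_labels.get(sid, 0) % len(_PALETTE)]
        lines.append(f'  "{sid}" [color="{color}"];')
    for parent, child, w in sorted(po.edges):
        if w < edge_threshold:
            continue
        lines.append(
            f'  "{parent}" -> "{child}" [penwidth={1 + 4 * w:.2f}, label="{w:.2f}"];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"
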
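"""Topological constraint rules on SNV population frequencies.

Under the infinite sites assumption an ancestral SNV's population frequency
can never fall below a descendant's, and in a branching phylogeny sibling
subclones share no cells, so a parent's frequency must cover the *sum* of
its children's.  Two decision rules follow for a triplet (A, B, C) with A
known ancestral to B and C:

* sum rule — if f_B + f_C > f_A in any sample, B and C cannot be siblings:
  the phylogeny must be linear (a chain);
* crossing rule — if B and C swap frequency order between two samples,
  neither can be ancestral to the other: the phylogeny must branch.

A can be a mock wildtype "SNV" with frequency 1.0 in every sample, which also
covers multicentral tumors.  `enumerate_consistent_trees` is the brute-force
counterpart: it lists every rooted tree over the given SNVs whose
parent-covers-children inequality holds in every sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Literal, Sequence

import numpy as np

__all__ = ["TripletVerdict", "classify_triplet", "enumerate_consistent_trees"]

Verdict = Literal["chain_only", "branching_only", "ambiguous", "inconsistent"]


@dataclass(frozen=True)
class TripletVerdict:
    verdict: Verdict
    witness: str


def _as_matrix(freqs: Sequence) -> np.ndarray:
    arr = np.atleast_2d(np.asarray(freqs, dtype=float))
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("frequencies must lie in [0,1]")
    return arr


def classify_triplet(freqs: Sequence, tol: float = 0.0) -> TripletVerdict:
    """Classify the phylogeny of a triplet (f_A, f_B, f_C) per sample.

    `freqs` is one (f_A, f_B, f_C) triple or a list of per-sample triples,
    with A asserted ancestral to B and C (use f_A = 1.0 for a mock wildtype
    ancestor).  `tol` absorbs estimation error in the frequencies.
    """
    arr = _as_matrix(freqs)
    if arr.shape[1] != 3:
        raise ValueError("each sample needs exactly (f_A, f_B, f_C)")
    f_a, f_b, f_c = arr[:, 0], arr[:, 1], arr[:, 2]
    bad = np.maximum(f_b, f_c) > f_a + tol
    if np.any(bad):
        t = int(np.argmax(bad))
        return TripletVerdict("inconsistent", f"ancestry violated in sample {t}")

    sum_hits = np.nonzero(f_b + f_c > f_a + tol)[0]
    b_over_c = np.nonzero(f_b > f_c + tol)[0]
    c_over_b = np.nonzero(f_c > f_b + tol)[0]
    crossing = len(b_over_c) > 0 and len(c_over_b) > 0

    if len(sum_hits) > 0 and crossing:
        return TripletVerdict(
            "inconsistent",
            f"sum rule in sample {sum_hits[0]} and crossing between samples "
            f"{b_over_c[0]} and {c_over_b[0]}",
        )
    if len(sum_hits) > 0:
        return TripletVerdict("chain_only", f"sum rule fired in sample {sum_hits[0]}")
    if crossing:
        return TripletVerdict(
            "branching_only",
            f"crossing rule fired between samples {b_over_c[0]} and {c_over_b[0]}",
        )
    return TripletVerdict("ambiguous", "neither rule fired")


def enumerate_consistent_trees(
    freqs: Sequence,
    tol: float = 0.0,
    root: int | None = None,
    mock_root: bool = False,
) -> list[tuple[int, ...]]:
    """All rooted labeled trees over k SNVs satisfying, in every sample,
    phi_parent >= sum of children's phi (within tol).

    Returns parent vectors: `parents[i]` is the parent of SNV i, -1 for the
    root.  With `mock_root=True` an implicit wildtype node with frequency 1.0
    is added above everything and SNVs may attach directly under it (parent
    -1), covering multicentral forests; `root` forces a specific SNV to be the
    single root.  Exhaustive, so k is capped at 8.
    """
    arr = _as_matrix(freqs)  # [S, k]
    k = arr.shape[1]
    if k > 8:
        raise ValueError("exhaustive enumeration supports at most 8 SNVs")
    if k == 1:
        return [(-1,)]

    out: list[tuple[int, ...]] = []
    choices: list[list[int]] = []
    for i in range(k):
        opts = [j for j in range(k) if j != i]
        if mock_root:
            opts.append(-1)
        elif root is None:
            opts.append(-1)
        elif i == root:
            opts = [-1]
        choices.append(opts)

    for parents in product(*choices):
        roots = [i for i in range(k) if parents[i] == -1]
        if mock_root:
            if not roots:
                continue
        else:
            if len(roots) != 1:
                continue
        # acyclicity: walking up from every node must terminate
        ok = True
        for start in range(k):
            seen, node = set(), start
            while node != -1:
                if node in seen:
                    ok = False
                    break
                seen.add(node)
                node = parents[node]
            if not ok:
                break
        if not ok:
            continue
        if _respects_frequencies(parents, arr, tol, mock_root):
            out.append(tuple(parents))
    return out


def _respects_frequencies(
    parents: tuple[int, ...], arr: np.ndarray, tol: float, mock_root: bool
) -> bool:
    k = arr.shape[1]
    child_sum = np.zeros((arr.shape[0], k + 1))  # last column: under the root
    for i, p in enumerate(parents):
        child_sum[:, p if p != -1 else k] += arr[:, i]
    for i in range(k):
        if np.any(child_sum[:, i] > arr[:, i] + tol):
            return False
    if mock_root and np.any(child_sum[:, k] > 1.0 + tol):
        return False
    return True
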
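"""Synthetic read-count generator for validating the tree inference.

Scenarios place clusters of heterozygous, normal-copy-number SNVs at chosen
population frequencies (optionally arranged on a tree, per sample) and draw
read counts binomially: depth d ~ Poisson(mean depth), variant reads
b ~ Binomial(d, 1 - [(1 - phi) * mu_r + phi * 0.5]).  The presets mirror the
standard validation designs for targeted deep sequencing of tumor panels:

* ``flat6`` — six frequency clusters {1.0, 0.85, 0.6, 0.35, 0.2, 0.08},
  nine SNVs each, one sample, mean depth 10,000 (no tree imposed: the
  frequencies are deliberately consistent with many phylogenies);
* ``chain5`` — a five-node chain 0.9 -> 0.75 -> 0.55 -> 0.4 -> 0.25 whose
  frequencies, by the sum rule, admit only the chain;
* ``crossing2`` — two samples of a branching clone pair whose frequencies
  cross between samples, so only the branching phylogeny fits both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    DEFAULT_ERROR_RATE,
    SampleSet,
    SnvObservation,
    default_genotype_config,
)

__all__ = ["SimScenario", "simulate_reads", "preset_scenarios"]


class ScenarioError(ValueError):
    """Scenario frequencies violate the clonal ordering constraint."""


@dataclass(frozen=True)
class SimScenario:
    """A simulation design.

    `node_phis[k][t]` is cluster k's population frequency in sample t.
    `tree_parents[k]` is the parent cluster of k (-1 = child of the implicit
    wildtype root); None means a flat design with no tree constraint checked.
    """

    name: str
    node_phis: tuple[tuple[float, ...], ...]
    snvs_per_node: tuple[int, ...]
    depth: float
    tree_parents: tuple[int, ...] | None = None
    error_rate: float = DEFAULT_ERROR_RATE
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.node_phis)
        if len(self.snvs_per_node) != k:
            raise ScenarioError("snvs_per_node length must match node_phis")
        n_samples = len(self.node_phis[0])
        if any(len(p) != n_samples for p in self.node_phis):
            raise ScenarioError("ragged per-sample frequencies")
        phis = np.asarray(self.node_phis)
        if np.any(phis < 0) or np.any(phis > 1):
            raise ScenarioError("frequencies must lie in [0,1]")
        if self.tree_parents is not None:
            if len(self.tree_parents) != k:
                raise ScenarioError("tree_parents length must match node_phis")
            child_sum = np.zeros((k + 1, n_samples))
            for i, p in enumerate(self.tree_parents):
                child_sum[p if p != -1 else k] += phis[i]
            for i in range(k):
                if np.any(child_sum[i] > phis[i] + 1e-9):
                    raise ScenarioError(
                        f"cluster {i}: children's frequencies exceed the parent's"
                    )
            if np.any(child_sum[k] > 1.0 + 1e-9):
                raise ScenarioError("top-level frequencies exceed 1")

    @property
    def n_samples(self) -> int:
        return len(self.node_phis[0])


def simulate_reads(scenario: SimScenario) -> tuple[SampleSet, pd.DataFrame]:
    """Draw read counts for a scenario; returns the dataset and the truth.

    The truth table has one row per SNV with its cluster index and true
    frequency in each sample, for recovery scoring.
    """
    rng = np.random.default_rng(scenario.seed)
    genotype = default_genotype_config(2, "heterozygous", scenario.error_rate)
    mu_r = genotype.ref_allele_prob_ref_pop
    snvs: list[SnvObservation] = []
    rows: list[dict] = []
    for k, (phis, count) in enumerate(zip(scenario.node_phis, scenario.snvs_per_node)):
        for j in range(count):
            sid = f"s{k}_{j}"
            b_list, d_list = [], []
            for phi in phis:
                d = max(int(rng.poisson(scenario.depth)), 1)
                p_ref = (1.0 - phi) * mu_r + phi * 0.5
                b = int(rng.binomial(d, 1.0 - p_ref))
                b_list.append(b)
                d_list.append(d)
            snvs.append(
                SnvObservation(sid, tuple(b_list), tuple(d_list), genotype)
            )
            rows.append(
                {
                    "snv_id": sid,
                    "cluster": k,
                    **{f"phi_{t}": phis[t] for t in range(len(phis))},
                }
            )
    labels = [f"sample{t}" for t in range(scenario.n_samples)]
    return SampleSet(snvs, labels), pd.DataFrame(rows).set_index("snv_id")


def preset_scenarios(
    depth: float | None = None, seed: int = 0, poisson_cluster_sizes: bool = False
) -> dict[str, SimScenario]:
    """The named validation designs (see module docstring).

    `depth` overrides the mean read depth of every preset (used for the
    reduced-depth variants of ``flat6`` at 1,000x and 200x).  With
    `poisson_cluster_sizes` the nine SNVs per cluster become draws from
    Poisson(9) truncated at 1, for "an average of nine SNVs per cluster"
    taken literally.
    """

    def _sizes(k: int) -> tuple[int, ...]:
        if not poisson_cluster_sizes:
            return (9,) * k
        rng = np.random.default_rng(seed + 10_007)
        return tuple(max(1, int(x)) for x in rng.poisson(9, size=k))
    flat6 = SimScenario(
        name="flat6",
        node_phis=tuple((f,) for f in (1.0, 0.85, 0.6, 0.35, 0.2, 0.08)),
        snvs_per_node=_sizes(6),
        depth=depth if depth is not None else 10000.0,
        tree_parents=None,
        seed=seed,
    )
    chain5 = SimScenario(
        name="chain5",
        node_phis=tuple((f,) for f in (0.9, 0.75, 0.55, 0.4, 0.25)),
        snvs_per_node=_sizes(5),
        depth=depth if depth is not None else 10000.0,
        tree_parents=(-1, 0, 1, 2, 3),
        seed=seed,
    )
    crossing2 = SimScenario(
        name="crossing2",
        node_phis=((0.8, 0.8), (0.4, 0.2), (0.2, 0.4)),
        snvs_per_node=_sizes(3),
        depth=depth if depth is not None else 10000.0,
        tree_parents=(-1, 0, 0),
        seed=seed,
    )
    return {"flat6": flat6, "chain5": chain5, "crossing2": crossing2}
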
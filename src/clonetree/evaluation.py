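"""Recovery experiments on the preset scenarios and the AML worked examples.

These are the validation computations the package runs end-to-end: simulate
(or load) the inputs, run the sampler, and score the result against the
known truth.  Problem sizes default to desk scale: around 2,000 Gibbs
sweeps with 100 inner Metropolis-Hastings iterations per sweep, which the
mixing diagnostics show is comfortably past burn-in for these panel sizes.
"""

from __future__ import annotations

import numpy as np

from .consensus import canonical_structure, genotype_posterior, modal_structure
from .datasets import aml_su048
from .mcmc import McmcConfig, McmcTrace, run_mcmc
from .simulate import preset_scenarios, simulate_reads

__all__ = [
    "flat6_recovery",
    "chain5_modal_is_chain",
    "crossing2_modal_is_branching",
    "su048_genotype_posteriors",
]


def flat6_recovery(
    depth: float | None,
    seed: int,
    n_iters: int = 2000,
    mh_iters: int = 100,
    fixed_hypers: tuple[float, float, float] | None = None,
    data_seed: int = 1,
) -> float:
    """Pearson correlation between posterior-mean per-SNV frequencies and the
    simulated truth for the six-cluster scenario at the given mean depth."""
    scenario = preset_scenarios(depth=depth, seed=data_seed)["flat6"]
    data, truth = simulate_reads(scenario)
    config = McmcConfig(
        n_iters=n_iters, burn_in=100, mh_iters=mh_iters, seed=seed,
        fixed_hypers=fixed_hypers,
    )
    trace = run_mcmc(data, config)
    est = trace.posterior_mean_phi()[:, 0]
    return float(np.corrcoef(est, truth["phi_0"].to_numpy())[0, 1])


def _expected_chain_key(n_clusters: int, snvs_per_node: int = 9) -> tuple:
    return tuple(
        sorted(
            (
                tuple(sorted(f"s{k}_{j}" for j in range(snvs_per_node))),
                tuple(sorted(f"s{k - 1}_{j}" for j in range(snvs_per_node)))
                if k > 0
                else None,
            )
            for k in range(n_clusters)
        )
    )


def chain5_modal_is_chain(
    seed: int, n_iters: int = 300, mh_iters: int = 100, data_seed: int = 1
) -> tuple[bool, float]:
    """Whether the modal posterior tree on the five-step chain scenario is the
    true 5-node chain, and its posterior frequency."""
    scenario = preset_scenarios(seed=data_seed)["chain5"]
    data, _ = simulate_reads(scenario)
    config = McmcConfig(n_iters=n_iters, burn_in=100, mh_iters=mh_iters, seed=seed)
    trace = run_mcmc(data, config)
    key, freq = modal_structure(trace)
    return key == _expected_chain_key(5), freq


def crossing2_modal_is_branching(
    seed: int, n_iters: int = 300, mh_iters: int = 100, data_seed: int = 1
) -> tuple[bool, float]:
    """Whether the modal tree on the two-sample crossing scenario is the true
    branching structure (both low clusters children of the high one)."""
    scenario = preset_scenarios(seed=data_seed)["crossing2"]
    data, _ = simulate_reads(scenario)
    config = McmcConfig(n_iters=n_iters, burn_in=100, mh_iters=mh_iters, seed=seed)
    trace = run_mcmc(data, config)
    key, freq = modal_structure(trace)
    top = tuple(sorted(f"s0_{j}" for j in range(9)))
    expected = tuple(
        sorted(
            [(top, None)]
            + [
                (tuple(sorted(f"s{k}_{j}" for j in range(9))), top)
                for k in (1, 2)
            ]
        )
    )
    return key == expected, freq


def su048_genotype_posteriors(
    seed: int, n_iters: int = 5000, mh_iters: int = 100
) -> tuple[float, float, McmcTrace]:
    """Posterior probabilities of the two benchmark lineage genotypes on the
    six-SNV SU048 panel: exactly {TET2-E1357stop}, and the five SNVs
    excluding ZMYM3."""
    data = aml_su048()
    config = McmcConfig(n_iters=n_iters, burn_in=100, mh_iters=mh_iters, seed=seed)
    trace = run_mcmc(data, config)
    p_tet2 = genotype_posterior(trace, {"TET2-E1357stop"})
    p_rest = genotype_posterior(trace, set(data.snv_ids) - {"ZMYM3"})
    return p_tet2, p_rest, trace
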
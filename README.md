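# clonetree

Bayesian nonparametric inference of tumor subclonal lineage trees from
deep-sequencing allele counts of somatic SNVs.

A bulk tumor sample mixes cells from several subclonal lineages. Targeted
deep sequencing measures, for each somatic single-nucleotide variant (SNV),
a variant read count *b* out of a total depth *d*, and the allele frequency
*b/d* reflects the fraction of cells carrying the variant — its *population
frequency* φ (≈ 2·*b/d* for a heterozygous diploid variant). Under the
infinite sites assumption (each SNV arises once and never reverts), the φ
values constrain the phylogeny of the subclones: an ancestor's frequency
must cover each descendant's, and in a branching clade the parent must cover
the *sum* of its children. `clonetree` infers, from the read counts alone,

- how the SNVs group into subclonal lineages,
- the rooted tree of those lineages and each lineage's cumulative genotype,
- the population frequency of every lineage in every sample,
- and the posterior uncertainty of all of the above.

## Model

Read counts follow a binomial observation model with genotype
marginalization: with reference-allele sampling probabilities μʳ (reference
population) and μᵛ:ᵍ (variant population with genotype *g*, e.g. 0.5 for
AB), and Dirichlet pseudo-counts δ over candidate genotypes,

    a | d, φ, g  ~  Binomial(d, (1−φ)·μʳ + φ·μᵛ:ᵍ),
    p(a | d, φ)  =  Σ_g  δ_g/Σδ · Binomial(a; d, ·)

The prior over trees is a tree-structured stick-breaking (TSSB) process:
depth sticks ν ~ Beta(1, λ^depth·α₀) and branch sticks ψ ~ Beta(1, γ) carve
the unit mass into node weights ω over an unbounded rooted tree, letting
data sit at internal nodes and letting the data choose the number of
lineages. Frequencies are parameterized by auxiliary weights η ≥ 0 with
Σ η = 1 per sample and φ_v = η_v + Σ_{descendants} η_w, so
φ_parent ≥ Σ φ_children holds by construction. Inference is MCMC: collapsed
Gibbs for SNV–node assignments, Beta conditionals for sticks, a uniform
prior over a settings grid for (α₀, γ, λ), Metropolis–Hastings with an
asymmetric Dirichlet proposal for η, plus frequency-preserving subtree
reattachment and genotype-informed frequency-jump moves for structure
mixing at deep coverage.

## Worked example

Infer the clone tree of the published six-SNV AML sample SU048 from its
printed allele counts:

```python
import numpy as np
from clonetree import aml_su048, McmcConfig, run_mcmc, best_tree, genotype_posterior

data = aml_su048()                      # 6 SNVs, one sample
trace = run_mcmc(data, McmcConfig(n_iters=2000, burn_in=100,
                                  mh_iters=100, seed=0))
best = best_tree(trace)
for k, genotype in enumerate(best.node_genotypes(data.snv_ids)):
    if genotype:
        print(sorted(genotype), "phi=%.2f" % best.phi[k, 0])
print("P(lineage genotype exactly {TET2-E1357stop}) =",
      genotype_posterior(trace, {"TET2-E1357stop"}))
```

prints (seed 0):

```
['TET2-E1357stop'] phi=0.76
['OLFM2'] phi=0.22
['SMC1A', 'TET2-E1357stop'] phi=0.55
['TET2-D1384V', 'TET2-E1357stop'] phi=0.21
['SMC1A', 'TET2-E1357stop', 'ZMYM3'] phi=0.12
['ACSM1', 'SMC1A', 'TET2-E1357stop'] phi=0.27
P(lineage genotype exactly {TET2-E1357stop}) = 1.0
```

i.e. the highest-likelihood tree puts TET2-E1357stop in the founding
lineage at φ ≈ 0.76 (allele frequency 0.38, so about three quarters of the
cells) with most other SNVs as nested secondary events branching below it,
and every posterior sample contains a founder lineage whose genotype is
exactly that single SNV. The frequencies of the remaining five SNVs admit
many chain and branching arrangements, which is visible in the
partial-order plot rather than in any single best tree.

The same pipeline is available from the shell:

```bash
clonetree simulate --preset chain5 --seed 1 --out chain5.tsv
clonetree infer --input chain5.tsv --iters 2000 --burnin 100 \
                --mh-iters 100 --seed 0 --outdir run/
clonetree consensus --trace run/trace.json --edge-threshold 0.1
clonetree triplet --freqs 0.8,0.6,0.4          # -> chain_only
```

`infer` writes the best tree (JSON), the SNV-level partial-order plot
(Graphviz DOT, edge weight = posterior probability that one SNV's lineage
directly parents another's), the co-clustering matrix, the likelihood
trace, and the full posterior trace.

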
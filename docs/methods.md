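# Methods

## Model

Each somatic SNV *i* in sample *t* is observed as a variant read count
b_i^t out of depth d_i^t (reference count a = d − b). Cells carrying the
variant form the variant population with unknown genotype g drawn from a
categorical with Dirichlet(δ_i) prior; integrating the categorical
probabilities analytically (a Dirichlet compound multinomial with one draw)
leaves a finite mixture over genotype states with weights δ_g/Σδ. Given the
SNV's population frequency φ, a read shows the reference allele with
probability (1−φ)μʳ + φμᵛ:ᵍ, so the marginal likelihood is a mixture of
binomials. We evaluate it in terms of variant counts b with success
probability 1 − p_ref (the identical binomial; the published tables print
variant counts, so this removes a conversion bug class). Success
probabilities are clamped to (1e−10, 1−1e−10) so log-likelihoods stay
finite when μᵛ:ᵍ is exactly 0 or 1.

Genotype configurations are built from copy number and zygosity:
heterozygous diploid gives the single state AB (μᵛ = 0.5), hemizygous gives
B (μᵛ = error rate), and unknown zygosity enumerates k = 1..copy-number
variant copies with allele ratio k/cn clamped away from {0, 1} by the error
rate, with uniform δ = 1. The sequencer error rate defaults to 1e−3
(μʳ = 0.999); it is an instrument property the data do not identify
separately, so it is a configurable constant rather than a parameter.

## Tree prior

Lineage trees follow the tree-structured stick-breaking (TSSB) process: a
depth stick ν_ε ~ Beta(1, α(|ε|)) at each node and branch sticks
ψ ~ Beta(1, γ) over its children define node weights that sum to one over
the unbounded tree, with α(j) = λʲ·α₀. α₀ and λ control the number and
depth of occupied nodes, γ the branching width. The hyperparameters carry a
uniform prior over the discrete settings grid α₀ ∈ {1, 2, 4, 10, 20, 50},
γ ∈ {1, 2, 4, 6, 8}, λ ∈ {0.25, 0.5, 1} and are sampled by
independence-proposal Metropolis within the MCMC. The grid is log-spaced;
we deliberately use the discrete grid rather than a continuous uniform over
its hull because a continuous Uniform[1, 50] on α₀ concentrates ~80% of its
prior mass above 10, which in our experiments over-fragmented the posterior
clusterings.

## Frequencies under the clonal constraint

Each node carries an auxiliary weight η_v^t ≥ 0 per sample with
Σ_v η_v^t = 1 and φ_v = η_v + Σ_{w descendant} η_w, so
φ_parent ≥ Σ_children φ and φ_root = 1 hold by construction. The generative
prior traverses the tree breadth-first: the root starts with the unit mass
and every child draws Uniform(0, η_parent), decrementing its parent. Its
density is the product of 1/(remaining mass) over the child draws, with the
remaining mass before child j equal to η_v + Σ_{l≥j} φ_{w_l}. The posterior
over η is sampled with Metropolis–Hastings using an asymmetric Dirichlet
proposal Dir(σ·η + 1e−4) with σ = 100 (the pseudo-floor keeps the proposal
proper as weights approach zero; the acceptance ratio accounts for it
exactly). Multi-sample data share the tree; the per-sample η vectors are
proposed jointly and accepted once against the product of per-sample
posteriors, which for one sample reduces exactly to the single-sample
update.

## MCMC

One sweep is: (1) SNV–node assignments, (2) stick conditionals and
hyperparameter Metropolis steps, (3) culling of unoccupied trailing leaves,
(4) subtree-reattachment moves, (5) the Dirichlet MH over η, (6)
frequency-jump moves. Defaults follow the standard protocol for these
panels — 5,000 sweeps, burn-in 100, 5,000 inner MH iterations, σ = 100, no
thinning — with reduced, documented sizes for the validation runs (below).
The complete-data log likelihood recorded per sweep is
Σ_i Σ_t log p(b_i^t | φ_{z_i}^t) + Σ_i log ω_{z_i}; the likelihood-only
part is exposed separately so either convention can be reproduced. The
best tree is the snapshot maximizing it (earliest wins ties).

Design choices worth recording:

- **Assignments** are resampled from the exact conditional
  ∝ ω_ε·Π_t p(b_i^t | φ_ε^t) over all instantiated nodes plus m = 3
  auxiliary candidates drawn from the prior restricted to the residual
  (uninstantiated) stick mass, each standing for residual/m of the
  unrepresented weight — the auxiliary-variable scheme for infinite mixture
  conditionals, adapted to the TSSB's explicit stick state. A retrospective
  slice sampler was implemented first and abandoned: at deep coverage it
  froze tree structures for hundreds of sweeps.
- **Auxiliary mass pooling.** The η of nodes with no data anywhere below
  them is conditioned on by nothing except the ordering scheme, so before
  each assignment update it is returned to the parents and fresh candidate
  nodes redraw from what is actually free. Without this, rejected
  candidates hoard mass and high-frequency lineages can never nucleate.
- **Culling** forgets only *trailing* unoccupied leaves. Deleting a middle
  sibling would re-index the later ones and multiply their stick weights by
  1/(1−ψ_k), silently pushing the deleted region's mass onto occupied nodes;
  we measured this as a ~35% inflation of the two-SNV co-clustering
  probability before fixing it. Empty middle siblings linger harmlessly
  until the children after them are gone.
- **Subtree reattachment.** A Metropolis move prunes a subtree and
  reattaches it elsewhere, crediting its total mass φ_v to the old parent's
  η and debiting the new parent's, so every node's φ — and hence the whole
  likelihood — is untouched; acceptance involves only the assignment prior,
  stick priors, η prior, and the proposal-count corrections. At depths of
  10⁴–10⁵ the likelihood pins frequencies so sharply that a relocated node
  can never redraw a fitting φ; this move is what lets the chain hop
  between chain-like and branching explanations of the same frequencies.
- **Frequency jumps.** With genotype marginalization the per-node frequency
  posterior can be multimodal (heterozygous φ = 2·AF vs homozygous
  φ = AF), with modes separated by likelihood barriers the σ = 100
  Dirichlet walk cannot cross at deep coverage. An independence-style MH
  move exchanges mass between a node's η and its parent's, proposing from
  narrow windows around each genotype-implied frequency plus a broad
  uniform component that keeps the chain irreducible.
- **Initialization** is a frequency-ordered chain of provisional clusters
  (single-linkage on allele-frequency-implied φ, cutting at 2 standard
  errors of separation), with η set from the monotone projection of the
  cluster frequencies. New nodes can only be born as leaves, so an
  ordering-inconsistent start can trap high-frequency SNVs above nodes they
  belong below; the constraint-consistent chain start avoids that, and the
  sampler is free to merge, split, and re-branch from it (the two-sample
  crossing scenario, whose truth is a branching tree, is recovered from
  this chain start with posterior frequency ≈ 1).

### Validation of the kernels

The full Gibbs kernel run on zero-depth data (flat likelihood) must sample
the TSSB prior exactly. We check the occupied-cluster-count distribution
against forward stick-breaking draws (two-sample KS), and the two-SNV
co-clustering probability against the closed form
E[Σ ω²] computed by a depth recursion over the stick moments
(E[ν²] = 2/((1+α)(2+α)), E[Σ GEM(γ)²] = 1/(1+γ)). The η sampler with flat
likelihood is checked per-coordinate against direct draws from the
breadth-first generative scheme, and against 1-D numerical integration of
the posterior for a two-node tree with one SNV.

## Synthetic data

`simulate` draws, for each SNV in a cluster at frequency φ, a depth
d ~ Poisson(mean depth) (the field reports "≈10,000×" without a
distribution; Poisson jitter is the natural minimal choice, with d clamped
to ≥ 1) and variant reads b ~ Binomial(d, 1 − [(1−φ)μʳ + φ·0.5]) —
heterozygous SNVs at normal copy number. The presets are the standard
validation designs: `flat6` (clusters at {1.0, 0.85, 0.6, 0.35, 0.2, 0.08},
9 SNVs each, one sample — deliberately consistent with many phylogenies),
`chain5` (0.9 → 0.75 → 0.55 → 0.4 → 0.25, forced to a chain by the sum
rule), and `crossing2` (two samples with clusters at (0.4, 0.2) and
(0.2, 0.4) under a (0.8, 0.8) parent, forced to branch by the crossing
rule). The generator emulates binomial sampling noise only: real data add
mapping and sequencing biases, copy-number changes, and overdispersion
beyond binomial, so passing these recoveries demonstrates correctness of
the inference machinery, not robustness to platform artifacts.

## Validation runs and problem sizes

The recovery experiments (`clonetree.evaluation`, reported by
`scripts/acceptance.py`) use 1,500–2,000 Gibbs sweeps with 100 inner MH
iterations — sizes at which the likelihood trace and cluster count are flat
well before burn-in ends for these 6–54 SNV panels — rather than the full
5,000/5,000 protocol. The deep-coverage six-cluster recovery is reported as
the minimum Pearson correlation over hyperparameter-grid corners
(1, 1, 1), (50, 8, 1) and (50, 8, 0.25); the reduced-depth variants sample
the hyperparameters.

## Known limitations

- The binomial observation model has no overdispersion; heavily
  overdispersed platforms will overstate confidence in φ.
- Copy number is an input, not inferred; mis-specified genotype
  configurations bias φ directly.
- On the published SU048 panel, the posterior probability of the founding
  lineage genotype {TET2-E1357stop} computes to ≈ 1.0 under heterozygous
  normal-copy-number inputs: at the printed depths, co-clustering that SNV
  with any other costs hundreds of log-likelihood units, and no lineage can
  sit above it. Published summaries of this panel that spread mass across
  alternatives reflect per-SNV genotype configurations from supplementary
  material (and sampler variance) that the printed counts alone do not
  determine.
- Structures whose frequencies are genuinely tied (the `flat6` design) mix
  across many trees; single-run summaries of *structure* should use the
  partial-order plot, not one best tree.
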
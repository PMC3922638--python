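"""Allelic-count observation model with genotype marginalization.

The data for one somatic SNV in one tumor sample are the variant read count
``b`` and total read depth ``d`` at its locus.  Cells carrying the variant
form the *variant population*; all other cells form the *reference
population*.  If a fraction ``phi`` of cells belong to the variant population
and the variant population has genotype ``g``, a sequenced read shows the
reference allele with probability

    p_ref(phi, g) = (1 - phi) * mu_r + phi * mu_v[g]

where ``mu_r`` is the probability of sampling a reference allele from a
reference-population cell (1 minus the sequencer error rate for a normal
diploid locus) and ``mu_v[g]`` the same probability for a variant-population
cell with genotype ``g`` (0.5 for a heterozygous diploid variant).  The
genotype is unknown a priori: it is drawn from a categorical distribution
whose probabilities carry a Dirichlet prior with pseudo-counts ``delta``.
Integrating the categorical probabilities out analytically (a Dirichlet
compound multinomial with a single draw) leaves a finite mixture over
genotype states with weights ``delta_g / sum(delta)``, so the marginal read
count likelihood is a mixture of binomials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "GenotypeState",
    "GenotypeConfig",
    "SnvObservation",
    "SampleSet",
    "mixture_weights",
    "ref_allele_prob",
    "snv_log_likelihood",
    "default_genotype_config",
    "PROB_CLAMP",
]

#: Clamp applied to binomial success probabilities so log-likelihoods stay
#: finite even when mu_v is exactly 0 or 1.
PROB_CLAMP = 1e-10

#: Default sequencer error rate used when building genotype configurations.
DEFAULT_ERROR_RATE = 1e-3


class InvalidPseudoCountError(ValueError):
    """A Dirichlet pseudo-count was non-positive."""


class InvalidObservationError(ValueError):
    """Read counts violate b <= d or are negative."""


@dataclass(frozen=True)
class GenotypeState:
    """One candidate genotype of the variant population."""

    label: str
    ref_allele_prob: float  # mu^{v:g}
    pseudo_count: float = 1.0  # delta_g

    def __post_init__(self) -> None:
        if not 0.0 <= self.ref_allele_prob <= 1.0:
            raise ValueError(f"mu^v for state {self.label!r} outside [0,1]")
        if not self.pseudo_count > 0:
            raise InvalidPseudoCountError(
                f"pseudo-count for state {self.label!r} must be > 0"
            )


@dataclass(frozen=True)
class GenotypeConfig:
    """Genotype configuration of one SNV.

    Parameters
    ----------
    ref_allele_prob_ref_pop
        Probability mu_r of sampling a reference allele from the reference
        population; 1 minus the sequencer error rate for a normal locus.
    states
        Candidate variant-population genotypes with their reference-allele
        sampling probabilities and Dirichlet pseudo-counts.
    """

    ref_allele_prob_ref_pop: float
    states: tuple[GenotypeState, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.ref_allele_prob_ref_pop <= 1.0:
            raise ValueError("mu_r outside [0,1]")
        if len(self.states) == 0:
            raise ValueError("at least one genotype state required")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.states)


def mixture_weights(config: GenotypeConfig) -> np.ndarray:
    """Marginal genotype probabilities after integrating out the Dirichlet.

    For a single categorical draw with Dirichlet(delta) prior the marginal
    probability of genotype g is

        Gamma(delta_g + 1) * prod_{g' != g} Gamma(delta_{g'})
        / Gamma(sum(delta) + 1) * Gamma(sum(delta)) ... = delta_g / sum(delta)

    i.e. the Dirichlet compound multinomial with one draw collapses to the
    normalized pseudo-counts.
    """
    delta = np.array([s.pseudo_count for s in config.states], dtype=float)
    if np.any(delta <= 0):
        raise InvalidPseudoCountError("all pseudo-counts must be > 0")
    return delta / delta.sum()


def ref_allele_prob(
    phi: float, mu_r: float, mu_v_g: float, eps: float = PROB_CLAMP
) -> float:
    """Probability that a read sampled at the locus shows the reference allele.

    ``(1 - phi) * mu_r + phi * mu_v_g`` clamped to ``(eps, 1 - eps)``.
    """
    for name, val in (("phi", phi), ("mu_r", mu_r), ("mu_v_g", mu_v_g)):
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"{name}={val} outside [0,1]")
    p = (1.0 - phi) * mu_r + phi * mu_v_g
    return float(min(max(p, eps), 1.0 - eps))


@dataclass(frozen=True)
class SnvObservation:
    """Read counts of one SNV across samples, plus its genotype configuration.

    ``variant_reads[t]`` is b_i^t, ``total_reads[t]`` is d_i^t; the reference
    read count a_i^t = d_i^t - b_i^t.
    """

    snv_id: str
    variant_reads: tuple[int, ...]
    total_reads: tuple[int, ...]
    genotype: GenotypeConfig

    def __post_init__(self) -> None:
        if len(self.variant_reads) != len(self.total_reads):
            raise InvalidObservationError("b and d must have equal length")
        for b, d in zip(self.variant_reads, self.total_reads):
            if d < 0 or b < 0 or b > d:
                raise InvalidObservationError(
                    f"{self.snv_id}: need 0 <= b <= d, got b={b}, d={d}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.variant_reads)

    def allele_frequency(self, sample_index: int = 0) -> float:
        d = self.total_reads[sample_index]
        return self.variant_reads[sample_index] / d if d > 0 else float("nan")


def snv_log_likelihood(obs: SnvObservation, sample_index: int, phi: float) -> float:
    """Genotype-marginalized log-likelihood of one SNV's counts at frequency phi.

    log sum_g w_g * Binomial(b; d, 1 - p_ref(phi, mu_r, mu_v_g)) computed in
    log space.  Written in terms of variant reads b with success probability
    1 - p_ref, which is the same binomial as the reference-count form.
    """
    if not 0.0 <= phi <= 1.0:
        raise ValueError(f"phi={phi} outside [0,1]")
    b = obs.variant_reads[sample_index]
    d = obs.total_reads[sample_index]
    a = d - b
    cfg = obs.genotype
    w = mixture_weights(cfg)
    logc = gammaln(d + 1) - gammaln(b + 1) - gammaln(a + 1)
    terms = np.empty(len(cfg.states))
    for k, state in enumerate(cfg.states):
        p_ref = ref_allele_prob(phi, cfg.ref_allele_prob_ref_pop, state.ref_allele_prob)
        terms[k] = np.log(w[k]) + b * np.log1p(-p_ref) + a * np.log(p_ref)
    return float(logsumexp(terms) + logc)


def default_genotype_config(
    copy_number: int,
    zygosity: str,
    error_rate: float = DEFAULT_ERROR_RATE,
) -> GenotypeConfig:
    """Build a genotype configuration from copy number and zygosity.

    ``heterozygous`` (copy number 2) yields the single state AB with
    mu^{v:AB} = 0.5; ``hemizygous`` (copy number 1) yields B with
    mu^{v:B} = error_rate; ``homozygous`` yields all-variant copies;
    ``unknown`` enumerates every genotype with k = 1..copy_number variant
    copies (allele ratio k / copy_number, clamped away from 0 and 1 by the
    error rate) with uniform pseudo-counts delta = 1.
    """
    if copy_number < 1:
        raise ValueError("copy_number must be >= 1")
    mu_r = 1.0 - error_rate
    zyg = zygosity.strip().lower()

    def _mu_for(k: int) -> float:
        frac_ref = (copy_number - k) / copy_number
        return float(min(max(frac_ref, error_rate), 1.0 - error_rate))

    def _label(k: int) -> str:
        return "A" * (copy_number - k) + "B" * k

    if zyg in ("heterozygous", "het", "ab"):
        if copy_number != 2:
            raise ValueError("heterozygous requires copy_number == 2")
        states = (GenotypeState("AB", 0.5),)
    elif zyg in ("hemizygous", "hemi", "b"):
        if copy_number != 1:
            raise ValueError("hemizygous requires copy_number == 1")
        states = (GenotypeState("B", error_rate),)
    elif zyg in ("homozygous", "hom"):
        states = (GenotypeState(_label(copy_number), error_rate),)
    elif zyg in ("unknown", "?"):
        states = tuple(
            GenotypeState(_label(k), _mu_for(k)) for k in range(1, copy_number + 1)
        )
    else:
        raise ValueError(f"unsupported zygosity label {zygosity!r}")
    return GenotypeConfig(mu_r, states)


class SampleSet:
    """A rectangular collection of SNV observations over S samples.

    Besides holding the per-SNV observations, this packs the counts and
    genotype states into padded arrays so the samplers can evaluate the
    genotype-marginalized binomial log-likelihood of every SNV at arbitrary
    frequencies in a few vectorized operations.
    """

    def __init__(
        self, snvs: Sequence[SnvObservation], sample_labels: Sequence[str] | None = None
    ) -> None:
        snvs = list(snvs)
        if not snvs:
            raise ValueError("need at least one SNV")
        n_samples = snvs[0].n_samples
        if n_samples < 1:
            raise ValueError("need at least one sample")
        for o in snvs:
            if o.n_samples != n_samples:
                raise InvalidObservationError(
                    f"{o.snv_id}: expected {n_samples} samples, got {o.n_samples}"
                )
        if sample_labels is None:
            sample_labels = [f"sample{t}" for t in range(n_samples)]
        if len(sample_labels) != n_samples:
            raise ValueError("sample_labels length mismatch")
        self.snvs = snvs
        self.sample_labels = list(sample_labels)
        self._pack()

    def _pack(self) -> None:
        n, s = len(self.snvs), self.n_samples
        self.b = np.array([o.variant_reads for o in self.snvs], dtype=float)
        self.d = np.array([o.total_reads for o in self.snvs], dtype=float)
        self.a = self.d - self.b
        self.mu_r = np.array(
            [o.genotype.ref_allele_prob_ref_pop for o in self.snvs], dtype=float
        )
        gmax = max(len(o.genotype.states) for o in self.snvs)
        self.mu_v = np.zeros((n, gmax))
        self.log_w = np.full((n, gmax), -np.inf)
        for i, o in enumerate(self.snvs):
            w = mixture_weights(o.genotype)
            for k, state in enumerate(o.genotype.states):
                self.mu_v[i, k] = state.ref_allele_prob
                self.log_w[i, k] = np.log(w[k])
        # binomial coefficient, constant in phi; kept so log-likelihoods are
        # proper log-probabilities
        self.log_binom_coeff = (
            gammaln(self.d + 1) - gammaln(self.b + 1) - gammaln(self.a + 1)
        )

    @property
    def n_snvs(self) -> int:
        return len(self.snvs)

    @property
    def n_samples(self) -> int:
        return self.snvs[0].n_samples

    @property
    def snv_ids(self) -> list[str]:
        return [o.snv_id for o in self.snvs]

    def log_likelihood(self, phi: np.ndarray) -> np.ndarray:
        """Log-likelihood of every SNV in every sample at frequencies phi[N, S]."""
        phi = np.asarray(phi, dtype=float)
        if phi.shape != (self.n_snvs, self.n_samples):
            raise ValueError(f"phi must have shape {(self.n_snvs, self.n_samples)}")
        # p_ref[N, S, G] = (1-phi) mu_r + phi mu_v
        p_ref = (
            (1.0 - phi)[:, :, None] * self.mu_r[:, None, None]
            + phi[:, :, None] * self.mu_v[:, None, :]
        )
        np.clip(p_ref, PROB_CLAMP, 1.0 - PROB_CLAMP, out=p_ref)
        terms = (
            self.log_w[:, None, :]
            + self.b[:, :, None] * np.log1p(-p_ref)
            + self.a[:, :, None] * np.log(p_ref)
        )
        return logsumexp(terms, axis=2) + self.log_binom_coeff

    def log_likelihood_sample(self, t: int, phi: np.ndarray) -> np.ndarray:
        """Log-likelihood of every SNV in sample t at per-SNV frequencies phi[N]."""
        phi = np.asarray(phi, dtype=float)
        p_ref = (1.0 - phi)[:, None] * self.mu_r[:, None] + phi[:, None] * self.mu_v
        np.clip(p_ref, PROB_CLAMP, 1.0 - PROB_CLAMP, out=p_ref)
        terms = (
            self.log_w
            + self.b[:, t, None] * np.log1p(-p_ref)
            + self.a[:, t, None] * np.log(p_ref)
        )
        return logsumexp(terms, axis=1) + self.log_binom_coeff[:, t]

    def log_likelihood_snv_multi(self, i: int, phi: np.ndarray) -> np.ndarray:
        """Log-likelihood of SNV i (summed over samples) at each row of
        phi[C, S] — one candidate frequency vector per row."""
        phi = np.asarray(phi, dtype=float)
        p_ref = (1.0 - phi)[:, :, None] * self.mu_r[i] + phi[:, :, None] * self.mu_v[i]
        np.clip(p_ref, PROB_CLAMP, 1.0 - PROB_CLAMP, out=p_ref)
        terms = (
            self.log_w[i][None, None, :]
            + self.b[i][None, :, None] * np.log1p(-p_ref)
            + self.a[i][None, :, None] * np.log(p_ref)
        )
        return logsumexp(terms, axis=2).sum(axis=1) + self.log_binom_coeff[i].sum()

    def log_likelihood_snv(self, i: int, phi_per_sample: np.ndarray) -> float:
        """Total log-likelihood of SNV i across samples at frequencies phi[S]."""
        phi = np.asarray(phi_per_sample, dtype=float)
        p_ref = (1.0 - phi)[:, None] * self.mu_r[i] + phi[:, None] * self.mu_v[i]
        np.clip(p_ref, PROB_CLAMP, 1.0 - PROB_CLAMP, out=p_ref)
        terms = (
            self.log_w[i][None, :]
            + self.b[i, :, None] * np.log1p(-p_ref)
            + self.a[i, :, None] * np.log(p_ref)
        )
        return float(logsumexp(terms, axis=1).sum() + self.log_binom_coeff[i].sum())
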
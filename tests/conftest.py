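import numpy as np
import pytest

from clonetree.model import (
    GenotypeConfig,
    GenotypeState,
    SampleSet,
    SnvObservation,
    default_genotype_config,
)


@pytest.fixture
def het_config() -> GenotypeConfig:
    return default_genotype_config(2, "heterozygous", 0.001)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def make_dataset(specs, genotype=None, n_samples=1):
    """Build a SampleSet from [(snv_id, b, d), ...] or [(id, (b,..), (d,..))]."""
    genotype = genotype or default_genotype_config(2, "heterozygous", 0.001)
    snvs = []
    for spec in specs:
        sid, b, d = spec
        if isinstance(b, int):
            b, d = (b,) * n_samples, (d,) * n_samples
        snvs.append(SnvObservation(sid, tuple(b), tuple(d), genotype))
    return SampleSet(snvs)


@pytest.fixture
def zero_depth_dataset(het_config):
    """Eight SNVs with no reads: the likelihood is flat in phi."""
    return SampleSet(
        [SnvObservation(f"v{i}", (0,), (0,), het_config) for i in range(8)]
    )
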
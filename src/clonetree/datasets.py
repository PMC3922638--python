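"""Worked example datasets: deep-targeted AML allele counts.

Variant read counts and depths for the hematopoietic stem cell samples SU070
(10 SNVs) and SU048 (6 SNVs) from deep targeted resequencing of
exome-identified somatic SNVs, with the published point estimates of the
allele frequencies for cross-checking.  All loci are treated as heterozygous
at normal copy number.
"""

from __future__ import annotations

from .model import SampleSet, SnvObservation, default_genotype_config

__all__ = ["aml_su070", "aml_su048", "SU070_COUNTS", "SU048_COUNTS"]

# snv_id: (variant reads, read depth, published allele frequency)
SU070_COUNTS = {
    "CACNA1H": (12085, 24860, 0.486),
    "TET2-T1884A": (4220, 8772, 0.481),
    "TET2-Y1649stop": (7792, 16211, 0.481),
    "CXorf66": (3684, 8150, 0.452),
    "CXorf36": (3523, 8060, 0.437),
    "DOCK9": (3391, 8676, 0.391),
    "NCRNA00200": (9201, 25413, 0.362),
    "CTCF": (10558, 30119, 0.351),
    "GABARAPL1": (1648, 4992, 0.330),
    "SCN4B": (5113, 16386, 0.312),
}

SU048_COUNTS = {
    "TET2-E1357stop": (7436, 19553, 0.380),
    "SMC1A": (182974, 660069, 0.277),
    "ACSM1": (17149, 127236, 0.135),
    "OLFM2": (13828, 122523, 0.113),
    "TET2-D1384V": (1833, 17687, 0.104),
    "ZMYM3": (18536, 307346, 0.060),
}


def _build(counts: dict, label: str, error_rate: float) -> SampleSet:
    genotype = default_genotype_config(2, "heterozygous", error_rate)
    snvs = [
        SnvObservation(sid, (b,), (d,), genotype) for sid, (b, d, _af) in counts.items()
    ]
    return SampleSet(snvs, [label])


def aml_su070(error_rate: float = 1e-3) -> SampleSet:
    """The 10-SNV SU070 sample as a single-sample dataset."""
    return _build(SU070_COUNTS, "SU070", error_rate)


def aml_su048(error_rate: float = 1e-3) -> SampleSet:
    """The 6-SNV SU048 sample as a single-sample dataset."""
    return _build(SU048_COUNTS, "SU048", error_rate)
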
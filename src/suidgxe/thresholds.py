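"""Genotype-frequency cutoffs that gate genetic-etiology classification.

Two independent upper bounds on the population frequency of a genotype that
is plausibly a highly penetrant cause of sudden unexpected infant death
(SUID):

1. A prevalence model: if a fraction ``G`` of SUID (population prevalence
   ``P``) is attributable to genetic disorders, spread over ``l`` loci with
   ``d`` distinct causal genotypes per locus, each conveying probability
   ``p_med`` of SUID, then a single causal genotype cannot be more common
   than ``f = P * G / (p_med * l * d)``.

2. A reference-population zero-count bound: a highly penetrant lethal
   genotype should be absent from a large adult reference cohort, so its
   frequency is bounded by the Wilson score upper confidence limit for zero
   occurrences in ``n_ref`` subjects.

Classification uses the larger of the two; a relaxed secondary cutoff
(``f_secondary``) admits pathogenic/likely-pathogenic findings of lower
implied penetrance as *possible* rather than *probable* etiologies.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ThresholdParams",
    "model_frequency_cutoff",
    "wilson_zero_upper",
    "genotype_frequency",
    "primary_cutoff",
]

#: 99% two-sided normal critical value. The bound this calibrates matches the
#: published reference-cohort cutoff (8.2e-6 for n=807,162); see docs/methods.md
#: for why this, and not the 99.9% value, is the default.
DEFAULT_CRIT = 2.5758293035489004

MOI_CODES = ("AD", "AR", "XL")


@dataclass(frozen=True)
class ThresholdParams:
    """Inputs to the two frequency cutoffs.

    Defaults are the published study values: US SUID prevalence 101/100,000,
    a third of SUID attributable to genetic disorders, median likelihood of
    SUID given a causal disorder 0.9, median locus heterogeneity 100, median
    genotype heterogeneity per locus 20, reference cohort of 807,162
    subjects, and a secondary (relaxed) cutoff of 3.6e-5.
    """

    P: float = 101 / 100_000
    G: float = 0.33
    p_med: float = 0.9
    l: float = 100.0
    d: float = 20.0
    n_ref: float = 807_162
    crit: float = DEFAULT_CRIT
    f_secondary: float = 3.6e-5

    def __post_init__(self) -> None:
        if not (0 < self.P < 1):
            raise ValueError(f"P must be in (0, 1), got {self.P}")
        if not (0 <= self.G <= 1):
            raise ValueError(f"G must be in [0, 1], got {self.G}")
        if not (0 < self.p_med <= 1):
            raise ValueError(f"p_med must be in (0, 1], got {self.p_med}")
        if self.l < 1:
            raise ValueError(f"l must be >= 1, got {self.l}")
        if self.d < 1:
            raise ValueError(f"d must be >= 1, got {self.d}")
        if self.n_ref < 1:
            raise ValueError(f"n_ref must be >= 1, got {self.n_ref}")
        if self.crit <= 0:
            raise ValueError(f"crit must be > 0, got {self.crit}")
        if not (0 < self.f_secondary < 1):
            raise ValueError(
                f"f_secondary must be in (0, 1), got {self.f_secondary}"
            )


def model_frequency_cutoff(params: ThresholdParams) -> float:
    """Prevalence-model genotype frequency cutoff ``P*G / (p_med*l*d)``.

    With the default parameters this evaluates to 1.85e-7 (printed as
    1.9e-7 at two significant figures).
    """
    return (params.P * params.G) / (params.p_med * params.l * params.d)


def wilson_zero_upper(n_ref: float, crit: float = DEFAULT_CRIT) -> float:
    """Wilson score upper confidence bound for 0 events in ``n_ref`` trials.

    For x = 0 the Wilson interval upper limit reduces to the closed form
    ``z^2 / (n + z^2)``. Strictly decreasing in ``n_ref`` and increasing in
    ``crit``; with n_ref = 807,162 and the default critical value it is
    8.2e-6 (two significant figures).
    """
    if n_ref < 1:
        raise ValueError(f"n_ref must be >= 1, got {n_ref}")
    if crit <= 0:
        raise ValueError(f"crit must be > 0, got {crit}")
    z2 = crit * crit
    return z2 / (n_ref + z2)


def primary_cutoff(params: ThresholdParams) -> float:
    """The operative cutoff: the larger of the model and Wilson bounds."""
    return max(
        model_frequency_cutoff(params),
        wilson_zero_upper(params.n_ref, params.crit),
    )


def genotype_frequency(allele_freq: float, moi: str) -> float:
    """Convert an allele frequency to a genotype frequency for a given MOI.

    AD and XL use the small-q heterozygote-dominant approximation (genotype
    frequency = allele frequency); AR uses the Hardy-Weinberg homozygote
    frequency q^2.
    """
    if not (0 <= allele_freq <= 1):
        raise ValueError(f"allele_freq must be in [0, 1], got {allele_freq}")
    if moi not in MOI_CODES:
        raise ValueError(f"moi must be one of {MOI_CODES}, got {moi!r}")
    if moi == "AR":
        return allele_freq * allele_freq
    return allele_freq
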
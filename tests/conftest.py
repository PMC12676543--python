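import pytest

from suidgxe import DisorderProfile, ThresholdParams


@pytest.fixture
def params():
    return ThresholdParams()


def make_profile(
    disorder_id="D0001",
    p_death=0.2,
    infant_death_associated=True,
    intervention_available=True,
    birth_prevalence=1e-5,
    principal_organ="other",
    name="fixture disorder",
):
    return DisorderProfile(
        disorder_id=disorder_id,
        name=name,
        birth_prevalence=birth_prevalence,
        p_death=p_death,
        infant_death_associated=infant_death_associated,
        intervention_available=intervention_available,
        principal_organ=principal_organ,
    )


@pytest.fixture
def profile_factory():
    return make_profile


@pytest.fixture
def passing_qc_metrics():
    return {
        "q30_fraction": 0.90,
        "error_rate": 0.01,
        "yield_gb": 130.0,
        "duplicate_fraction": 0.10,
        "aligned_fraction": 0.99,
        "titv_ratio": 2.1,
        "hom_het_ratio": 0.50,
        "mim_cov10_fraction": 0.95,
        "sex_match": True,
    }
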
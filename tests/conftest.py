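import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from porphyra.flowcyto import StandardRef
from porphyra.genotypes import PolyploidGenotype
from porphyra.synthetic import study_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def standard() -> StandardRef:
    """Tomato internal standard: 2C = 1.96 pg, acquired at channel 720."""
    return StandardRef("S_lycopersicum", dna_2c=1.96, expected_channel=720.0)


@pytest.fixture(scope="session")
def study():
    """The fixed survey-design cohort (122 blades / 217 analyses / 121 genotypes)."""
    return study_cohort(seed=1)


@pytest.fixture(scope="session")
def study_flow_results(study):
    """Flow chain run once over the whole stand-in cohort (shared: expensive)."""
    from porphyra.pipeline import process_flow_cohort, profiles_from_calls

    std = study.config.flow.standard_ref()
    samples = (
        (events, truth.blade_id, truth.section_type)
        for events, truth in study.flow_samples()
    )
    calls, failures = process_flow_cohort(samples, std)
    species_of = {b.blade_id: b.species for b in study.blades}
    profiles, cal = profiles_from_calls(calls, species_of)
    return dict(calls=calls, failures=failures, profiles=profiles, calibration=cal)


def make_genotype(
    ind: str,
    alleles_by_locus: dict[str, tuple],
    ploidy: int | None = None,
    species: str = "sp",
) -> PolyploidGenotype:
    return PolyploidGenotype(
        individual_id=ind,
        species=species,
        loci={k: tuple(sorted(v)) for k, v in alleles_by_locus.items()},
        ploidy=ploidy,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
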
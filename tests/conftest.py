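import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from beflitter import (
    AllometryParams,
    Composition,
    LeachingFactors,
    MicrocosmRecord,
    SyntheticConfig,
    compute_metrics,
    generate_experiment,
)


@pytest.fixture(scope="session")
def allometry() -> AllometryParams:
    return AllometryParams()


@pytest.fixture(scope="session")
def leaching() -> LeachingFactors:
    return LeachingFactors({"A": 0.753, "C": 0.843, "Q": 0.844, "I": 0.767})


def make_record(
    species=("A",),
    detritivores=False,
    initial=None,
    final_afdm=None,
    final_dm=None,
    fpom=(1.0, 1.0, 1.0),
    case_lengths=None,
    final_det_dm=None,
    microcosm_id="m1",
    proportions=None,
) -> MicrocosmRecord:
    """Small hand-built microcosm for unit tests."""
    species = tuple(species)
    initial = dict(initial or {sp: 100.0 for sp in species})
    final_afdm = dict(final_afdm or {sp: 50.0 for sp in species})
    final_dm = dict(final_dm or {sp: v * 1.05 for sp, v in final_afdm.items()})
    if detritivores and case_lengths is None:
        case_lengths = (10.0, 10.0, 10.0)
    if detritivores and final_det_dm is None:
        final_det_dm = 20.0
    return MicrocosmRecord(
        microcosm_id=microcosm_id,
        composition=Composition(species, proportions),
        detritivores_present=detritivores,
        n_discs_per_species=48 // len(species),
        initial_airdry_dm=initial,
        final_dm=final_dm,
        final_afdm=final_afdm,
        fpom_filter_mass=tuple(fpom),
        detritivore_case_lengths=tuple(case_lengths) if case_lengths else None,
        detritivore_final_dm=final_det_dm,
        expected_larvae=len(case_lengths) if case_lengths else 3,
    )


@pytest.fixture(scope="session")
def paper_config() -> SyntheticConfig:
    return SyntheticConfig.paper_like(seed=2024)


@pytest.fixture(scope="session")
def paper_records(paper_config):
    return generate_experiment(paper_config)


@pytest.fixture(scope="session")
def paper_metrics(paper_config, paper_records):
    return compute_metrics(paper_records, paper_config.leaching, paper_config.allometry)
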
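import pytest

from coronadiel import FieldConfig, OscillatorEnsemble, literature_fixture


@pytest.fixture(scope="session")
def field():
    """Microwave probe configuration: 6.41 GHz, 4.9 V/m, 1 us eval time."""
    return FieldConfig()


@pytest.fixture(scope="session")
def fixture_data():
    """(records, registry) for the insulin/papain/ZnO measurement fixture."""
    return literature_fixture()


@pytest.fixture
def simple_ensemble():
    """Ensemble with comfortably real inversion roots at eps_r of tens."""
    return OscillatorEnsemble(
        n_molecules_N=1e11, strength_NQ2_over_M=1e12, gamma_eff=5e9
    )
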
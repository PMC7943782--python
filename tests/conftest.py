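import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from barcodelib import protax
from barcodelib.simulate import SyntheticConfig, generate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_dataset():
    """Default-condition synthetic library (32 species, variable sampling)."""
    return generate_dataset(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def identification_dataset():
    """Identification cohort: ~30 species at 20 specimens each, one forced
    singleton species and one congeneric introgressed pair."""
    cfg = SyntheticConfig(
        seed=1,
        constant_n=20,
        n_singleton_species=1,
        introgression_pairs=[("Fam2_Sub1_Gen1_sp1", "Fam2_Sub1_Gen1_sp2", 2)],
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def trained_model(identification_dataset):
    return protax.train(identification_dataset.library, seed=5)


@pytest.fixture(scope="session")
def loo_results(trained_model):
    return protax.leave_one_out(trained_model)


@pytest.fixture(scope="session")
def spatial_dataset():
    """Spatial cohort: heavy continent-wide sampling so most species qualify
    in most belts (richness gradient peaked at 42.5 deg)."""
    return generate_dataset(SyntheticConfig(seed=3, specimens_coef=50.0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
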
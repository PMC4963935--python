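import pytest
from hypothesis import settings

from vlatt.io import GenomeRecord
from vlatt.element_discovery import discover
from vlatt.lineage_classifier import profiles_from_models
from vlatt.synthetic_genome import default_models, make_background, plant_elements

settings.register_profile("vlatt", derandomize=True, max_examples=50)
settings.load_profile("vlatt")


@pytest.fixture(scope="session")
def models():
    return default_models()


@pytest.fixture(scope="session")
def small_genome(models):
    """600 kb background, 2 copies per lineage, 2% divergence."""
    bg = make_background(600_000, 0.40, 7)
    genome, truth = plant_elements(bg, models, 2, 0.02, seed=5, genome_id="g")
    return genome, truth


@pytest.fixture(scope="session")
def small_elements(small_genome):
    genome, _ = small_genome
    return discover(GenomeRecord("g", genome))


@pytest.fixture(scope="session")
def rt_profiles(models):
    """Calibrated profiles for the 11 default lineage models."""
    return profiles_from_models(models)
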
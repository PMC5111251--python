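import numpy as np
import pytest

from dysbiota.pathogens import load_pathogen_table
from dysbiota.simulate import SimulationSpec, simulate_reference


@pytest.fixture(scope="session")
def bundled_table():
    return load_pathogen_table()


@pytest.fixture(scope="session")
def small_reference():
    """Small, well-separated synthetic reference: 4 genera x 2 species."""
    spec = SimulationSpec(
        n_genera=4, species_per_genus=2, sequence_length=400,
        genus_divergence=0.15, species_divergence=0.03,
        harmful_genera=(0,), seed=11,
    )
    return simulate_reference(spec)


@pytest.fixture(scope="session")
def study_reference():
    """The default study condition: 10 genera x 2 species, 1200 bp."""
    return simulate_reference(SimulationSpec(seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
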
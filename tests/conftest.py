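import pytest

from spawnfeast.diet import load_diet_items
from spawnfeast.simulate import load_preset, simulate_dataset


@pytest.fixture(scope="session")
def diet_items():
    return load_diet_items()


@pytest.fixture(scope="session")
def published_fv_2012():
    """The published 2012 annual faecal-volume column (trace items as 0)."""
    return {
        "brown_algae": 38.6,
        "green_algae": 0.0,
        "red_algae": 0.6,
        "amphipods": 5.4,
        "herring_eggs": 1.1,
        "seagrasses": 39.5,
        "graminoids": 5.9,
        "forbs": 1.1,
    }


@pytest.fixture(scope="session")
def strong_bundle():
    """One strong-effect synthetic season shared across tests."""
    return simulate_dataset(load_preset("strong", seed=11))
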
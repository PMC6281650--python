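import logging

import pytest

from dpnnet.deg import map_orthologues
from dpnnet.simulate import SyntheticConfig, generate_bundle

logging.getLogger("dpnnet").setLevel(logging.ERROR)

SMALL_SIZES = (40, 20, 60, 35, 18, 15, 45, 70)
SMALL_LABELS = ("m1", "m2", "m3", "m4", "m5", "m6", "m7", "hs")


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Reduced-scale world for unit tests: 150-gene universe, 3 hubs."""
    return SyntheticConfig(n_genes=150, deg_set_sizes=SMALL_SIZES,
                           dataset_labels=SMALL_LABELS, n_planted_hubs=3,
                           n_pathways=20, pathway_size_range=(5, 15), seed=11)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_bundle(small_config)


@pytest.fixture(scope="session")
def mapped_degs(small_bundle):
    """All eight DEG sets lifted into the human namespace."""
    out = []
    for deg in small_bundle.deg_sets:
        if deg.species == "mouse":
            deg, _ = map_orthologues(deg, small_bundle.orthologue_map)
        out.append(deg)
    return out
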
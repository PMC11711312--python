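import numpy as np
import pandas as pd
import pytest

from folliclemap import (
    AxonNode,
    AxonReconstruction,
    SyntheticConfig,
    classify,
    generate_follicle,
)


@pytest.fixture(scope="session")
def small_follicle():
    """One deterministic synthetic follicle at the default study conditions."""
    config = SyntheticConfig(seed=11)
    recons, features, truth = generate_follicle(config)
    features = features.copy()
    features["afferent_type"] = np.where(
        features["superficial"], "Superficial",
        np.where(~features["myelinated"], "Unmyelinated",
                 classify(features, bands=config.bands)))
    return config, recons, features, truth


@pytest.fixture()
def chain_reconstruction():
    """Unbranched 3-node vertical chain with constant radius 1 µm."""
    nodes = [
        AxonNode(1, -1, 0.0, 0.0, 0.0, 1.0),
        AxonNode(2, 1, 0.0, 0.0, 100.0, 1.0),
        AxonNode(3, 2, 0.0, 0.0, 250.0, 1.0),
    ]
    return AxonReconstruction(afferent_id="chain", nodes=nodes)
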
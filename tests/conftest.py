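import warnings

import numpy as np
import pytest

from urban3d.synthetic_city import (
    CityConfig,
    SyntheticTruth,
    generate_monitoring_panel,
    generate_parcels,
    generate_roads,
)

# the generators intentionally warn in degenerate situations; keep test
# output clean without hiding warnings from the assertions that want them
warnings.filterwarnings("ignore", category=UserWarning, module="urban3d")


@pytest.fixture(scope="session")
def default_city_seed0():
    """Parcels, candidates, roads, truth and panel of the default city."""
    cfg = CityConfig(seed=0)
    parcels, candidates = generate_parcels(cfg)
    roads = generate_roads(cfg)
    truth = SyntheticTruth()
    panel = generate_monitoring_panel(cfg, parcels, roads, truth, candidates=candidates)
    return {
        "config": cfg,
        "parcels": parcels,
        "candidates": candidates,
        "roads": roads,
        "truth": truth,
        "panel": panel,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
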
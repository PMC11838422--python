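import numpy as np
import pytest

import geciquant as gq

#: The 16-point free-calcium grid of the standard EGTA/Ca-EGTA reciprocal
#: dilution series (nM), used as the titration x-axis in fitting tests.
CA_GRID_NM = np.array(
    [2.1, 7.9, 16.3, 35.4, 79.2, 135.5, 208.4, 312.6, 468.9, 731.5,
     1254.6, 2817.6, 5856.0, 11858.0, 21923.7, 81276.0]
)


@pytest.fixture(scope="session")
def frcampi() -> gq.IndicatorParams:
    return gq.FRCAMPI


@pytest.fixture(scope="session")
def ca_grid() -> np.ndarray:
    return CA_GRID_NM


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def tiny_pipeline_config(seed: int = 7) -> dict:
    """A small, fast configuration for pipeline-level tests."""
    return {
        "seed": seed,
        "scene": {
            "n_neurons": 6,
            "fov": [64.0, 64.0],
            "neurite_length": 150.0,
        },
        "activity": {"duration_s": 30.0},
    }
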
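import numpy as np
import pandas as pd
import pytest

from soilhazard.io import SampleSet


def make_samples(coords, nonnegative=True, **metal_values) -> SampleSet:
    """Build a SampleSet from a coordinate array and per-metal value vectors."""
    coords = np.asarray(coords, dtype=float)
    data = {
        "id": [f"p{i}" for i in range(len(coords))],
        "x": coords[:, 0],
        "y": coords[:, 1],
    }
    data.update({k: np.asarray(v, dtype=float) for k, v in metal_values.items()})
    return SampleSet(pd.DataFrame(data), nonnegative=nonnegative)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_cfg():
    from soilhazard.synthetic import default_config

    return default_config()
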
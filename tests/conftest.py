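import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py

from firescape.raster_core import Grid


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def grid_10m():
    def make(values, nodata=-1):
        return Grid(np.asarray(values), resolution_m=10.0, nodata=nodata)

    return make


@pytest.fixture
def grid_30m():
    def make(values, nodata=-1):
        return Grid(np.asarray(values), resolution_m=30.0, nodata=nodata)

    return make
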
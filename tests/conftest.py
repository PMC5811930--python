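import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from gpcrbias import ModelSpec, default_parameters


@pytest.fixture(scope="session")
def spec22():
    return ModelSpec(n_active=2, n_gprot=2, ligand_mode="constant")


@pytest.fixture
def params22(spec22):
    return default_parameters(spec22)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
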
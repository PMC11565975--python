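import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from nacyl.chem_core import default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def heads_by_name(registry):
    return {h.name: h for h in registry}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
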
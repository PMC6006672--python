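import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from te_exchange.synthetic_data import default_species_tree  # noqa: E402


@pytest.fixture(scope="session")
def species_tree():
    return default_species_tree()


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
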
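import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose oracles.py

from qctlung.phantom import generate_phantom, random_phantom_spec


@pytest.fixture(scope="session")
def noisefree_phantom():
    """One randomized noise-free five-lobe phantom with ground truth."""
    spec = random_phantom_spec(11)
    ct, labels, truth = generate_phantom(spec, seed=11)
    return spec, ct, labels, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
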
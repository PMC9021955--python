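import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from equistr.panel import load_locus_stats, load_panel
from equistr.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def panel():
    return load_panel()


@pytest.fixture(scope="session")
def locus_table():
    return load_locus_stats()


@pytest.fixture(scope="session")
def study():
    """One small synthetic study shared across tests (fixed seed)."""
    return simulate_study(SimulationConfig(seed=2024, n_individuals=60, n_breeds=4))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
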
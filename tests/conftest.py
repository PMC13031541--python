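import numpy as np
import pytest

from invclines.io_formats import load_default_enzymes, load_european_locations
from invclines.synthetic_data import SimulationConfig, simulate_inversion_dataset


@pytest.fixture(scope="session")
def table1():
    """The packaged ten-location European karyotype count table."""
    return load_european_locations()


@pytest.fixture(scope="session")
def enzymes():
    return load_default_enzymes()


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulated dataset shared across tests."""
    cfg = SimulationConfig(seed=7)
    g, truth = simulate_inversion_dataset(cfg)
    return cfg, g, truth


def jaccard(a, b):
    """Interval Jaccard overlap; empty call scores 0."""
    if a is None or b is None:
        return 0.0
    lo, hi = max(a[0], b[0]), min(a[1], b[1])
    inter = max(0, hi - lo)
    return inter / ((a[1] - a[0]) + (b[1] - b[0]) - inter)
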
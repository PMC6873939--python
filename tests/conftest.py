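import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import scdiversity as sd

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def tiny_table() -> sd.CellAnnotationTable:
    """Two samples, two conditions, three clusters; hand-countable."""
    rows = [
        ("AAAA-1", "H1", "healthy", 1),
        ("AAAC-1", "H1", "healthy", 1),
        ("AAAG-1", "H1", "healthy", 1),
        ("AAAT-1", "H1", "healthy", 2),
        ("CCCA-2", "A1", "aml", 1),
        ("CCCC-2", "A1", "aml", 2),
        ("CCCG-2", "A1", "aml", 3),
        ("CCCT-2", "A1", "aml", 3),
    ]
    return sd.CellAnnotationTable(
        pd.DataFrame(rows, columns=["barcode", "sample_id", "condition", "cluster"])
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A simulated two-condition cohort shared across I/O and network tests."""
    spec = sd.preset_scenarios(seed=7, n_cells=150)["aml-vs-healthy"]
    return sd.simulate_cohort(spec)


def random_distribution(rng: np.random.Generator, max_clusters: int = 50):
    """Random occupancy distribution with 2..max_clusters occupied clusters."""
    k = int(rng.integers(2, max_clusters + 1))
    # wide count range keeps exact ties at the maximum vanishingly rare, so
    # the finite-q Berger-Parker check is well posed
    counts = rng.integers(1, 10**6, size=k)
    return sd.ClusterDistribution(tuple(range(1, k + 1)), counts)
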
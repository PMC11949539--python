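import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

from prevstab import OccurrenceTable, StabilityParams, make_fixture_table


@pytest.fixture
def default_params():
    return StabilityParams(seed=0)


@pytest.fixture
def tiny_table():
    """Two groups, two species, one missing cell."""
    return OccurrenceTable(
        groups=("A", "A", "A", "B", "B"),
        species_names=("sp1", "sp2"),
        values=np.array(
            [[1, 0], [0, 1], [1, np.nan], [0, 1], [1, 1]], dtype=float
        ),
    )


@pytest.fixture
def mixed_fixture_table():
    """Deterministic medium table with known per-pair totals."""
    return make_fixture_table(
        [
            ("H1", "s1", 40, 10),
            ("H1", "s2", 30, 15),
            ("H2", "s1", 25, 20),
        ],
        seed=7,
    )


def noisy_curve(seed: int, k_max: int = 40, start: float = 50.0, scale: float = 3.0):
    """Random smooth-ish curve in [0, 100] for detector tests."""
    rng = np.random.default_rng(seed)
    steps = rng.normal(0, scale / np.arange(1, k_max), size=k_max - 1)
    m = np.clip(start + np.concatenate([[0.0], np.cumsum(steps)]), 0.0, 100.0)
    return m
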
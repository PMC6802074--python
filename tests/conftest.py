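import numpy as np
import pytest

from groupedkde import GroupedSample, datasets


@pytest.fixture(scope="session")
def pooled_10mm() -> GroupedSample:
    return datasets.load_wild_oat_pooled(10)


@pytest.fixture(scope="session")
def cylinders_10mm():
    return datasets.load_wild_oat(10)


@pytest.fixture
def symmetric_sample() -> GroupedSample:
    return GroupedSample(edges=[-3.0, -1.0, 1.0, 3.0], counts=[4, 0, 4])


@pytest.fixture(scope="session")
def fine_normal_sample():
    """Finely binned large normal sample with known moments (mu=100, sd=10)."""
    rng = np.random.default_rng(20240601)
    draws = rng.normal(100.0, 10.0, size=100_000)
    edges = np.linspace(50.0, 150.0, 61)
    counts = np.histogram(draws, bins=edges)[0]
    return GroupedSample(edges=edges, counts=counts, label="normal(100,10)")
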
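import numpy as np
import pytest
from hypothesis import settings

from roctrio import SampleData

settings.register_profile("repro", deadline=None, derandomize=True)
settings.load_profile("repro")


@pytest.fixture
def tiny_sample() -> SampleData:
    """The 2x2 worked example: Y1 = {3, 5}, Y0 = {1, 4}."""
    return SampleData([3.0, 5.0], [1.0, 4.0])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20120628)


@pytest.fixture
def small_sample_factory(rng):
    """Random small integer-valued samples (2 <= n1, n0 <= 8), with ties."""

    def factory():
        n1 = int(rng.integers(2, 9))
        n0 = int(rng.integers(2, 9))
        return SampleData(
            rng.integers(0, 6, n1).astype(float), rng.integers(0, 6, n0).astype(float)
        )

    return factory


@pytest.fixture
def binormal_sample_factory(rng):
    """Samples from the benchmark's normal scenario (a=1.4, b=0.9)."""

    def factory(n1=100, n0=100, a=1.4, b=0.9):
        return SampleData(rng.normal(a / b, 1 / b, n1), rng.normal(0, 1, n0))

    return factory
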
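import numpy as np
import pytest

from transectne import (ChromosomeMap, LengthGrid, SampleSet, SamplingScheme)


@pytest.fixture(scope="session")
def autosomes() -> ChromosomeMap:
    return ChromosomeMap.default_autosomes()


@pytest.fixture
def small_chroms() -> ChromosomeMap:
    return ChromosomeMap({"1": 1.5, "2": 1.0, "3": 2.0})


@pytest.fixture
def grid() -> LengthGrid:
    return LengthGrid.from_cm(8, 20, 0.25)


@pytest.fixture
def two_set_scheme() -> SamplingScheme:
    return SamplingScheme([SampleSet(0, 5), SampleSet(12, 4)])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
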
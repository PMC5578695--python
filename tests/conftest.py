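import numpy as np
import pytest

from meiomap import GenomeMap, MarkerMap


@pytest.fixture
def small_genome() -> GenomeMap:
    return GenomeMap((("chrA", 120_000), ("chrB", 80_000)))


@pytest.fixture
def six_markers() -> MarkerMap:
    return MarkerMap({"chrS": np.array([1000, 3000, 5000, 7000, 9000, 11000])})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20170821)
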
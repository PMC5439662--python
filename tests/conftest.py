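import numpy as np
import pytest

from dnapartition.fixtures import random_sequence
from dnapartition.model import DesignRecord
from dnapartition.params import PartitionParams


@pytest.fixture(scope="session")
def record_20k() -> DesignRecord:
    """The worked-example input: 20 kb seeded random design, GC 0.5."""
    return DesignRecord("design20k", random_sequence(20000, 0.5, 1)).validate()


@pytest.fixture(scope="session")
def record_100k() -> DesignRecord:
    return DesignRecord("design100k", random_sequence(100000, 0.5, 2)).validate()


@pytest.fixture()
def default_params() -> PartitionParams:
    return PartitionParams()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20170522)
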
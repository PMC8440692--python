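import numpy as np
import pytest

from qsat import (
    ParameterGrid,
    STUDY_OBSERVERS,
    TaskSpec,
    VirtualObserver,
    init_prior,
)


@pytest.fixture(scope="session")
def task():
    return TaskSpec()


@pytest.fixture(scope="session")
def observer1():
    return VirtualObserver(STUDY_OBSERVERS[1])


@pytest.fixture(scope="session")
def observer3():
    return VirtualObserver(STUDY_OBSERVERS[3])


@pytest.fixture(scope="session")
def grid():
    return ParameterGrid()


@pytest.fixture
def uniform_prior(grid):
    return init_prior(grid)


@pytest.fixture
def tiny_grid():
    return ParameterGrid(
        lam_axis=np.array([0.42, 0.46, 0.50]),
        gam_axis=np.array([5.0, 10.0, 20.0]),
        del_axis=np.array([0.1, 0.25, 0.4]),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
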
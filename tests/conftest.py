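import numpy as np
import pytest

from pullnma import (
    DumbbellSpec,
    ENMParameters,
    align_pulling_axis,
    compute_enm_modes,
    make_dimer,
    make_dumbbell,
    make_helix,
)


@pytest.fixture(scope="session")
def dimer():
    return make_dimer(3.8)


@pytest.fixture(scope="session")
def dimer_modes(dimer):
    return compute_enm_modes(dimer, ENMParameters(n_modes="all"))


@pytest.fixture(scope="session")
def helix10():
    return make_helix(10)


@pytest.fixture(scope="session")
def helix10_modes(helix10):
    return compute_enm_modes(helix10, ENMParameters(n_modes="all"))


@pytest.fixture(scope="session")
def dumbbell():
    """Symmetric dumbbell: (model, domain map, pulling geometry)."""
    return make_dumbbell(DumbbellSpec(seed=7))


@pytest.fixture(scope="session")
def dumbbell_aligned(dumbbell):
    """Dumbbell rotated so the pulling direction is the z-axis, plus its modes."""
    model, dm, pull = dumbbell
    aligned, _ = align_pulling_axis(model, pull)
    modes = compute_enm_modes(aligned, ENMParameters(n_modes="all"))
    return aligned, dm, pull, modes


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
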
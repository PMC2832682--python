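import numpy as np
import pytest

import sizechange as sc


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def all_conditions():
    return sc.CueCondition.all_conditions()


@pytest.fixture(scope="session")
def hb_none():
    return sc.CueCondition(haptic=False, binocular=False)


@pytest.fixture(scope="session")
def haptic_only():
    return sc.CueCondition(haptic=True, binocular=False)


@pytest.fixture(scope="session")
def binocular_only():
    return sc.CueCondition(haptic=False, binocular=True)


@pytest.fixture(scope="session")
def small_grid(hb_none):
    """Single-condition Experiment-1 grid at 30 repeats per point."""
    return sc.build_exp1_grid(repeats=30, conditions=[hb_none], seed=11)


@pytest.fixture(scope="session")
def image_only_records(small_grid):
    return sc.simulate_exp1(small_grid, sc.image_only_observer(), seed=21)


@pytest.fixture(scope="session")
def veridical_records(small_grid):
    return sc.simulate_exp1(small_grid, sc.veridical_observer(), seed=22)


@pytest.fixture(scope="session")
def exp2_design_haptic(haptic_only):
    return sc.build_exp2_design(repeats=50, condition=haptic_only, seed=31)
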
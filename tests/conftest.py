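import numpy as np
import pytest

import mitobrush as mb
from mitobrush.fixtures import toy_mini_state


@pytest.fixture(scope="session")
def mini_state():
    """90-bead, three-loop bottlebrush with auto bridges (seed 1)."""
    return toy_mini_state(seed=1)


@pytest.fixture(scope="session")
def mini_traj(mini_state):
    """Short two-phase run on the mini system, shared by format/analysis tests."""
    return mb.run_schedule(
        mini_state,
        mb.ForceFieldParams(),
        mb.EngineParams(seed=7),
        mb.Schedule(phase1_steps=300, phase2_steps=1500, snapshot_every=300),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
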
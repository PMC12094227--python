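import numpy as np
import pytest

from omispike import clustering, synth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def sched_small():
    """~1000 slots, ~35 omissions."""
    return synth.generate_schedule(synth.ScheduleConfig(n_trials=150, seed=11))


@pytest.fixture(scope="session")
def sched_dense():
    """Long schedule with ~150 omissions for modulation power tests."""
    return synth.generate_schedule(synth.ScheduleConfig(n_trials=600, seed=12))


@pytest.fixture(scope="session")
def archetype_session(sched_small):
    """Five visual archetypes x 16 units on one session."""
    mix = [
        synth.UnitSpec(synth.DEFAULT_TEMPLATES[name], 16)
        for name in clustering.VISUAL_ARCHETYPES
    ]
    units = synth.generate_units(sched_small, mix, seed=21)
    return sched_small, units
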
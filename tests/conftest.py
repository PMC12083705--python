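import numpy as np
import pytest

from mocoshift import (
    MotionConfig,
    PairedSample,
    PhantomConfig,
    ScheduleConfig,
    build_schedule,
    corrupt,
    make_phantom,
)


@pytest.fixture(scope="session")
def train_schedule():
    """Default 20-step training schedule (gamma 2, p 0.3)."""
    return build_schedule(ScheduleConfig())


@pytest.fixture(scope="session")
def sampler_schedule():
    """Default 4-step sampler schedule with the same endpoints."""
    return build_schedule(ScheduleConfig(n_steps=4))


@pytest.fixture(scope="session")
def phantom64():
    return make_phantom(PhantomConfig(size=64, seed=11))


@pytest.fixture(scope="session")
def phantom128():
    return make_phantom(PhantomConfig(size=128, seed=11))


@pytest.fixture(scope="session")
def heavy_pair(phantom64):
    y, plan = corrupt(
        phantom64, MotionConfig.preset("heavy"), np.random.default_rng(42)
    )
    return PairedSample(x=phantom64, y=y, level="heavy", meta={"plan": plan})
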
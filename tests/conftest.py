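import numpy as np
import pytest

from hiermotion.config import RunConfig
from hiermotion.datamodel import SensorWindow
from hiermotion.synthetic import gen_session


@pytest.fixture(scope="session")
def cfg() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def short_session():
    """36 s of synthetic standing/brushing/computer-working data."""
    schedule = [("SD", 12.0), ("BR", 12.0), ("CW", 12.0)]
    return gen_session(schedule, seed=7, subject_id="subj")


def random_window(rng: np.random.Generator, n: int = 300) -> SensorWindow:
    return SensorWindow(
        subject_id="rnd",
        timestamps=np.arange(n) / 50.0,
        accel=rng.normal(0.0, 0.5, size=(n, 3)),
        gyro=rng.normal(0.0, 1.0, size=(n, 3)),
    )
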
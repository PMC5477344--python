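import warnings

import numpy as np
import pytest

from kaps.config import LimbConfig, ProtocolConfig, RobotConfig
from kaps.simulate import simulate_trial
from kaps.store import TrialRecording

# percentile-bias warnings etc. from tiny fixtures are exercised explicitly
# in the tests that assert them
warnings.filterwarnings("ignore", message="hold shorter")


@pytest.fixture(scope="session")
def robot() -> RobotConfig:
    return RobotConfig()


@pytest.fixture(scope="session")
def protocol600() -> ProtocolConfig:
    return ProtocolConfig(durations=(600,))


@pytest.fixture(scope="session")
def healthy_extension(robot, protocol600) -> TrialRecording:
    """Noise-free healthy 600 ms extension trial (65 -> 145)."""
    limb = LimbConfig(noise_sd=0.0)
    return simulate_trial(limb, robot, protocol600, "extension", 600, 65.0, 0)


def make_synthetic_trial(*, direction="extension", duration=600, n=3600,
                         angle=None, velocity=None, start=65.0, target=145.0,
                         subject_id="synth", arm="affected", trial_index=1,
                         onset=0.0):
    """Hand-built schema-valid recording for parameter unit tests."""
    t = np.arange(n, dtype=float)
    if angle is None:
        angle = np.full(n, start)
    if velocity is None:
        velocity = np.zeros(n)
    return TrialRecording(
        subject_id=subject_id, arm=arm, direction=direction,
        nominal_duration_ms=duration, trial_index=trial_index,
        time_ms=t, angle_deg=np.asarray(angle, float),
        velocity_deg_s=np.asarray(velocity, float),
        onset_ms=onset, start_angle_deg=start, target_angle_deg=target,
        next_onset_ms=float(n),
    )
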
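import numpy as np
import pytest

from gaitstab import (StabilityParams, Trajectory, condition_presets,
                      detect_gait_events, exclude_turn_strides,
                      generate_reference_trial)

LANDMARKS = ("l_heel", "l_ball", "r_heel", "r_ball")


@pytest.fixture(scope="session")
def params():
    return StabilityParams(0.92)


@pytest.fixture(scope="session")
def normal_trial():
    """One reference-system normal-walking trial with ground truth."""
    spec = condition_presets()["normal"]
    return generate_reference_trial(spec, seed=11)


@pytest.fixture(scope="session")
def processed_normal(normal_trial):
    """Filtered trial + detected (turn-screened) events + ground truth."""
    traj, gt = normal_trial
    f = traj.filtered()
    ev = exclude_turn_strides(f, detect_gait_events(f), 30.0)
    return f, ev, gt


@pytest.fixture
def make_traj():
    """Factory for hand-built trajectories (zeros unless overridden)."""

    def _make(n=600, rate=100.0, com=None, landmarks=None, **kwargs):
        t = np.arange(n) / rate
        com = np.zeros((n, 3)) if com is None else np.asarray(com, float)
        lm = {k: np.zeros((n, 3)) for k in LANDMARKS}
        if landmarks:
            for k, v in landmarks.items():
                lm[k] = np.asarray(v, float)
        return Trajectory(time=t, com=com, landmarks=lm, rate=rate, **kwargs)

    return _make
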
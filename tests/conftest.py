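import numpy as np
import pytest

from skimech import SimConfig, TrialMeta, default_point_model, generate_trial
from skimech.io import KinematicTrial
from skimech.simulate import base_pose


@pytest.fixture(scope="session")
def model():
    return default_point_model()


@pytest.fixture(scope="session")
def meta():
    return TrialMeta(participant="T1", skill="intermediate", effort="medium",
                     body_mass_kg=80.0)


def make_static_trial(n_frames, model, meta, rate_hz=240.0, identity_pelvis=True):
    """Static upright skier; pelvis frame made exactly global when requested."""
    pose = dict(base_pose())
    if identity_pelvis:
        pose["PELVIS_LASIS"] = (0.12, 0.13, 0.0)
        pose["PELVIS_RASIS"] = (0.12, -0.13, 0.0)
        pose["PELVIS_ORIGIN"] = (0.0, 0.0, 0.0)
    frames = np.empty((n_frames, 76, 3))
    for i, lbl in enumerate(model.labels):
        frames[:, i, :] = np.asarray(pose[lbl]) * 1000.0
    time_s = np.arange(n_frames) / rate_hz
    power = np.zeros((n_frames, 5))
    return KinematicTrial(frames=frames, time_s=time_s, power=power,
                          meta=meta, model=model)


@pytest.fixture()
def static_trial(model, meta):
    return make_static_trial(48, model, meta)


@pytest.fixture(scope="session")
def clean_trial():
    """Noise-free simulated diagonal-stride trial with ground truth."""
    cfg = SimConfig(technique="diagonal_stride", skill="intermediate",
                    n_cycles=8, noise_sd_mm=0.0, drift_mm_per_s=0.0, seed=7)
    return generate_trial(cfg)


@pytest.fixture(scope="session")
def noisy_trial():
    """Default-noise simulated trial with ground truth."""
    cfg = SimConfig(technique="double_pole", skill="advanced", n_cycles=10, seed=21)
    return generate_trial(cfg)
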
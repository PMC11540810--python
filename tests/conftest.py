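import numpy as np
import pytest
from hypothesis import settings

import thumbrom.synthetic_hand as sh
from thumbrom import HandLandmarkFrame, LandmarkDataset

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_frame(rng, frame_id=0, labeled=True, scale=200.0, offset=400.0):
    """A geometrically generic labeled frame (no special alignments)."""
    pts = offset + scale * rng.random((21, 2))
    return HandLandmarkFrame(
        frame_id=frame_id, points=pts,
        true_angle_deg=float(rng.uniform(0, 180)) if labeled else None,
        view_azimuth_deg=0.0, subject_id=f"S{frame_id % 3:02d}")


@pytest.fixture()
def small_dataset(rng):
    return LandmarkDataset([random_frame(rng, i) for i in range(6)],
                           metadata={"origin": "unit-test"})


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Deterministic zero-noise, bias-free frontal simulation."""
    cfg = sh.SimConfig(seed=7, n_subjects=6, frames_per_angle=20,
                       noise=sh.NoiseModel(sigma_px=0.0), detector_bias=None)
    return sh.generate_dataset(cfg)
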
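import numpy as np
import pytest

import gonipose as gp


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_noisy_table():
    """Small default-noise dataset: 4 subjects x 6 yaws x 16 angles x 2 frames."""
    cfg = gp.DatasetConfig(master_seed=11, n_subjects=4, frames_per_condition=2)
    return gp.features_table(gp.generate_dataset(cfg))


@pytest.fixture()
def tpose_frame():
    """Fronto-parallel T-pose-like frame: right arm horizontal (90 degrees)."""
    return gp.frame_from_points(
        {
            "right_shoulder": (-0.10, -0.30, 0.0),
            "left_shoulder": (0.10, -0.30, 0.0),
            "right_elbow": (-0.25, -0.30, 0.0),
            "left_elbow": (0.10, -0.15, 0.0),
            "right_hip": (-0.07, 0.0, 0.0),
            "left_hip": (0.07, 0.0, 0.0),
            "nose": (0.0, -0.45, -0.05),
            "right_ear": (-0.06, -0.47, 0.0),
            "left_ear": (0.06, -0.47, 0.0),
        },
        subject_id="T",
        true_abduction_deg=90.0,
    )
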
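"""Simulate a small labeled recording and turn it into geometric features.

Builds 2 synthetic subjects performing right-shoulder abduction (10-160
degrees) filmed from three camera yaws, then prints a few feature rows.
The planar abduction reading tracks the true angle closely at the frontal
camera and drifts at oblique yaws — the problem the two-stage model solves.
"""

import gonipose as gp

config = gp.DatasetConfig(
    n_subjects=2,
    camera_yaws_deg=(-30.0, 0.0, 45.0),
    frames_per_condition=1,
    master_seed=7,
)
frames = gp.generate_dataset(config)
table = gp.features_table(frames)
print(f"{len(table)} frames, {len(gp.FEATURE_NAMES)} features per frame\n")

cols = ["camera_yaw_deg", "true_abduction_deg", "rtshoulderAbduction", "rtshoulder_3Dabduction"]
sample = table[(table.subject_id == "S00") & table.true_abduction_deg.isin([30.0, 90.0, 150.0])]
print(sample[cols].to_string(index=False, float_format=lambda v: f"{v:8.2f}"))
print(
    "\nAt yaw 0 the planar reading (rtshoulderAbduction) matches the true angle;"
    "\nat -30/+45 degrees foreshortening biases it by several degrees."
)
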
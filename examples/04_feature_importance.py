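"""Which geometric parameters drive the abduction estimate?

Computes feature-angle Pearson correlations (the exploratory-analysis view)
and permutation importances of the trained any-camera abduction model (the
model's view): shuffling a feature column and measuring the r2 drop.
"""

import gonipose as gp
from gonipose.features import CAM_ANGLE_FEATURE, STAGE2_FEATURES

config = gp.DatasetConfig(n_subjects=4, frames_per_condition=4, master_seed=7)
table = gp.features_table(gp.generate_dataset(config))

corr = gp.feature_target_correlations(
    table, "true_abduction_deg", features=list(gp.FEATURE_NAMES)
)
print("Pearson correlation with the true abduction angle (selected features):")
for name in ("rtshoulderAbduction", "rtshoulder_3Dabduction", "rtelbowhip_distratio",
             "rtarm_distratio", "rtshoulder_distratio", "rthip_distratio"):
    print(f"  {name:24s} {corr[name]:+.3f}")

pipeline, _ = gp.train_two_stage(table, gp.RegressorSpec(seed=7), gp.SplitSpec(seed=7))
_, test = gp.split_dataset(table, gp.SplitSpec(seed=7))
test = test.copy()
test[CAM_ANGLE_FEATURE] = pipeline.camera_model.predict(test[list(STAGE2_FEATURES)])
importances = gp.permutation_importance(
    pipeline.abduction_model,
    test[list(pipeline.abduction_features)],
    test["true_abduction_deg"],
    n_repeats=10,
    seed=7,
)
print("\npermutation importance (mean r2 drop +- sd over 10 shuffles):")
for name, (mean, sd) in sorted(importances.items(), key=lambda kv: -kv[1][0]):
    print(f"  {name:24s} {mean:+.4f} +- {sd:.4f}")
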
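"""Regression pipeline: fixed-camera models, camera-yaw model, two-stage estimator.

The workflow has three model families:

1. *Fixed-camera abduction models* — one regressor per camera yaw, trained
   only on that yaw's frames, mapping right-arm geometry to the abduction
   angle.
2. *Camera installation-position model* — a regressor from trunk/face
   geometry (which reflects body orientation rather than arm pose) to the
   camera yaw in degrees.  Scored by MAE: MAPE is undefined across the 0-yaw
   condition.
3. *Two-stage any-camera estimator* — the camera model's prediction is
   appended to every row as ``estimate_camAngle`` and an abduction regressor
   is trained on top, making the final estimate camera-placement invariant.

Regressors are pluggable: ordinary least squares or gradient-boosted trees
(LightGBM), both deterministic given their seed.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigError,
    InsufficientDataError,
    SchemaMismatchError,
    ValidationError,
)
from .evaluate import EvalReport, score
from .features import (
    CAM_ANGLE_FEATURE,
    STAGE1_FEATURES,
    STAGE2_FEATURES,
    features_table,
    stage3_features,
)

__all__ = [
    "RegressorSpec",
    "SplitSpec",
    "FittedRegressor",
    "TwoStagePipeline",
    "split_dataset",
    "train_regressor",
    "train_fixed_camera_models",
    "train_camera_model",
    "train_two_stage",
    "predict_abduction",
]

LINEAR = "linear"
TREES = "gbdt"

_DEFAULT_TREE_PARAMS = {
    "n_estimators": 500,
    "learning_rate": 0.05,
    "num_leaves": 31,
    "min_child_samples": 20,
}


@dataclass(frozen=True)
class RegressorSpec:
    """Which regressor family to fit, with its hyperparameters."""

    family: str = TREES
    hyperparameters: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.family not in (LINEAR, TREES):
            raise ConfigError(f"unknown regressor family {self.family!r}")
        unknown = set(self.hyperparameters) - set(_DEFAULT_TREE_PARAMS)
        if self.family == TREES and unknown:
            raise ConfigError(f"unknown tree hyperparameters: {sorted(unknown)}")
        if self.family == LINEAR and self.hyperparameters:
            raise ConfigError("linear family takes no hyperparameters")
        for k in ("n_estimators", "num_leaves", "min_child_samples"):
            if k in self.hyperparameters and self.hyperparameters[k] < 1:
                raise ConfigError(f"{k} must be positive")

    def tree_params(self) -> dict:
        params = dict(_DEFAULT_TREE_PARAMS)
        params.update(self.hyperparameters)
        return params


@dataclass(frozen=True)
class SplitSpec:
    """Train/test partitioning policy."""

    train_fraction: float = 0.8
    mode: str = "frame-random"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigError("train_fraction must lie in (0, 1)")
        if self.mode not in ("frame-random", "subject-grouped"):
            raise ConfigError(f"unknown split mode {self.mode!r}")


def split_dataset(
    rows: pd.DataFrame, spec: SplitSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministically split rows into train/test partitions.

    ``frame-random`` permutes rows; ``subject-grouped`` permutes subjects and
    never splits one subject's frames across partitions.
    """
    n = len(rows)
    if n < 2:
        raise ConfigError("need at least two rows to split")
    rng = np.random.default_rng(spec.seed)
    if spec.mode == "frame-random":
        perm = rng.permutation(n)
        n_train = int(round(spec.train_fraction * n))
        n_train = min(max(n_train, 1), n - 1)
        train_idx, test_idx = np.sort(perm[:n_train]), np.sort(perm[n_train:])
        return rows.iloc[train_idx], rows.iloc[test_idx]
    if "subject_id" not in rows.columns:
        raise ConfigError("subject-grouped split requires a subject_id column")
    subjects = pd.unique(rows["subject_id"])
    if len(subjects) < 2:
        raise ConfigError("subject-grouped split needs at least two subjects")
    perm = rng.permutation(len(subjects))
    n_train_subj = int(round(spec.train_fraction * len(subjects)))
    n_train_subj = min(max(n_train_subj, 1), len(subjects) - 1)
    train_subjects = set(subjects[perm[:n_train_subj]])
    mask = rows["subject_id"].isin(train_subjects).to_numpy()
    return rows[mask], rows[~mask]


class FittedRegressor:
    """A trained regressor bound to the exact feature schema it was fit on."""

    def __init__(self, estimator, features: Sequence[str], spec: RegressorSpec):
        self.estimator = estimator
        self.features = list(features)
        self.spec = spec

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if set(self.features) - set(X.columns):
                raise SchemaMismatchError(self.features, list(X.columns))
            X = X[self.features]
        return np.asarray(self.estimator.predict(X), dtype=float)


def train_regressor(
    X: pd.DataFrame, y, spec: RegressorSpec = RegressorSpec()
) -> FittedRegressor:
    """Fit one regressor of the requested family.

    Linear is an exact (minimum-norm) least-squares fit; trees are LightGBM
    with single-threaded deterministic training so that a seed fully pins the
    model.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
        X.columns = [f"f{i}" for i in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValidationError("X and y row counts differ")
    if X.shape[1] < 1:
        raise ValidationError("need at least one feature")
    values = X.to_numpy(dtype=float)
    if not np.isfinite(values).all() or not np.isfinite(y).all():
        raise ValidationError("non-finite values in training data")

    if spec.family == LINEAR:
        from sklearn.linear_model import LinearRegression

        est = LinearRegression()
        est.fit(X, y)
    else:
        from lightgbm import LGBMRegressor

        params = spec.tree_params()
        est = LGBMRegressor(
            n_estimators=int(params["n_estimators"]),
            learning_rate=float(params["learning_rate"]),
            num_leaves=int(params["num_leaves"]),
            min_child_samples=int(params["min_child_samples"]),
            random_state=spec.seed,
            n_jobs=1,
            deterministic=True,
            force_row_wise=True,
            verbose=-1,
        )
        est.fit(X, y)
    return FittedRegressor(est, list(X.columns), spec)


def _require_labeled(rows: pd.DataFrame, column: str) -> pd.DataFrame:
    if column not in rows.columns:
        raise ValidationError(f"dataset lacks required label column {column!r}")
    labeled = rows[np.isfinite(rows[column].to_numpy(dtype=float))]
    if len(labeled) < 2:
        raise InsufficientDataError(f"fewer than two rows labeled with {column!r}")
    return labeled


def train_fixed_camera_models(
    rows: pd.DataFrame,
    spec: RegressorSpec = RegressorSpec(),
    split: SplitSpec = SplitSpec(),
    min_rows: int = 10,
) -> dict[float, tuple[FittedRegressor, EvalReport]]:
    """Train one abduction model per camera yaw on that yaw's frames only."""
    rows = _require_labeled(rows, "true_abduction_deg")
    rows = _require_labeled(rows, "camera_yaw_deg")
    out: dict[float, tuple[FittedRegressor, EvalReport]] = {}
    for yaw in sorted(pd.unique(rows["camera_yaw_deg"])):
        sub = rows[rows["camera_yaw_deg"] == yaw]
        if len(sub) < min_rows:
            raise InsufficientDataError(
                f"camera yaw {yaw}: only {len(sub)} rows (minimum {min_rows})"
            )
        train, test = split_dataset(sub, split)
        model = train_regressor(
            train[list(STAGE1_FEATURES)], train["true_abduction_deg"], spec
        )
        pred = model.predict(test[list(STAGE1_FEATURES)])
        out[float(yaw)] = (
            model,
            score(test["true_abduction_deg"], pred, mape="auto"),
        )
    return out


def train_camera_model(
    rows: pd.DataFrame,
    spec: RegressorSpec = RegressorSpec(),
    split: SplitSpec = SplitSpec(),
) -> tuple[FittedRegressor, EvalReport]:
    """Train the camera installation-position regressor (trunk/face features -> yaw)."""
    rows = _require_labeled(rows, "camera_yaw_deg")
    train, test = split_dataset(rows, split)
    model = train_regressor(train[list(STAGE2_FEATURES)], train["camera_yaw_deg"], spec)
    pred = model.predict(test[list(STAGE2_FEATURES)])
    # MAE is the headline metric; MAPE is undefined whenever yaw 0 is present.
    report = score(test["camera_yaw_deg"], pred, mape="auto")
    return model, report


@dataclass
class TwoStagePipeline:
    """Trained camera model + abduction model with their feature schemas."""

    camera_model: FittedRegressor
    abduction_model: FittedRegressor
    camera_features: tuple[str, ...]
    abduction_features: tuple[str, ...]
    metadata: dict

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        """Predict abduction degrees for feature rows (clipped to [0, 180])."""
        missing = set(self.camera_features) - set(rows.columns)
        if missing:
            raise SchemaMismatchError(self.camera_features, list(rows.columns))
        augmented = rows.copy()
        augmented[CAM_ANGLE_FEATURE] = self.camera_model.predict(
            rows[list(self.camera_features)]
        )
        missing = set(self.abduction_features) - set(augmented.columns)
        if missing:
            raise SchemaMismatchError(self.abduction_features, list(augmented.columns))
        pred = self.abduction_model.predict(augmented[list(self.abduction_features)])
        return np.clip(pred, 0.0, 180.0)


def _fingerprint(rows: pd.DataFrame) -> str:
    digest = hashlib.sha256()
    digest.update(pd.util.hash_pandas_object(rows, index=False).to_numpy().tobytes())
    return digest.hexdigest()[:16]


def train_two_stage(
    rows: pd.DataFrame,
    spec: RegressorSpec = RegressorSpec(),
    split: SplitSpec = SplitSpec(),
    feature_mode: str = "table1",
) -> tuple[TwoStagePipeline, EvalReport]:
    """Train the any-camera two-stage abduction estimator.

    The data are split once; the camera model is fit on the training
    partition only, its predictions fill ``estimate_camAngle`` for both
    partitions, and the abduction model is fit on the augmented training
    rows.  The report is computed on held-out rows never seen by either
    stage.
    """
    rows = _require_labeled(rows, "true_abduction_deg")
    rows = _require_labeled(rows, "camera_yaw_deg")
    if rows["camera_yaw_deg"].nunique() < 2:
        raise InsufficientDataError("two-stage training needs at least two camera yaws")
    train, test = split_dataset(rows, split)

    camera_model = train_regressor(
        train[list(STAGE2_FEATURES)], train["camera_yaw_deg"], spec
    )
    stage3 = stage3_features(feature_mode)
    train_aug = train.copy()
    train_aug[CAM_ANGLE_FEATURE] = camera_model.predict(train[list(STAGE2_FEATURES)])
    test_aug = test.copy()
    test_aug[CAM_ANGLE_FEATURE] = camera_model.predict(test[list(STAGE2_FEATURES)])

    abduction_model = train_regressor(
        train_aug[list(stage3)], train_aug["true_abduction_deg"], spec
    )
    pipeline = TwoStagePipeline(
        camera_model=camera_model,
        abduction_model=abduction_model,
        camera_features=tuple(STAGE2_FEATURES),
        abduction_features=tuple(stage3),
        metadata={
            "regressor": {"family": spec.family, "hyperparameters": dict(spec.hyperparameters), "seed": spec.seed},
            "split": {"train_fraction": split.train_fraction, "mode": split.mode, "seed": split.seed},
            "feature_mode": feature_mode,
            "train_fingerprint": _fingerprint(train),
            "train_subjects": sorted(map(str, pd.unique(train["subject_id"])))
            if "subject_id" in train.columns
            else [],
            "n_train": int(len(train)),
            "n_test": int(len(test)),
            "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
        },
    )
    pred = np.clip(
        abduction_model.predict(test_aug[list(stage3)]), 0.0, 180.0
    )
    report = score(test["true_abduction_deg"], pred, mape="auto")
    return pipeline, report


def predict_abduction(pipeline: TwoStagePipeline, frames) -> np.ndarray:
    """Predict abduction for landmark frames (or an existing feature table)."""
    if isinstance(frames, pd.DataFrame):
        table = frames
    else:
        table = features_table(frames)
    return pipeline.predict(table)
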
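"""CSV dialects, model-bundle persistence, and the structured run config.

Landmark CSV (long form): one row per (frame, keypoint) with columns
``subject_id, frame_index, keypoint, x, y, z`` plus optional
``true_abduction_deg`` and ``camera_yaw_deg``; UTF-8, header required.

Feature CSV (wide form): one row per frame, as produced by
:func:`gonipose.features.features_table`; angle-valued columns are written
with six decimals (degree convention), everything else at full precision.

A model bundle is a directory holding a JSON manifest (schemas, seeds, data
fingerprint) plus the two serialized stage models.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable

import joblib
import numpy as np
import pandas as pd
import yaml

from .errors import BundleError, ConfigError, ParseError
from .features import ANGLE_FEATURES, FEATURE_NAMES, LABEL_COLUMNS, META_COLUMNS
from .landmarks import REQUIRED_KEYPOINTS, Landmark, LandmarkFrame
from .models import (
    FittedRegressor,
    RegressorSpec,
    SplitSpec,
    TwoStagePipeline,
)
from .simulate import CameraSpec, DatasetConfig, NoiseSpec

__all__ = [
    "read_landmarks",
    "write_landmarks",
    "read_features",
    "write_features",
    "save_bundle",
    "load_bundle",
    "RunConfig",
    "load_run_config",
]

LANDMARK_COLUMNS = ("subject_id", "frame_index", "keypoint", "x", "y", "z")
BUNDLE_VERSION = 1


# ---------------------------------------------------------------------------
# Landmark CSV


def write_landmarks(frames: Iterable[LandmarkFrame], path) -> None:
    """Write frames to the long-form landmark CSV dialect."""
    records = []
    for frame in frames:
        for name, lm in frame.landmarks.items():
            rec = {
                "subject_id": frame.subject_id,
                "frame_index": frame.frame_index,
                "keypoint": name,
                "x": repr(lm.x),
                "y": repr(lm.y),
                "z": repr(lm.z),
            }
            if frame.true_abduction_deg is not None:
                rec["true_abduction_deg"] = f"{frame.true_abduction_deg:.6f}"
            if frame.camera_yaw_deg is not None:
                rec["camera_yaw_deg"] = f"{frame.camera_yaw_deg:.6f}"
            records.append(rec)
    df = pd.DataFrame.from_records(records)
    df.to_csv(path, index=False)


def read_landmarks(path) -> list[LandmarkFrame]:
    """Read the long-form landmark CSV back into frames.

    Frames are grouped by (subject_id, frame_index) in order of first
    appearance; every frame must contain the required keypoint subset.
    Parse failures name the offending line (1-based, counting the header).
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        # round_trip float parsing: repr-precision coordinates survive exactly
        df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ParseError("file is empty (expected at least a header)") from None
    missing = [c for c in LANDMARK_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing required column(s): {missing}", line=1)
    if df.empty:
        return []

    for col in ("x", "y", "z", "frame_index"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(coerced.isna().to_numpy() & df[col].notna().to_numpy())
        nan_bad = np.flatnonzero(df[col].isna().to_numpy())
        if nan_bad.size:
            raise ParseError(f"empty value in column {col!r}", line=int(nan_bad[0]) + 2)
        if bad.size:
            raise ParseError(
                f"non-numeric value {df[col].iloc[bad[0]]!r} in column {col!r}",
                line=int(bad[0]) + 2,
            )
        df[col] = coerced
    for col in ("true_abduction_deg", "camera_yaw_deg"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")

    frames: list[LandmarkFrame] = []
    for (subject_id, frame_index), group in df.groupby(
        ["subject_id", "frame_index"], sort=False
    ):
        lms = {}
        for _, row in group.iterrows():
            kp = str(row["keypoint"])
            lms[kp] = Landmark(kp, float(row["x"]), float(row["y"]), float(row["z"]))
        for kp in REQUIRED_KEYPOINTS:
            if kp not in lms:
                first_line = int(group.index[0]) + 2
                raise ParseError(
                    f"frame ({subject_id!r}, {int(frame_index)}) lacks required "
                    f"keypoint {kp!r}",
                    line=first_line,
                )
        label = group["true_abduction_deg"].iloc[0] if "true_abduction_deg" in group else np.nan
        yaw = group["camera_yaw_deg"].iloc[0] if "camera_yaw_deg" in group else np.nan
        frames.append(
            LandmarkFrame(
                landmarks=lms,
                subject_id=str(subject_id),
                frame_index=int(frame_index),
                true_abduction_deg=None if pd.isna(label) else float(label),
                camera_yaw_deg=None if pd.isna(yaw) else float(yaw),
            )
        )
    return frames


# ---------------------------------------------------------------------------
# Feature CSV


def write_features(table: pd.DataFrame, path) -> None:
    """Write a feature table; angle-valued columns rounded to 6 decimals."""
    out = table.copy()
    angle_cols = [c for c in out.columns if c in ANGLE_FEATURES or c in LABEL_COLUMNS or c == "estimate_camAngle"]
    for col in angle_cols:
        out[col] = out[col].round(6)
    out.to_csv(path, index=False)


def read_features(path) -> pd.DataFrame:
    """Read a feature CSV, checking the fixed column set is present."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in list(META_COLUMNS) + list(FEATURE_NAMES) if c not in df.columns]
    if missing:
        raise ParseError(f"feature CSV missing column(s): {missing}", line=1)
    return df


# ---------------------------------------------------------------------------
# Model bundle


def save_bundle(pipeline: TwoStagePipeline, directory) -> None:
    """Persist a two-stage pipeline as manifest + per-stage model files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "bundle_version": BUNDLE_VERSION,
        "camera_features": list(pipeline.camera_features),
        "abduction_features": list(pipeline.abduction_features),
        "metadata": pipeline.metadata,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    joblib.dump(pipeline.camera_model, directory / "camera_model.joblib")
    joblib.dump(pipeline.abduction_model, directory / "abduction_model.joblib")


def load_bundle(directory) -> TwoStagePipeline:
    """Load a bundle, verifying version and feature-schema integrity."""
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise BundleError(f"no manifest.json in {directory}")
    manifest = json.loads(manifest_path.read_text())
    version = manifest.get("bundle_version")
    if version != BUNDLE_VERSION:
        raise BundleError(
            f"bundle version {version!r} not supported (expected {BUNDLE_VERSION})"
        )
    camera_model: FittedRegressor = joblib.load(directory / "camera_model.joblib")
    abduction_model: FittedRegressor = joblib.load(directory / "abduction_model.joblib")
    for label, model, declared in (
        ("camera", camera_model, manifest["camera_features"]),
        ("abduction", abduction_model, manifest["abduction_features"]),
    ):
        if list(model.features) != list(declared):
            raise BundleError(
                f"{label} model feature schema differs from manifest: "
                f"model={model.features} manifest={declared}"
            )
    return TwoStagePipeline(
        camera_model=camera_model,
        abduction_model=abduction_model,
        camera_features=tuple(manifest["camera_features"]),
        abduction_features=tuple(manifest["abduction_features"]),
        metadata=manifest["metadata"],
    )


# ---------------------------------------------------------------------------
# Run config


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Validated configuration for a full simulate/train/evaluate run."""

    dataset: DatasetConfig = dataclasses.field(default_factory=DatasetConfig)
    split: SplitSpec = dataclasses.field(default_factory=SplitSpec)
    regressor: RegressorSpec = dataclasses.field(default_factory=RegressorSpec)
    stage3_feature_mode: str = "table1"
    output_dir: str = "gonipose_out"
    log_level: str = "INFO"

    def __post_init__(self):
        if self.stage3_feature_mode not in ("table1", "all-bilateral"):
            raise ConfigError(
                f"unknown stage3_feature_mode {self.stage3_feature_mode!r}"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build(cls, data: dict, context: str):
    """Instantiate a (frozen) dataclass from a mapping, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ConfigError(f"{context}: expected a mapping, got {type(data).__name__}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"{context}: unknown key(s) {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        sub = _NESTED.get((cls, key))
        if sub is not None and isinstance(value, dict):
            value = _build(sub, value, f"{context}.{key}")
        if key in ("camera_yaws_deg", "abduction_grid_deg") and isinstance(value, list):
            value = tuple(float(v) for v in value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{context}: {exc}") from exc


_NESTED = {
    (RunConfig, "dataset"): DatasetConfig,
    (RunConfig, "split"): SplitSpec,
    (RunConfig, "regressor"): RegressorSpec,
    (DatasetConfig, "noise"): NoiseSpec,
    (DatasetConfig, "camera"): CameraSpec,
}


def load_run_config(path=None, text: str | None = None) -> RunConfig:
    """Load and validate a YAML run config (unknown keys are rejected by name)."""
    if text is None:
        text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return _build(RunConfig, data, "config")
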
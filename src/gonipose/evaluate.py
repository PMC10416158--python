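"""Regression metrics, feature-target correlations, permutation importance.

Metrics follow the goniometry-validation conventions: R-squared
(1 - SS_res/SS_tot), MAPE as the mean of absolute percentage errors (reported
in percent; undefined whenever a true value is zero, which is why the camera
model is scored by MAE instead), MAE in degrees, and the Pearson correlation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import MetricUndefinedError, SchemaMismatchError, ValidationError

__all__ = [
    "EvalReport",
    "score",
    "feature_target_correlations",
    "permutation_importance",
]


@dataclass
class EvalReport:
    """Container for a model evaluation on one data partition."""

    r2: float
    mae: float
    pearson_r: float
    n: int
    mape_percent: float | None = None
    per_feature_correlation: dict[str, float | None] | None = None
    importances: dict[str, tuple[float, float]] | None = None
    notes: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return asdict(self)

    def to_text(self) -> str:
        """Flat human-readable key: value report."""
        lines = [
            f"n: {self.n}",
            f"r2: {self.r2:.6f}",
            f"mae: {self.mae:.6f}",
            f"pearson_r: {self.pearson_r:.6f}",
            "mape_percent: "
            + ("undefined" if self.mape_percent is None else f"{self.mape_percent:.6f}"),
        ]
        for note in self.notes:
            lines.append(f"note: {note}")
        if self.per_feature_correlation:
            for k, v in self.per_feature_correlation.items():
                lines.append(
                    f"corr[{k}]: " + ("undefined" if v is None else f"{v:.6f}")
                )
        if self.importances:
            for k, (mean, sd) in self.importances.items():
                lines.append(f"importance[{k}]: {mean:.6f} +- {sd:.6f}")
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _as_arrays(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yt.shape != yp.shape or yt.ndim != 1:
        raise ValidationError("y_true and y_pred must be 1-D arrays of equal length")
    if yt.size < 2:
        raise ValidationError("need at least two observations to score")
    if not (np.isfinite(yt).all() and np.isfinite(yp).all()):
        raise ValidationError("non-finite values in scoring inputs")
    return yt, yp


def score(y_true, y_pred, mape: str = "require") -> EvalReport:
    """Score predictions against ground truth.

    Parameters
    ----------
    mape:
        ``"require"`` raises :class:`MetricUndefinedError` if any true value
        is zero; ``"auto"`` reports MAPE as undefined (with a note) in that
        case; ``"skip"`` never computes it.
    """
    yt, yp = _as_arrays(y_true, y_pred)
    resid = yt - yp
    ss_res = float(resid @ resid)
    centered = yt - yt.mean()
    ss_tot = float(centered @ centered)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -math.inf)
    mae = float(np.abs(resid).mean())
    if yt.std() == 0 or yp.std() == 0:
        pearson = float("nan")
        notes = ("pearson_r undefined: constant input",)
    else:
        pearson = float(np.corrcoef(yt, yp)[0, 1])
        notes = ()

    mape_percent: float | None = None
    if mape not in ("require", "auto", "skip"):
        raise ValidationError(f"unknown mape mode {mape!r}")
    if mape != "skip":
        if np.any(yt == 0):
            if mape == "require":
                raise MetricUndefinedError(
                    "MAPE undefined: ground truth contains zero values"
                )
            notes = notes + ("MAPE undefined: ground truth contains zero values",)
        else:
            mape_percent = float(np.mean(np.abs(resid) / np.abs(yt)) * 100.0)
    return EvalReport(
        r2=r2, mae=mae, pearson_r=pearson, n=int(yt.size),
        mape_percent=mape_percent, notes=notes,
    )


def feature_target_correlations(
    table: pd.DataFrame,
    target: str | Sequence[float],
    features: Sequence[str] | None = None,
) -> dict[str, float | None]:
    """Pearson correlation of each feature column with the target.

    Constant columns are reported as ``None`` (undefined) rather than NaN so
    downstream consumers must handle them explicitly.
    """
    if isinstance(target, str):
        y = table[target].to_numpy(dtype=float)
        default_feats = [c for c in table.columns if c != target]
    else:
        y = np.asarray(target, dtype=float)
        default_feats = list(table.columns)
    if len(table) < 3:
        raise ValidationError("need at least three rows for correlations")
    feats = list(features) if features is not None else [
        c for c in default_feats if pd.api.types.is_numeric_dtype(table[c])
    ]
    y_sd = y.std()
    out: dict[str, float | None] = {}
    for name in feats:
        x = table[name].to_numpy(dtype=float)
        if x.std() == 0 or y_sd == 0:
            out[name] = None
        else:
            out[name] = float(np.corrcoef(x, y)[0, 1])
    return out


def correlation_matrix(table: pd.DataFrame, columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Heatmap-ready Pearson correlation matrix over feature columns."""
    cols = list(columns) if columns is not None else [
        c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])
    ]
    return table[cols].corr(method="pearson")


def save_correlation_heatmap(matrix: pd.DataFrame, path) -> None:
    """Render a correlation matrix as a heatmap image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(0.45 * len(matrix.columns) + 2,) * 2)
    im = ax.imshow(matrix.to_numpy(), vmin=-1, vmax=1, cmap="coolwarm")
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(matrix.index)), matrix.index, fontsize=7)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _metric_value(metric: str, y_true: np.ndarray, y_pred: np.ndarray) -> float:
    if metric == "r2":
        rep = score(y_true, y_pred, mape="skip")
        return rep.r2
    if metric == "mae":
        return float(np.abs(np.asarray(y_true) - np.asarray(y_pred)).mean())
    raise ValidationError(f"unknown importance metric {metric!r}")


def permutation_importance(
    model,
    X: pd.DataFrame,
    y,
    metric: str = "r2",
    n_repeats: int = 10,
    seed: int = 0,
) -> dict[str, tuple[float, float]]:
    """Permutation feature importance: score drop when one column is shuffled.

    For each feature, the column is independently re-permuted ``n_repeats``
    times (all other columns untouched) and the drop relative to the baseline
    score is recorded; returns feature -> (mean drop, sd over repeats).
    For the MAE metric the drop is the *increase* in error, so that larger
    is always more important.
    """
    if n_repeats < 1:
        raise ValidationError("n_repeats must be >= 1")
    features = list(X.columns)
    missing = [f for f in features if f not in X.columns]
    if missing:
        raise SchemaMismatchError(features, list(X.columns))
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    baseline = _metric_value(metric, y, np.asarray(model.predict(X), dtype=float))
    sign = 1.0 if metric == "r2" else -1.0
    out: dict[str, tuple[float, float]] = {}
    for name in features:
        drops = np.empty(n_repeats)
        for rep in range(n_repeats):
            shuffled = X.copy()
            shuffled[name] = rng.permutation(shuffled[name].to_numpy())
            permuted_score = _metric_value(
                metric, y, np.asarray(model.predict(shuffled), dtype=float)
            )
            drops[rep] = sign * (baseline - permuted_score)
        out[name] = (float(drops.mean()), float(drops.std(ddof=1) if n_repeats > 1 else 0.0))
    return out
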
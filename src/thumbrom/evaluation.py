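"""Accuracy metrics and residual diagnostics for predicted angles."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score

from .errors import UndefinedStatisticError, ValidationError


@dataclass(frozen=True)
class Metrics:
    """RMSE/MAE in degrees; R^2 (1 - SSres/SStot, evaluation-set form, may
    be negative); Pearson correlation coefficient; sample count."""

    rmse: float
    mae: float
    r2: float
    cc: float
    n: int

    def as_dict(self) -> dict:
        return {"rmse": self.rmse, "mae": self.mae, "r2": self.r2,
                "cc": self.cc, "n": self.n}


def _check_pair(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.ndim != 1 or y_pred.ndim != 1:
        raise ValidationError("label sequences must be one-dimensional")
    if len(y_true) != len(y_pred):
        raise ValidationError(
            f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted")
    if len(y_true) < 2:
        raise ValidationError("need at least 2 observations")
    if not (np.all(np.isfinite(y_true)) and np.all(np.isfinite(y_pred))):
        raise ValidationError("non-finite value in label sequence")
    return y_true, y_pred


def metrics(y_true, y_pred) -> Metrics:
    """RMSE, MAE, R^2 and Pearson CC for a (true, predicted) pair.

    R^2 and CC require positive variance in ``y_true``; for constant truth
    an :class:`UndefinedStatisticError` is raised that still carries the
    computed ``rmse`` and ``mae`` attributes.
    """
    y_true, y_pred = _check_pair(y_true, y_pred)
    rmse = float(np.sqrt(mean_squared_error(y_true, y_pred)))
    mae = float(mean_absolute_error(y_true, y_pred))
    if np.var(y_true) == 0.0:
        raise UndefinedStatisticError(
            "y_true has zero variance: CC and R^2 are undefined "
            "(rmse/mae attached to this error)", rmse=rmse, mae=mae)
    r2 = float(r2_score(y_true, y_pred))
    if np.var(y_pred) == 0.0:
        # Pearson CC undefined for a constant prediction; report 0 linear
        # association rather than raising (truth still varies).
        cc = 0.0
    else:
        cc = float(np.corrcoef(y_true, y_pred)[0, 1])
    return Metrics(rmse=rmse, mae=mae, r2=r2, cc=cc, n=len(y_true))


@dataclass
class ResidualTable:
    """Residual-plot data: truth on x, (actual - predicted) on y."""

    frame: pd.DataFrame  # columns true_angle_deg, residual_deg
    mean_residual: float


def residual_table(y_true, y_pred) -> ResidualTable:
    """Residuals ``actual - predicted`` against the true angle."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_true) != len(y_pred):
        raise ValidationError(
            f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted")
    resid = y_true - y_pred
    frame = pd.DataFrame({"true_angle_deg": y_true, "residual_deg": resid})
    return ResidualTable(frame=frame, mean_residual=float(resid.mean()))


def residual_plot(table: ResidualTable, path, title: str = "") -> None:
    """Write a residual scatter plot (truth vs actual - predicted) to path."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(table.frame["true_angle_deg"], table.frame["residual_deg"],
               s=6, alpha=0.4)
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xlabel("true angle (deg)")
    ax.set_ylabel("residual: actual - predicted (deg)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
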
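"""Model explainability: permutation importance, exact Shapley values,
SHAP-style summaries and the feature/label correlation matrix.

With only seven features, Shapley attributions are computed *exactly* by
enumerating all 2^7 = 128 feature coalitions — no sampling approximation.
The coalition value function is the marginal (interventional) expectation:
``v(S)`` is the mean model prediction over a background sample with the
features in S taken from the instance being explained and the remaining
features from the background row.  Under this value function a linear model
``f(x) = b + sum_j w_j x_j`` has the closed form
``phi_j = w_j (x_j - mean background_j)``, which the test-suite uses as an
oracle.  Efficiency — base value plus attributions equals the model's
prediction — holds by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.inspection import permutation_importance as _sk_permutation_importance

from .errors import SchemaError, UndefinedStatisticError, ValidationError
from .features import FEATURE_NAMES
from .models import TrainedModel
from .models import predict as model_predict

_METRIC_TO_SCORING = {"r2": "r2", "neg_rmse": "neg_root_mean_squared_error"}


@dataclass
class ImportanceTable:
    """Permutation importances: mean score drop (and its spread) per feature."""

    table: pd.DataFrame  # columns feature, importance, dispersion
    metric: str
    n_repeats: int
    seed: int


def permutation_importance(model: TrainedModel, features, labels,
                           metric: str = "r2", n_repeats: int = 10,
                           seed: int = 0) -> ImportanceTable:
    """Score drop when one feature column is randomly shuffled.

    ``importance_f`` = baseline score minus the mean score over
    ``n_repeats`` shuffles of column f; ``dispersion`` is the standard
    deviation over repeats.  Metrics: ``r2`` or ``neg_rmse``.
    """
    if metric not in _METRIC_TO_SCORING:
        raise ValidationError(f"unknown importance metric {metric!r}")
    if n_repeats < 1:
        raise ValidationError("n_repeats must be >= 1")
    X = _feature_matrix(features, model.feature_names)
    y = np.asarray(labels, dtype=float)
    if len(y) != len(X):
        raise SchemaError("labels do not match the feature rows")
    result = _sk_permutation_importance(
        model.estimator, pd.DataFrame(X, columns=list(model.feature_names)),
        y, scoring=_METRIC_TO_SCORING[metric],
        n_repeats=n_repeats, random_state=seed)
    table = pd.DataFrame({
        "feature": list(model.feature_names),
        "importance": result.importances_mean,
        "dispersion": result.importances_std,
    })
    return ImportanceTable(table=table, metric=metric,
                           n_repeats=n_repeats, seed=seed)


@dataclass
class ShapVector:
    """Exact Shapley attribution of one prediction.

    ``base_value + phi.sum()`` equals the model's prediction on the
    instance (efficiency axiom), up to floating-point error.
    """

    phi: pd.Series          # indexed by feature name, degrees
    base_value: float       # mean prediction over the background
    prediction: float

    def as_dict(self) -> dict:
        return {"phi": self.phi.to_dict(), "base_value": self.base_value,
                "prediction": self.prediction}


@dataclass
class ShapSummary:
    phi: pd.DataFrame       # one row per explained instance
    base_value: float
    ranking: pd.DataFrame   # feature, mean_abs_phi; sorted descending


def _feature_matrix(features, feature_names: Sequence[str]) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        missing = [c for c in feature_names if c not in features.columns]
        if missing:
            raise SchemaError(f"feature table is missing columns {missing}")
        return features.loc[:, list(feature_names)].to_numpy(dtype=float)
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    if X.shape[1] != len(feature_names):
        raise SchemaError(
            f"expected {len(feature_names)} feature columns, got {X.shape[1]}")
    return X


def _resolve_predict(model) -> tuple[Callable[[np.ndarray], np.ndarray], list[str] | None]:
    if isinstance(model, TrainedModel):
        return (lambda X: model_predict(model, X)), list(model.feature_names)
    if callable(model):
        return (lambda X: np.asarray(model(X), dtype=float)), None
    raise ValidationError("model must be a TrainedModel or a callable")


def _shapley_weights(k: int) -> np.ndarray:
    # w[s] = s! (k - s - 1)! / k!  for a coalition of size s not containing f
    return np.array([math.factorial(s) * math.factorial(k - s - 1) / math.factorial(k)
                     for s in range(k)])


def _coalition_values(predict_fn, instances: np.ndarray,
                      background: np.ndarray) -> dict[frozenset, np.ndarray]:
    """v(S) for every coalition S, for each instance row.

    For coalition S the prediction input takes the columns in S from the
    instance and the rest from each background row; v(S) is the mean over
    the background.  Predictions are batched per coalition.
    """
    m, k = instances.shape
    n = len(background)
    values: dict[frozenset, np.ndarray] = {}
    tiled_bg = np.tile(background, (m, 1))
    for size in range(k + 1):
        for subset in combinations(range(k), size):
            X = tiled_bg.copy()
            if subset:
                cols = list(subset)
                repl = np.repeat(instances[:, cols], n, axis=0)
                X[:, cols] = repl
            preds = predict_fn(X).reshape(m, n)
            values[frozenset(subset)] = preds.mean(axis=1)
    return values


def _phi_from_values(values: dict[frozenset, np.ndarray], k: int,
                     m: int) -> np.ndarray:
    w = _shapley_weights(k)
    phi = np.zeros((m, k))
    for f in range(k):
        others = [j for j in range(k) if j != f]
        for size in range(k):
            for subset in combinations(others, size):
                S = frozenset(subset)
                phi[:, f] += w[size] * (values[S | {f}] - values[S])
    return phi


def exact_shapley(model, instance, background,
                  feature_names: Sequence[str] | None = None) -> ShapVector:
    """Exact Shapley attribution of one instance by coalition enumeration.

    ``model`` is a :class:`~thumbrom.models.TrainedModel` or any callable
    mapping an (n, k) array to n predictions; ``background`` is a non-empty
    table of reference rows defining the marginal expectation.
    """
    predict_fn, names = _resolve_predict(model)
    if feature_names is not None:
        names = list(feature_names)
    if isinstance(instance, pd.Series):
        instance = instance.to_frame().T
    if hasattr(instance, "as_array"):  # FeatureVector
        instance = instance.as_array()
    bg = _feature_matrix(background, names) if names is not None \
        else np.asarray(background, dtype=float)
    if len(bg) == 0:
        raise ValidationError("background must be non-empty")
    if names is None:
        names = [f"f{i}" for i in range(bg.shape[1])]
    inst = _feature_matrix(instance, names)
    if len(inst) != 1:
        raise ValidationError("exact_shapley explains one instance at a time")
    values = _coalition_values(predict_fn, inst, bg)
    phi = _phi_from_values(values, len(names), 1)[0]
    base = float(values[frozenset()][0])
    prediction = float(values[frozenset(range(len(names)))][0])
    return ShapVector(phi=pd.Series(phi, index=names), base_value=base,
                      prediction=prediction)


def shap_summary(model, features, background,
                 feature_names: Sequence[str] | None = None) -> ShapSummary:
    """Exact Shapley attributions for a table of instances, plus a ranking.

    The ranking orders features by mean absolute attribution, descending;
    ties break by feature-name lexicographic order.
    """
    predict_fn, names = _resolve_predict(model)
    if feature_names is not None:
        names = list(feature_names)
    bg = _feature_matrix(background, names) if names is not None \
        else np.asarray(background, dtype=float)
    if len(bg) == 0:
        raise ValidationError("background must be non-empty")
    if names is None:
        names = [f"f{i}" for i in range(bg.shape[1])]
    inst = _feature_matrix(features, names)
    values = _coalition_values(predict_fn, inst, bg)
    phi = _phi_from_values(values, len(names), len(inst))
    phi_df = pd.DataFrame(phi, columns=names)
    mean_abs = phi_df.abs().mean(axis=0)
    ranking = (pd.DataFrame({"feature": names, "mean_abs_phi": mean_abs.values})
               .sort_values(["mean_abs_phi", "feature"],
                            ascending=[False, True], kind="mergesort")
               .reset_index(drop=True))
    base = float(values[frozenset()].mean())
    return ShapSummary(phi=phi_df, base_value=base, ranking=ranking)


def correlation_matrix(feature_table: pd.DataFrame,
                       columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Pearson correlations over the seven features plus the true angle.

    Symmetric with a unit diagonal; raises
    :class:`UndefinedStatisticError` naming any zero-variance column.
    """
    if columns is None:
        columns = [c for c in FEATURE_NAMES if c in feature_table.columns]
        if "true_angle_deg" in feature_table.columns:
            columns = columns + ["true_angle_deg"]
    missing = [c for c in columns if c not in feature_table.columns]
    if missing:
        raise SchemaError(f"feature table is missing columns {missing}")
    sub = feature_table.loc[:, list(columns)].astype(float)
    if len(sub) < 3:
        raise ValidationError("need at least 3 rows for a correlation matrix")
    variances = sub.var(ddof=0)
    dead = variances[variances == 0.0].index.tolist()
    if dead:
        raise UndefinedStatisticError(
            f"zero-variance column(s) {dead}: correlation undefined")
    corr = sub.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


def correlation_heatmap(corr: pd.DataFrame, path, title: str = "") -> None:
    """Write a correlation heatmap image to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(corr.values, vmin=-1, vmax=1, cmap="coolwarm")
    ax.set_xticks(range(len(corr.columns)))
    ax.set_xticklabels(corr.columns, rotation=60, ha="right", fontsize=8)
    ax.set_yticks(range(len(corr.index)))
    ax.set_yticklabels(corr.index, fontsize=8)
    fig.colorbar(im, ax=ax, label="Pearson r")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
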
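"""The five-regressor suite: specs, split, fit, predict.

Five regression families predict the abduction angle from the seven
geometric features: ordinary least squares, ElasticNet, RBF-kernel support
vector regression, random forest, and gradient-boosted decision trees
(LightGBM).  Hyperparameters default to the published protocol:

* elastic_net: alpha 1.0, l1_ratio 0.5, fit_intercept True
* svm_rbf: C 1.0, gamma "scale" (degree 3 is recorded but inert for RBF)
* random_forest: 100 trees, max_depth 6, squared-error criterion
* gbdt: mean-absolute-error objective, learning_rate 0.01, max_depth 7,
  500 boosting rounds

The linear model is plain OLS: the published option list for it (an L2
penalty with C and an lbfgs solver) describes a classifier interface that
does not apply to least-squares regression, so those options are recorded
in the spec's hyperparameter table but not consumed.

Inputs are standardized (train-set mean/scale) for the SVM only: RBF
kernels with C = 1 are scale-sensitive, while the linear models keep the
features' native units (degrees and dimensionless ratios, already
commensurate) and trees are scale-equivariant.  The flag is per-spec and
can be overridden.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lightgbm import LGBMRegressor
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNet, LinearRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .errors import SchemaError, ValidationError
from .features import FEATURE_NAMES, feature_table
from .landmarks_io import LandmarkDataset

MODEL_NAMES = ["linear_regression", "elastic_net", "svm_rbf", "random_forest", "gbdt"]

DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "linear_regression": {},
    "elastic_net": {"alpha": 1.0, "fit_intercept": True, "l1_ratio": 0.5,
                    "max_iter": 10_000},
    "svm_rbf": {"C": 1.0, "degree": 3, "gamma": "scale"},
    "random_forest": {"max_depth": 6, "criterion": "squared_error",
                      "n_estimators": 100},
    "gbdt": {"objective": "regression_l1", "learning_rate": 0.01,
             "max_depth": 7, "n_estimators": 500},
}

_DEFAULT_STANDARDIZE = {
    "linear_regression": False,
    "elastic_net": False,
    "svm_rbf": True,
    "random_forest": False,
    "gbdt": False,
}


@dataclass
class ModelSpec:
    """One regressor family plus its hyperparameters and preprocessing."""

    name: str
    hyperparameters: dict = field(default_factory=dict)
    standardize_inputs: bool | None = None

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValidationError(
                f"unknown model {self.name!r}; choose one of {MODEL_NAMES}")
        merged = copy.deepcopy(DEFAULT_HYPERPARAMETERS[self.name])
        merged.update(self.hyperparameters)
        self.hyperparameters = merged
        if self.standardize_inputs is None:
            self.standardize_inputs = _DEFAULT_STANDARDIZE[self.name]


def default_specs() -> list[ModelSpec]:
    """The five specs with published hyperparameters, in canonical order."""
    return [ModelSpec(name) for name in MODEL_NAMES]


@dataclass
class SplitConfig:
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValidationError("train_fraction must lie in (0, 1)")


def split_dataset(n_rows: int, config: SplitConfig) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint train/test index split.

    ``|train| = round(train_fraction * n_rows)``; the two index arrays are
    disjoint and exhaustive, and identical seeds give identical splits.
    """
    if n_rows < 2:
        raise ValidationError("need at least 2 rows to split")
    n_train = int(round(config.train_fraction * n_rows))
    n_train = min(max(n_train, 1), n_rows - 1)
    perm = np.random.default_rng(config.seed).permutation(n_rows)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def _build_estimator(spec: ModelSpec, seed: int):
    hp = dict(spec.hyperparameters)
    if spec.name == "linear_regression":
        est = LinearRegression()
    elif spec.name == "elastic_net":
        est = ElasticNet(random_state=seed, **hp)
    elif spec.name == "svm_rbf":
        hp.pop("degree", None)  # inert for the RBF kernel; recorded only
        est = SVR(kernel="rbf", **hp)
    elif spec.name == "random_forest":
        est = RandomForestRegressor(random_state=seed, n_jobs=1, **hp)
    elif spec.name == "gbdt":
        est = LGBMRegressor(random_state=seed, n_jobs=1, verbose=-1, **hp)
    else:  # pragma: no cover - guarded by ModelSpec
        raise ValidationError(f"unknown model {spec.name!r}")
    if spec.standardize_inputs:
        return Pipeline([("scale", StandardScaler()), ("model", est)])
    return est


@dataclass
class TrainedModel:
    """A fitted regressor bound to a fixed feature-name order."""

    spec: ModelSpec
    estimator: object
    feature_names: tuple[str, ...]
    seed: int = 0

    @property
    def standardization_params(self) -> pd.DataFrame | None:
        """Per-feature location/scale of the fitted scaler, if any."""
        if isinstance(self.estimator, Pipeline):
            scaler = self.estimator.named_steps["scale"]
            return pd.DataFrame(
                {"location": scaler.mean_, "scale": scaler.scale_},
                index=list(self.feature_names))
        return None

    def predict(self, features) -> np.ndarray:
        return predict(self, features)


def _as_matrix(features, feature_names: Sequence[str]) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        missing = [c for c in feature_names if c not in features.columns]
        if missing:
            raise SchemaError(f"feature table is missing columns {missing}")
        X = features.loc[:, list(feature_names)].to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(feature_names):
            raise SchemaError(
                f"expected a table with {len(feature_names)} feature columns, "
                f"got shape {X.shape}")
    if np.isnan(X).any():
        raise ValidationError("feature matrix contains NaN")
    return X


def fit_model(spec: ModelSpec, features, labels, seed: int = 0,
              feature_names: Sequence[str] | None = None) -> TrainedModel:
    """Fit one regressor.

    ``features`` is an n x 7 DataFrame (columns selected by name) or array
    in :data:`~thumbrom.features.FEATURE_NAMES` order.  Standardization,
    when enabled, is fitted on exactly these rows — pass training rows only.
    """
    if feature_names is None:
        feature_names = FEATURE_NAMES
    X = _as_matrix(features, feature_names)
    y = np.asarray(labels, dtype=float)
    if y.ndim != 1 or len(y) != len(X):
        raise ValidationError("labels must be a 1-D sequence matching the rows")
    if len(X) < 10:
        raise ValidationError("need at least 10 rows to fit")
    if np.isnan(y).any():
        raise ValidationError("labels contain NaN")
    est = _build_estimator(spec, seed)
    est.fit(pd.DataFrame(X, columns=list(feature_names)), y)
    return TrainedModel(spec=spec, estimator=est,
                        feature_names=tuple(feature_names), seed=seed)


def predict(model: TrainedModel, features) -> np.ndarray:
    """Predict angles for an m x 7 feature table (columns aligned by name)."""
    X = _as_matrix(features, model.feature_names)
    frame = pd.DataFrame(X, columns=list(model.feature_names))
    out = np.asarray(model.estimator.predict(frame), dtype=float)
    if not np.all(np.isfinite(out)):
        raise ValidationError("model produced non-finite predictions")
    return out


@dataclass
class ModelResult:
    model: TrainedModel
    predictions: pd.DataFrame  # frame_id, true_angle_deg, predicted_angle_deg


@dataclass
class ResultBundle:
    """Per-model fits and held-out predictions over one shared split."""

    feature_frame: pd.DataFrame
    train_idx: np.ndarray
    test_idx: np.ndarray
    split: SplitConfig
    model_seed: int
    results: dict[str, ModelResult]


def fit_all(dataset: LandmarkDataset, specs: Sequence[ModelSpec] | None = None,
            split: SplitConfig | None = None, model_seed: int = 0,
            normalize_palm_areas: bool = True) -> ResultBundle:
    """Featurize, split once, and fit every spec on the shared split."""
    if specs is None:
        specs = default_specs()
    if split is None:
        split = SplitConfig()
    if not dataset.labeled:
        raise ValidationError("fit_all requires a labeled dataset")
    table = feature_table(dataset, normalize_palm_areas=normalize_palm_areas)
    results: dict[str, ModelResult] = {}
    if specs:
        train_idx, test_idx = split_dataset(len(table), split)
    else:
        train_idx = np.array([], dtype=int)
        test_idx = np.array([], dtype=int)
    X = table[FEATURE_NAMES]
    y = table["true_angle_deg"].to_numpy(dtype=float)
    for spec in specs:
        model = fit_model(spec, X.iloc[train_idx], y[train_idx], seed=model_seed)
        y_hat = predict(model, X.iloc[test_idx])
        preds = pd.DataFrame({
            "frame_id": table["frame_id"].iloc[test_idx].to_numpy(),
            "true_angle_deg": y[test_idx],
            "predicted_angle_deg": y_hat,
        })
        results[spec.name] = ModelResult(model=model, predictions=preds)
    return ResultBundle(feature_frame=table, train_idx=train_idx,
                        test_idx=test_idx, split=split, model_seed=model_seed,
                        results=results)
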
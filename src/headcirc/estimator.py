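"""Tree-ensemble regression from head features to circumference.

Four tree-based regressors are supported (decision tree, extra trees,
AdaBoost, random forest); the random forest is the default estimator.
Accuracy is reported as mean absolute error in centimetres --
MAE = (1/n) sum |y_i - yhat_i| -- deliberately not MSE/RMSE, which
over-weight the occasional badly-posed scene.  The error distribution is
additionally binned into <=1 cm, 1-2 cm and >2 cm, the categories that
matter clinically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.ensemble import AdaBoostRegressor, ExtraTreesRegressor, RandomForestRegressor
from sklearn.tree import DecisionTreeRegressor

from .features import FEATURE_NAMES, FeatureVector

ALGORITHMS = ("decision_tree", "extra_trees", "adaboost", "random_forest")

ERROR_BINS_CM = (1.0, 2.0)   # <=1, 1-2, >2


def _make_regressor(algorithm: str, seed: int):
    if algorithm == "decision_tree":
        return DecisionTreeRegressor(random_state=seed)
    if algorithm == "extra_trees":
        return ExtraTreesRegressor(n_estimators=100, random_state=seed)
    if algorithm == "adaboost":
        return AdaBoostRegressor(random_state=seed)
    if algorithm == "random_forest":
        # 100 trees, unrestricted depth, all features per split
        return RandomForestRegressor(n_estimators=100, max_features=None,
                                     random_state=seed)
    raise ValueError(f"unknown algorithm '{algorithm}'; expected one of {ALGORITHMS}")


def _as_feature_matrix(features, feature_names=None) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(features, FeatureVector):
        features = [features]
    if len(features) and isinstance(features[0], FeatureVector):
        names = features[0].names
        for fv in features:
            if fv.names != names:
                raise ValueError(f"inconsistent feature names: {fv.names} vs {names}")
        x = np.vstack([fv.as_array() for fv in features])
        return x, tuple(names)
    x = np.asarray(features, dtype=np.float64)
    if x.ndim == 1:
        x = x.reshape(1, -1)
    if feature_names:
        names = tuple(feature_names)
    elif x.shape[1] <= len(FEATURE_NAMES):
        names = FEATURE_NAMES[: x.shape[1]]
    else:
        names = FEATURE_NAMES + tuple(f"extra_{i}" for i in range(x.shape[1] - len(FEATURE_NAMES)))
    if len(names) != x.shape[1]:
        raise ValueError(f"{len(names)} feature names for {x.shape[1]} columns")
    return x, names


@dataclass
class CircumferenceModel:
    """A fitted features -> circumference (cm) regressor with metadata."""

    algorithm: str
    regressor: object
    feature_names: tuple[str, ...]
    n_train: int
    seed: int

    def predict(self, features) -> np.ndarray:
        x, names = _as_feature_matrix(features, self.feature_names)
        if names != self.feature_names:
            raise ValueError(f"feature names {names} do not match the model's "
                             f"{self.feature_names}")
        pred = self.regressor.predict(x)
        if not np.all(np.isfinite(pred)) or np.any(pred <= 0):
            raise RuntimeError("model produced a non-finite or non-positive circumference")
        return pred

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "CircumferenceModel":
        model = joblib.load(path)
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not contain a CircumferenceModel")
        return model


@dataclass
class EvaluationReport:
    """MAE plus the clinically-binned error distribution."""

    mae_cm: float
    rmse_cm: float
    abs_errors_cm: np.ndarray
    bin_fractions: dict[str, float]
    n: int

    def to_dict(self) -> dict:
        return {"mae_cm": self.mae_cm, "rmse_cm": self.rmse_cm, "n": self.n,
                "error_bins": self.bin_fractions,
                "abs_errors_cm": [float(e) for e in self.abs_errors_cm]}


def train(features, circumferences_cm, algorithm: str = "random_forest",
          seed: int = 0, feature_names=None) -> CircumferenceModel:
    """Fit a tree-ensemble regressor; deterministic for a fixed seed.

    Requires at least 10 paired rows with strictly positive targets.
    """
    x, names = _as_feature_matrix(features, feature_names)
    y = np.asarray(circumferences_cm, dtype=np.float64)
    if len(x) != len(y):
        raise ValueError(f"{len(x)} feature rows but {len(y)} targets")
    if len(y) < 10:
        raise ValueError(f"need >= 10 training rows, got {len(y)}")
    if np.any(y <= 0):
        raise ValueError("all target circumferences must be > 0 cm")
    reg = _make_regressor(algorithm, seed)
    reg.fit(x, y)
    return CircumferenceModel(algorithm=algorithm, regressor=reg,
                              feature_names=names, n_train=len(y), seed=seed)


def predict(model: CircumferenceModel, features) -> np.ndarray:
    return model.predict(features)


def evaluate(predictions_cm, truths_cm) -> EvaluationReport:
    """MAE, RMSE and the <=1 / 1-2 / >2 cm error-bin fractions."""
    pred = np.asarray(predictions_cm, dtype=np.float64).ravel()
    truth = np.asarray(truths_cm, dtype=np.float64).ravel()
    if len(pred) != len(truth):
        raise ValueError(f"{len(pred)} predictions but {len(truth)} truths")
    if len(pred) == 0:
        raise ValueError("cannot evaluate an empty set")
    err = np.abs(pred - truth)
    lo, hi = ERROR_BINS_CM
    bins = {
        "<=1cm": float(np.mean(err <= lo)),
        "1-2cm": float(np.mean((err > lo) & (err <= hi))),
        ">2cm": float(np.mean(err > hi)),
    }
    return EvaluationReport(mae_cm=float(np.mean(err)),
                            rmse_cm=float(np.sqrt(np.mean(err ** 2))),
                            abs_errors_cm=err, bin_fractions=bins, n=len(pred))


def compare_algorithms(x_train, y_train, x_test, y_test,
                       algorithms=ALGORITHMS, seed: int = 0) -> dict[str, float]:
    """Train each algorithm on the identical split; return {algorithm: MAE}.

    Duplicate tags are deduplicated (with a warning).  Bit-reproducible
    for a fixed seed.
    """
    seen: list[str] = []
    for tag in algorithms:
        if tag in seen:
            warnings.warn(f"duplicate algorithm tag '{tag}' ignored")
        else:
            seen.append(tag)
    table: dict[str, float] = {}
    for tag in seen:
        model = train(x_train, y_train, algorithm=tag, seed=seed)
        report = evaluate(model.predict(x_test), y_test)
        table[tag] = report.mae_cm
    return table
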
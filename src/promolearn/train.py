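"""Estimator fitting with repeated-split hyperparameter search.

Three estimator families are supported — random forest (RF), gradient
boosted trees (GBT) and RBF-kernel support vector machines (SVM) — for
both regression and classification. Hyperparameters are tuned by grid
search where each candidate is scored as the mean validation score over
repeated replicate-joint 9:1 splits of the training data (default 100
repeats), then the winner is refit on the full training set.

Tuning scores use the task metric also reported downstream: R² for
regression and support-weighted F1 for classification.
"""

from __future__ import annotations

import json
import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.ensemble import (
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.metrics import f1_score, r2_score
from sklearn.model_selection import ParameterGrid
from sklearn.svm import SVC, SVR

from .errors import EstimatorError
from .featurize import (
    FeatureSpec,
    TargetSpec,
    encode_sequences_features,
    one_hot_encode,
    split_train_test,
)
from .library import PromoterLibrary

KINDS = ("RF", "GBT", "SVM")


def default_grid(kind: str) -> dict[str, list]:
    """Built-in hyperparameter grids, overridable via configuration."""
    if kind == "RF":
        return {
            "n_estimators": [100, 300, 1000],
            "max_depth": [None, 5, 10],
            "min_samples_leaf": [1, 3],
        }
    if kind == "GBT":
        return {
            "n_estimators": [100, 300],
            "learning_rate": [0.01, 0.1],
            "max_depth": [2, 3, 5],
        }
    if kind == "SVM":
        return {"C": [0.1, 1.0, 10.0, 100.0], "gamma": ["scale", 0.01, 0.1]}
    raise EstimatorError(f"unknown estimator kind {kind!r}; expected one of {KINDS}")


@dataclass
class EstimatorSpec:
    """What to fit and how to tune it.

    ``tuning_repeats`` repeated replicate-joint splits at
    ``tuning_train_fraction`` score each grid candidate; ties keep the
    first candidate in grid order.
    """

    kind: str
    task: str  # "regression" | "classification"
    grid: dict[str, list] | None = None
    tuning_repeats: int = 100
    tuning_train_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise EstimatorError(
                f"unknown estimator kind {self.kind!r}; expected one of {KINDS}"
            )
        if self.task not in {"regression", "classification"}:
            raise ValueError(f"unknown task {self.task!r}")
        if self.grid is None:
            self.grid = default_grid(self.kind)
        if not self.grid:
            raise ValueError("hyperparameter grid must be nonempty")
        if self.tuning_repeats < 1:
            raise ValueError("tuning_repeats must be >= 1")


def make_estimator(kind: str, task: str, params: dict, seed: int = 0):
    """Instantiate the scikit-learn model behind a (kind, task) pair."""
    params = dict(params)
    if kind == "RF":
        cls = RandomForestRegressor if task == "regression" else RandomForestClassifier
        return cls(random_state=seed, **params)
    if kind == "GBT":
        cls = (
            GradientBoostingRegressor
            if task == "regression"
            else GradientBoostingClassifier
        )
        return cls(random_state=seed, **params)
    if kind == "SVM":
        if task == "regression":
            return SVR(kernel="rbf", **params)
        return SVC(kernel="rbf", random_state=seed, **params)
    raise EstimatorError(f"unknown estimator kind {kind!r}")


def score_predictions(task: str, y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Task metric: R² for regression, support-weighted F1 for classification."""
    if task == "regression":
        return float(r2_score(y_true, y_pred))
    return float(f1_score(y_true, y_pred, average="weighted", zero_division=0))


@dataclass
class TrainedEstimator:
    """A fitted model bundled with everything needed to reproduce predictions."""

    spec: EstimatorSpec
    feature_spec: FeatureSpec
    target_spec: TargetSpec
    model: object
    best_params: dict
    tuning_scores: list[dict]
    position_labels: tuple[int, ...]
    train_target_range: tuple[float, float]

    def predict(self, sequences: list[str]) -> np.ndarray:
        return predict(self, sequences)

    def save(self, path: str | Path) -> None:
        """Serialize model + sidecar spec (JSON) next to it."""
        path = Path(path)
        with open(path, "wb") as fh:
            pickle.dump(self, fh)
        sidecar = {
            "kind": self.spec.kind,
            "task": self.spec.task,
            "best_params": self.best_params,
            "retained_positions": list(self.feature_spec.retained_positions),
            "include_gc": self.feature_spec.include_gc,
            "entropy_cutoff_bits": self.feature_spec.entropy_cutoff_bits,
            "response_value": self.target_spec.response_value,
            "bin_edges": (
                list(self.target_spec.bin_edges)
                if self.target_spec.bin_edges
                else None
            ),
            "scaler": (
                [self.target_spec.scaler.mean, self.target_spec.scaler.sd]
                if self.target_spec.scaler
                else None
            ),
            "position_labels": list(self.position_labels),
        }
        path.with_suffix(path.suffix + ".spec.json").write_text(
            json.dumps(sidecar, indent=2) + "\n"
        )

    @staticmethod
    def load(path: str | Path) -> "TrainedEstimator":
        with open(path, "rb") as fh:
            est = pickle.load(fh)
        if not isinstance(est, TrainedEstimator):
            raise EstimatorError(f"{path} does not contain a TrainedEstimator")
        return est


def grid_search_train(
    train_lib: PromoterLibrary,
    espec: EstimatorSpec,
    fspec: FeatureSpec,
    tspec: TargetSpec,
) -> TrainedEstimator:
    """Tune hyperparameters by repeated replicate-joint splits and refit.

    Every grid candidate is scored as the mean validation score across
    ``espec.tuning_repeats`` seeded 9:1 splits of *train_lib* (identical
    sequences move jointly). Candidates whose fits fail on some splits are
    scored on the remaining ones; a candidate failing everywhere is
    dropped with a warning. The best candidate (first in grid order on
    ties) is refit on the full training set.
    """
    train_lib.require_nonempty()
    X_full = one_hot_encode(train_lib, fspec)
    y_full = tspec.encode(train_lib.expression_values())
    if tspec.task == "classification" and len(np.unique(y_full)) < 2:
        raise ValueError("training data contains fewer than 2 classes")

    candidates = list(ParameterGrid(espec.grid))
    results = []
    for params in candidates:
        scores = []
        for rep in range(espec.tuning_repeats):
            sub_train, sub_val = split_train_test(
                train_lib, espec.tuning_train_fraction, seed=espec.seed + rep
            )
            Xtr = one_hot_encode(sub_train, fspec)
            Xva = one_hot_encode(sub_val, fspec)
            ytr = tspec.encode(sub_train.expression_values())
            yva = tspec.encode(sub_val.expression_values())
            if tspec.task == "classification" and len(np.unique(ytr)) < 2:
                continue
            try:
                model = make_estimator(espec.kind, espec.task, params, espec.seed)
                model.fit(Xtr, ytr)
                scores.append(score_predictions(espec.task, yva, model.predict(Xva)))
            except Exception as exc:  # degenerate grid point: record, not fatal
                warnings.warn(
                    f"grid point {params} failed on split {rep}: {exc}",
                    stacklevel=2,
                )
        results.append(
            {
                "params": params,
                "mean_score": float(np.mean(scores)) if scores else float("nan"),
                "sd_score": float(np.std(scores, ddof=0)) if scores else float("nan"),
                "n_splits": len(scores),
            }
        )
    valid = [r for r in results if np.isfinite(r["mean_score"])]
    if not valid:
        raise EstimatorError("every grid candidate failed during tuning")
    best = max(valid, key=lambda r: r["mean_score"])  # first wins ties

    model = make_estimator(espec.kind, espec.task, best["params"], espec.seed)
    model.fit(X_full, y_full)
    return TrainedEstimator(
        spec=espec,
        feature_spec=fspec,
        target_spec=tspec,
        model=model,
        best_params=dict(best["params"]),
        tuning_scores=results,
        position_labels=train_lib.position_labels,
        train_target_range=(
            float(train_lib.expression_values().min()),
            float(train_lib.expression_values().max()),
        ),
    )


def fit_estimator(
    train_lib: PromoterLibrary,
    espec: EstimatorSpec,
    fspec: FeatureSpec,
    tspec: TargetSpec,
    params: dict | None = None,
) -> TrainedEstimator:
    """Fit once with fixed hyperparameters (no grid search).

    ``params=None`` uses the scikit-learn defaults for the estimator kind.
    Used by cross-validation, where tuning inside every repeat would
    multiply the cost without changing the leakage guarantees under test.
    """
    train_lib.require_nonempty()
    params = params or {}
    X = one_hot_encode(train_lib, fspec)
    y = tspec.encode(train_lib.expression_values())
    model = make_estimator(espec.kind, espec.task, params, espec.seed)
    model.fit(X, y)
    return TrainedEstimator(
        spec=espec,
        feature_spec=fspec,
        target_spec=tspec,
        model=model,
        best_params=dict(params),
        tuning_scores=[],
        position_labels=train_lib.position_labels,
        train_target_range=(
            float(train_lib.expression_values().min()),
            float(train_lib.expression_values().max()),
        ),
    )


def predict(est: TrainedEstimator, sequences: list[str]) -> np.ndarray:
    """Predict expression values (regression) or class labels.

    Sequences must match the training library's length and alphabet.
    Regression predictions are mapped back to the original expression
    scale when the targets were standardized. Deterministic: repeated
    calls return identical output.
    """
    X = encode_sequences_features(
        list(sequences), est.feature_spec, est.position_labels
    )
    raw = est.model.predict(X)
    return est.target_spec.decode(raw)
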
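"""Severity classification from lesion counts.

A single-hidden-layer network (7 logistic units, L2 penalty 0.001) trained
on z-scored count features with a stratified 80/20 split.  Scaling
parameters are estimated on the training split only and stored with the
model, so test rows never influence scaling.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier

from lesioncount.types import GRADES, MEASURE_COLUMNS, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_FEATURES = ("MA", "Hma", "HE")
N_CLASSES = len(GRADES)


@dataclass
class FeatureMatrix:
    """Lesion-count features and grade labels, rows = images.

    Rows with any missing selected feature are dropped on construction;
    ``n_dropped`` records how many.
    """

    X: np.ndarray
    y: np.ndarray  # integer grades
    feature_names: tuple[str, ...]
    image_ids: list[str] = field(default_factory=list)
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.y)


@dataclass(frozen=True)
class ClassifierConfig:
    hidden_units: int = 7
    weight_decay: float = 0.001
    train_fraction: float = 0.8
    seed: int = 0
    max_iterations: int = 3000

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValidationError(f"train_fraction must be in (0, 1), got {self.train_fraction}")
        if self.hidden_units < 1:
            raise ValidationError("hidden_units must be >= 1")
        if self.weight_decay < 0:
            raise ValidationError("weight_decay must be >= 0")


@dataclass
class ClassifierReport:
    """Held-out evaluation: 4x4 confusion matrix, accuracy, sensitivities.

    Confusion rows are true grades, columns predicted; ``sensitivity[k]`` is
    confusion[k, k] / row-sum k, NaN when the class is absent from the test
    set.
    """

    confusion: np.ndarray
    accuracy: float
    sensitivity: np.ndarray
    n_train: int
    n_test: int
    converged: bool = True

    def to_frame(self) -> pd.DataFrame:
        labels = [g.label for g in GRADES]
        frame = pd.DataFrame(self.confusion, index=labels, columns=labels)
        frame["sensitivity"] = self.sensitivity
        return frame


def build_features(
    table: pd.DataFrame,
    features: tuple[str, ...] = DEFAULT_FEATURES,
) -> FeatureMatrix:
    """Assemble the feature matrix from a (filtered) count table.

    RL is excluded from the default feature set because it is an exact
    linear combination of MA and Hma; pass ``features=("MA","Hma","RL","HE")``
    to restore it.
    """
    unknown = [f for f in features if f not in MEASURE_COLUMNS]
    if unknown:
        raise ValidationError(f"unknown features {unknown}; choose from {sorted(MEASURE_COLUMNS)}")
    cols = [MEASURE_COLUMNS[f] for f in features]
    values = table[cols].astype(float)
    complete = values.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("build_features: dropped %d rows with missing features", n_dropped)
    kept = table.loc[complete]
    y = np.array([int(g) for g in kept["grade"]])
    if len(np.unique(y)) < 2:
        raise ValidationError(
            f"need >= 2 distinct classes to train, got {len(np.unique(y))}"
        )
    return FeatureMatrix(
        X=values.loc[complete].to_numpy(),
        y=y,
        feature_names=tuple(features),
        image_ids=kept["image_id"].astype(str).tolist(),
        n_dropped=n_dropped,
    )


@dataclass
class CountClassifier:
    """Trained network plus the scaling parameters and feature list."""

    mlp: MLPClassifier
    feature_names: tuple[str, ...]
    center: np.ndarray
    spread: np.ndarray

    def _scale(self, X: np.ndarray) -> np.ndarray:
        return (X - self.center) / self.spread

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.mlp.predict(self._scale(np.asarray(X, dtype=float)))

    def save(self, path) -> None:
        payload = {
            "feature_names": list(self.feature_names),
            "center": self.center.tolist(),
            "spread": self.spread.tolist(),
            "classes": self.mlp.classes_.tolist(),
            "coefs": [c.tolist() for c in self.mlp.coefs_],
            "intercepts": [b.tolist() for b in self.mlp.intercepts_],
            "activation": self.mlp.activation,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path) -> "CountClassifier":
        with open(path) as fh:
            payload = json.load(fh)
        coefs = [np.asarray(c) for c in payload["coefs"]]
        mlp = MLPClassifier(
            hidden_layer_sizes=(coefs[0].shape[1],),
            activation=payload["activation"],
        )
        mlp.coefs_ = coefs
        mlp.intercepts_ = [np.asarray(b) for b in payload["intercepts"]]
        mlp.classes_ = np.asarray(payload["classes"])
        mlp.n_layers_ = len(coefs) + 1
        mlp.n_outputs_ = len(mlp.classes_)
        mlp.out_activation_ = "softmax" if len(mlp.classes_) > 2 else "logistic"
        mlp._label_binarizer = _binarizer_for(mlp.classes_)
        return cls(
            mlp=mlp,
            feature_names=tuple(payload["feature_names"]),
            center=np.asarray(payload["center"], dtype=float),
            spread=np.asarray(payload["spread"], dtype=float),
        )


def _binarizer_for(classes: np.ndarray):
    from sklearn.preprocessing import LabelBinarizer

    lb = LabelBinarizer()
    lb.fit(classes)
    return lb


def _report_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, n_train: int, converged: bool = True
) -> ClassifierReport:
    confusion = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    for t, p in zip(y_true, y_pred):
        confusion[int(t), int(p)] += 1
    n_test = len(y_true)
    row_sums = confusion.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sensitivity = np.where(
            row_sums > 0, np.diag(confusion) / np.maximum(row_sums, 1), np.nan
        )
    return ClassifierReport(
        confusion=confusion,
        accuracy=float(np.trace(confusion)) / n_test if n_test else float("nan"),
        sensitivity=sensitivity,
        n_train=n_train,
        n_test=n_test,
        converged=converged,
    )


def train_classifier(
    features: FeatureMatrix,
    config: ClassifierConfig = ClassifierConfig(),
) -> tuple[CountClassifier, ClassifierReport]:
    """Train on a stratified train fraction, report on the held-out rest.

    Deterministic for a fixed (data, seed).  Non-convergence is recorded in
    the report, never raised.
    """
    if len(features) < 20:
        raise ValidationError(f"need >= 20 samples to train, got {len(features)}")
    X_train, X_test, y_train, y_test = train_test_split(
        features.X,
        features.y,
        train_size=config.train_fraction,
        random_state=config.seed,
        stratify=features.y,
    )
    center = X_train.mean(axis=0)
    spread = X_train.std(axis=0)
    spread = np.where(spread == 0, 1.0, spread)
    mlp = MLPClassifier(
        hidden_layer_sizes=(config.hidden_units,),
        activation="logistic",
        alpha=config.weight_decay,
        solver="lbfgs",
        max_iter=config.max_iterations,
        random_state=config.seed,
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        mlp.fit((X_train - center) / spread, y_train)
        converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
    model = CountClassifier(
        mlp=mlp, feature_names=features.feature_names, center=center, spread=spread
    )
    y_pred = model.predict(X_test)
    report = _report_from_predictions(y_test, y_pred, n_train=len(y_train), converged=converged)
    return model, report


def evaluate(model: CountClassifier, features: FeatureMatrix) -> ClassifierReport:
    """Confusion matrix, accuracy and per-class sensitivity on a feature set."""
    if tuple(features.feature_names) != tuple(model.feature_names):
        raise ValidationError(
            f"feature mismatch: model trained on {model.feature_names}, "
            f"got {features.feature_names}"
        )
    y_pred = model.predict(features.X)
    return _report_from_predictions(features.y, y_pred, n_train=0)
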
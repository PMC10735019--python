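"""The two quality-control models: RBF SVM and the dense neural network.

Both consume the PCA-projected per-image feature vectors and emit an
acceptance probability in [0, 1] (positive class = "Accepted"). The SVM
is found by randomized cross-validated search over (C, gamma) and its
signed decision value is squashed through a logistic; the network trains
with the fixed schedule of :class:`trackqc.nn.NNConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import uniform
from sklearn.model_selection import KFold, RandomizedSearchCV, cross_val_predict
from sklearn.svm import SVC

from .dataset import PCATransform
from .nn import DenseNetwork, NNConfig

__all__ = [
    "SVMConfig",
    "NNConfig",
    "CVReport",
    "TrainedModel",
    "svm_search_and_train",
    "svm_probability",
    "nn_train",
    "predict",
    "as_xy",
]

POSITIVE_LABEL = "Accepted"


@dataclass(frozen=True)
class SVMConfig:
    """Randomized hyperparameter search space for the RBF SVM.

    The printed search ranges in the source material are partly
    corrupted; C in [0.1, 30] and gamma in (0, 0.3] are usable defaults
    around the reported optimum (C=16.5, gamma=0.09).
    """

    c_range: tuple[float, float] = (0.1, 30.0)
    gamma_range: tuple[float, float] = (1e-3, 0.3)
    n_candidates: int = 50
    cv_folds: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.c_range[0] <= 0 or self.gamma_range[0] <= 0:
            raise ValueError("C and gamma must be strictly positive")


@dataclass(frozen=True)
class CVReport:
    """Cross-validation outcome of the randomized SVM search."""

    best_c: float
    best_gamma: float
    cv_accuracy: float
    cv_decision_values: np.ndarray  # out-of-fold decision values
    cv_labels: np.ndarray


@dataclass
class TrainedModel:
    """A fitted classifier plus the feature transform it expects."""

    kind: str  # "svm" | "nn"
    estimator: object
    pca: PCATransform | None = None
    threshold: float = 0.5
    history: dict | None = None


def as_xy(table: pd.DataFrame, features: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Label vector (Accepted=1) and feature matrix from a feature table."""
    y = (table["label"].to_numpy() == POSITIVE_LABEL).astype(np.int64)
    if features is None:
        from .dataset import feature_columns_of

        features = table.loc[:, feature_columns_of(table)].to_numpy(dtype=np.float64)
    return np.asarray(features, dtype=np.float64), y


def svm_search_and_train(
    x: np.ndarray, y: np.ndarray, config: SVMConfig | None = None
) -> tuple[TrainedModel, CVReport]:
    """Randomized CV search for (C, gamma), refit on the full data.

    Out-of-fold decision values are retained so the cross-validated
    confusion matrix and prediction histogram can be reported the way
    the SVM is evaluated (no separate validation split).
    """
    config = config or SVMConfig()
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y).ravel()
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    cv = KFold(n_splits=config.cv_folds, shuffle=True, random_state=config.rng_seed)
    search = RandomizedSearchCV(
        SVC(kernel="rbf"),
        param_distributions={
            "C": uniform(config.c_range[0], config.c_range[1] - config.c_range[0]),
            "gamma": uniform(config.gamma_range[0], config.gamma_range[1] - config.gamma_range[0]),
        },
        n_iter=config.n_candidates,
        cv=cv,
        random_state=config.rng_seed,
        n_jobs=1,
    )
    search.fit(x, y)
    best = search.best_estimator_
    decisions = cross_val_predict(best, x, y, cv=cv, method="decision_function")
    cv_acc = float(np.mean((decisions > 0) == (y == 1)))
    report = CVReport(
        best_c=float(best.C),
        best_gamma=float(best.gamma),
        cv_accuracy=cv_acc,
        cv_decision_values=np.asarray(decisions, dtype=np.float64),
        cv_labels=y.copy(),
    )
    return TrainedModel(kind="svm", estimator=best), report


def svm_probability(model: TrainedModel, x: np.ndarray) -> np.ndarray:
    """Logistic squashing of the SVM's signed decision value.

    Monotone in the decision value; a decision value of 0 (a point on
    the separating surface) maps to probability 0.5.
    """
    if model.kind != "svm":
        raise ValueError("svm_probability expects an SVM model")
    d = model.estimator.decision_function(np.atleast_2d(np.asarray(x, dtype=np.float64)))
    return 1.0 / (1.0 + np.exp(-d))


def nn_train(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    config: NNConfig | None = None,
) -> TrainedModel:
    """Train the dense network with its full schedule; history retained."""
    config = config or NNConfig()
    net = DenseNetwork(n_features=np.asarray(x_train).shape[1], config=config)
    net.fit(x_train, y_train, x_val, y_val)
    return TrainedModel(kind="nn", estimator=net, history=net.history)


def predict(model: TrainedModel, x: np.ndarray) -> np.ndarray:
    """Acceptance probability per row, in [0, 1]."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    if model.kind == "svm":
        n_expected = model.estimator.n_features_in_
        if x.shape[1] != n_expected:
            raise ValueError(f"expected {n_expected} features, got {x.shape[1]}")
        return svm_probability(model, x)
    if model.kind == "nn":
        return model.estimator.predict_proba(x)
    raise ValueError(f"unknown model kind {model.kind!r}")
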
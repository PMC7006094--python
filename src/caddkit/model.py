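"""L2-regularized logistic classifier separating simulated (1) from derived (0).

The model is deliberately plain: a linear logistic regressor over the scaled
feature matrix, with an L2 penalty on the weights (intercept unpenalized) and
an iteration cap. Defaults follow the CADD-family choice of penalty 0.1 and
100 iterations, with internal feature rescaling off (scaling already happened
in the feature-matrix builder).

Penalty parameterization: the objective is ``sum of log-losses +
l2_penalty * ||w||^2``; the underlying scikit-learn solver is configured with
``C = 1 / (2 * l2_penalty)`` to realise exactly that objective.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .annotation import FeatureMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainingConfig:
    l2_penalty: float = 0.1
    max_iterations: int = 100
    internal_rescaling: bool = False  # kept for config parity; never used
    seed: int = 0

    def __post_init__(self):
        if self.l2_penalty < 0:
            raise ValueError("l2_penalty must be >= 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class LogisticModel:
    weights: np.ndarray
    intercept: float
    fingerprint: str
    config: TrainingConfig = TrainingConfig()

    def linear_predictor(self, matrix: FeatureMatrix) -> np.ndarray:
        if matrix.fingerprint != self.fingerprint:
            raise ValueError(
                "feature-matrix fingerprint does not match the model; the "
                "column catalogue or scaling differs from training time"
            )
        if len(matrix.columns) != self.weights.size:
            raise ValueError("weight vector length mismatch")
        return matrix.frame.to_numpy() @ self.weights + self.intercept

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                dict(
                    weights=self.weights.tolist(),
                    intercept=self.intercept,
                    fingerprint=self.fingerprint,
                    config=dict(
                        l2_penalty=self.config.l2_penalty,
                        max_iterations=self.config.max_iterations,
                        internal_rescaling=self.config.internal_rescaling,
                        seed=self.config.seed,
                    ),
                ),
                fh,
            )

    @classmethod
    def from_json(cls, path: str) -> "LogisticModel":
        with open(path) as fh:
            blob = json.load(fh)
        return cls(
            np.asarray(blob["weights"], dtype=float),
            float(blob["intercept"]),
            blob["fingerprint"],
            TrainingConfig(**blob["config"]),
        )


def split_train_test(
    variants: pd.DataFrame,
    test_fraction: float = 1 / 11,
    seed: int = 0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Class-balanced random split into (train, test).

    Per class, ``round(n_class * test_fraction)`` rows go to the test set
    (round-half-even, numpy's rounding); the rest train. Both classes must
    have at least 2 members.
    """
    if not 0.0 <= test_fraction < 1.0:
        raise ValueError("test_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    classes = variants["class_label"].unique()
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    test_parts, train_parts = [], []
    for label in sorted(classes):
        sub = variants[variants["class_label"] == label]
        if len(sub) < 2:
            raise ValueError(f"class {label} has fewer than 2 members")
        n_test = int(np.round(len(sub) * test_fraction))
        order = rng.permutation(len(sub))
        test_parts.append(sub.iloc[order[:n_test]])
        train_parts.append(sub.iloc[order[n_test:]])
    train = pd.concat(train_parts).sort_index()
    test = pd.concat(test_parts).sort_index()
    return train.reset_index(drop=True), test.reset_index(drop=True)


def train(
    matrix: FeatureMatrix,
    labels: np.ndarray,
    config: TrainingConfig = TrainingConfig(),
) -> LogisticModel:
    """Fit the classifier on an encoded feature matrix.

    Deterministic for a fixed seed; logs if the iteration cap was reached
    before convergence. A larger penalty never increases the weight norm.
    """
    labels = np.asarray(labels)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(labels)) < 2:
        raise ValueError("training needs both classes")
    X = matrix.frame.to_numpy()
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains non-finite values")

    C = np.inf if config.l2_penalty == 0 else 1.0 / (2.0 * config.l2_penalty)
    clf = LogisticRegression(
        penalty=None if config.l2_penalty == 0 else "l2",
        C=1.0 if config.l2_penalty == 0 else C,
        max_iter=config.max_iterations,
        solver="lbfgs",
        random_state=config.seed,
        tol=1e-6,
    )
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # convergence reported via log below
        clf.fit(X, labels)
    if clf.n_iter_[0] >= config.max_iterations:
        logger.info("iteration cap (%d) reached before convergence",
                    config.max_iterations)
    return LogisticModel(
        clf.coef_.ravel().copy(), float(clf.intercept_[0]),
        matrix.fingerprint, config,
    )


def predict(model: LogisticModel, matrix: FeatureMatrix) -> np.ndarray:
    """Posterior probability of class 1 (proxy-deleterious) per variant."""
    z = model.linear_predictor(matrix)
    return 1.0 / (1.0 + np.exp(-z))
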
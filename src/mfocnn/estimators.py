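"""Scikit-learn style estimators wrapping the CNN and the MFO search.

:class:`CNNClassifier` is the block-structured 1D-CNN as a plain classifier
with explicit hyperparameters; :class:`MFOCNNClassifier` wraps the whole
method — moth-flame search over the six-dimensional hyperparameter space
followed by full retraining of the winner — behind the same fit/predict
surface, so both compose with sklearn pipelines and model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from . import mfo
from .model import build_model_spec
from .search_space import (
    HyperparameterVector,
    decode_position,
    default_space,
)
from .training import (
    FitnessCache,
    FitnessConfig,
    TrainConfig,
    evaluate_fitness,
    stratified_holdout,
    train_model,
)

__all__ = ["CNNClassifier", "MFOCNNClassifier"]

_ACT_CODES = {"relu": 0, "sigmoid": 1, "tanh": 2}


def _as_hp(
    n_kernels, kernel_size, activation, dropout, learning_rate, pool_size
) -> HyperparameterVector:
    code = _ACT_CODES.get(activation, activation) if isinstance(activation, str) else activation
    return HyperparameterVector(
        n_kernels=n_kernels,
        kernel_size=kernel_size,
        activation=int(code),
        dropout=dropout,
        learning_rate=learning_rate,
        pool_size=pool_size,
    )


class CNNClassifier(ClassifierMixin, BaseEstimator):
    """Block-structured 1D-CNN classifier for fixed-length signals.

    Parameters mirror the six tuned hyperparameters plus the training
    budget.  Rows of ``X`` are single-channel signals of equal length.

    Examples
    --------
    >>> clf = CNNClassifier(epochs=20, random_state=0)
    >>> clf.fit(X_train, y_train).score(X_test, y_test)  # doctest: +SKIP
    """

    def __init__(
        self,
        n_kernels: int = 50,
        kernel_size: int = 10,
        activation: str | int = "relu",
        dropout: float = 0.2,
        learning_rate: float = 1e-3,
        pool_size: int = 2,
        n_blocks: int = 6,
        batch_size: int = 256,
        epochs: int = 20,
        val_fraction: float = 0.1,
        random_state: int = 0,
    ):
        self.n_kernels = n_kernels
        self.kernel_size = kernel_size
        self.activation = activation
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.pool_size = pool_size
        self.n_blocks = n_blocks
        self.batch_size = batch_size
        self.epochs = epochs
        self.val_fraction = val_fraction
        self.random_state = random_state

    def _hp(self) -> HyperparameterVector:
        return _as_hp(
            self.n_kernels,
            self.kernel_size,
            self.activation,
            self.dropout,
            self.learning_rate,
            self.pool_size,
        )

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=np.float64)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise ValueError("need at least two classes")
        seed = 0 if self.random_state is None else int(self.random_state)
        hp = self._hp()
        self.model_spec_ = build_model_spec(
            hp,
            input_len=X.shape[1],
            n_classes=self.classes_.size,
            n_blocks=self.n_blocks,
        )
        data = stratified_holdout(X, y_enc, self.val_fraction, seed)
        cfg = TrainConfig(
            batch_size=min(self.batch_size, data[0].shape[0]),
            epochs=self.epochs,
            val_fraction=self.val_fraction,
            seed=seed,
        )
        self.network_, self.history_ = train_model(self.model_spec_, data, cfg)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "network_")
        X = check_array(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        X3 = X.astype(np.float32)[:, :, None]
        out = [self.network_(X3[i : i + 1024]) for i in range(0, X3.shape[0], 1024)]
        return np.vstack(out).astype(np.float64)

    def predict(self, X):
        probs = self.predict_proba(X)
        return self.classes_[probs.argmax(axis=1)]


class MFOCNNClassifier(ClassifierMixin, BaseEstimator):
    """Moth-flame hyperparameter search wrapped around :class:`CNNClassifier`.

    ``fit`` carves a validation set out of the training data, runs MFO over
    the constrained six-dimensional space using short-budget validation
    cross-entropy as the objective, then retrains the winning configuration
    at full budget.  The reference study conditions are 20 moths and 30
    iterations with final training at batch 256 for 500 epochs; desk-scale
    work will usually pass smaller values.

    Attributes
    ----------
    best_hyperparameters_ : HyperparameterVector
    optimization_result_ : mfo.OptimizationResult (with per-iteration trace)
    estimator_ : the final fitted CNNClassifier
    """

    def __init__(
        self,
        n_moths: int = 20,
        max_iter: int = 30,
        spiral_b: float = 1.0,
        search_epochs: int = 10,
        search_batch_size: int = 256,
        max_train_samples: int | None = None,
        n_blocks: int = 6,
        batch_size: int = 256,
        epochs: int = 500,
        val_fraction: float = 0.1,
        random_state: int = 0,
    ):
        self.n_moths = n_moths
        self.max_iter = max_iter
        self.spiral_b = spiral_b
        self.search_epochs = search_epochs
        self.search_batch_size = search_batch_size
        self.max_train_samples = max_train_samples
        self.n_blocks = n_blocks
        self.batch_size = batch_size
        self.epochs = epochs
        self.val_fraction = val_fraction
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=np.float64)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise ValueError("need at least two classes")
        seed = 0 if self.random_state is None else int(self.random_state)
        data = stratified_holdout(X, y_enc, self.val_fraction, seed)
        fit_cfg = FitnessConfig(
            search_epochs=self.search_epochs,
            batch_size=self.search_batch_size,
            max_train_samples=self.max_train_samples,
        )
        cache = FitnessCache()

        def objective(pos: np.ndarray) -> float:
            hp = decode_position(pos)
            return evaluate_fitness(
                hp,
                data,
                fit_cfg,
                seed=seed,
                cache=cache,
                n_classes=self.classes_.size,
            )

        config = mfo.MFOConfig(
            bounds=default_space().bounds,
            n_moths=self.n_moths,
            max_iter=self.max_iter,
            spiral_b=self.spiral_b,
            seed=seed,
        )
        self.optimization_result_ = mfo.run_mfo(objective, config)
        self.best_hyperparameters_ = decode_position(self.optimization_result_.best_position)
        hp = self.best_hyperparameters_
        self.estimator_ = CNNClassifier(
            n_kernels=hp.n_kernels,
            kernel_size=hp.kernel_size,
            activation=hp.activation,
            dropout=hp.dropout,
            learning_rate=hp.learning_rate,
            pool_size=hp.pool_size,
            n_blocks=self.n_blocks,
            batch_size=self.batch_size,
            epochs=self.epochs,
            val_fraction=self.val_fraction,
            random_state=seed,
        ).fit(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "estimator_")
        return self.estimator_.predict(X)

    def predict_proba(self, X):
        check_is_fitted(self, "estimator_")
        return self.estimator_.predict_proba(X)
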
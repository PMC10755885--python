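"""Model training, the optimizer's fitness function, and the batch-size sweep.

Two training regimes coexist:

* **Search-time fitness** — inside the hyperparameter-search loop each
  candidate network is trained for a short budget (default 10 epochs) and
  scored by its final validation cross-entropy.  Results are cached on the
  decoded hyperparameters, so rounding-equivalent positions never retrain.
* **Final training** — the winning configuration is retrained at full budget
  (default batch 256, 500 epochs) with best-validation checkpointing: after
  every epoch the validation accuracy is compared with the incumbent and the
  best snapshot is kept, so the returned model is the best-validation model,
  not the last-epoch one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .model import ModelSpec, build_model_spec, instantiate
from .nn import Adam, Network
from .search_space import HyperparameterVector

__all__ = [
    "TrainConfig",
    "FitnessConfig",
    "TrainingHistory",
    "cross_entropy",
    "train_model",
    "evaluate_fitness",
    "FitnessCache",
    "batch_size_sweep",
]

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class TrainConfig:
    batch_size: int = 256
    epochs: int = 500
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1:
            raise ConfigurationError("batch_size and epochs must be >= 1")
        if not 0.0 < self.val_fraction < 1.0:
            raise ConfigurationError("val_fraction must be in (0, 1)")


@dataclass
class FitnessConfig:
    """Per-evaluation training budget used inside the optimizer loop."""

    search_epochs: int = 10
    batch_size: int = 256
    max_train_samples: Optional[int] = None  # subsample cap for cheap fitness

    def __post_init__(self) -> None:
        if self.search_epochs < 1:
            raise ConfigurationError("search_epochs must be >= 1")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = -1  # 0-based index into the lists
    best_val_accuracy: float = -np.inf

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.train_loss) + 1),
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
                "val_acc": self.val_accuracy,
            }
        )


def cross_entropy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Mean negative log predicted probability of the true class.

    ``pred`` is a batch of probability rows; probabilities are clamped at
    1e-12 before the logarithm so a confidently wrong model yields a large
    finite loss rather than infinity.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=int)
    p_true = pred[np.arange(truth.size), truth]
    if np.any(p_true < _EPS):
        logger.debug("clamping %d zero-probability predictions", int((p_true < _EPS).sum()))
        p_true = np.clip(p_true, _EPS, None)
    return float(-np.log(p_true).mean())


def _accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    return float((pred.argmax(axis=1) == truth).mean())


def _eval_in_batches(net: Network, X: np.ndarray, batch: int = 1024) -> np.ndarray:
    return np.vstack([net(X[i : i + batch]) for i in range(0, X.shape[0], batch)])


def train_model(
    spec: ModelSpec,
    data: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    cfg: TrainConfig,
) -> tuple[Network, TrainingHistory]:
    """Adam training of the cross-entropy objective with checkpointing.

    ``data`` is (X_train, y_train, X_val, y_val); inputs are (n, L) signal
    matrices.  Returns the best-validation model and the epoch history.
    Training aborts (history preserved) if the loss becomes non-finite.
    """
    X_tr, y_tr, X_val, y_val = data
    if cfg.batch_size > X_tr.shape[0]:
        logger.warning(
            "batch_size %d exceeds training size %d; using full-batch steps",
            cfg.batch_size,
            X_tr.shape[0],
        )
    X_tr3 = np.asarray(X_tr, dtype=np.float32)[:, :, None]
    X_val3 = np.asarray(X_val, dtype=np.float32)[:, :, None]
    y_tr = np.asarray(y_tr, dtype=int)
    y_val = np.asarray(y_val, dtype=int)
    n_classes = spec.n_classes

    net = instantiate(spec, seed=cfg.seed)
    if spec.hyperparameters is not None:
        lr = spec.hyperparameters.learning_rate
    else:
        lr = 1e-3
    opt = Adam(net.parameters(), lr=lr)
    shuffle_rng = np.random.default_rng(cfg.seed + 1)

    history = TrainingHistory()
    best_state: list[np.ndarray] | None = None
    onehot = np.eye(n_classes, dtype=np.float32)

    for epoch in range(cfg.epochs):
        order = shuffle_rng.permutation(X_tr3.shape[0])
        epoch_loss, n_batches = 0.0, 0
        aborted = False
        for start in range(0, order.size, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = X_tr3[idx], y_tr[idx]
            probs = net.forward(xb, training=True)
            loss = cross_entropy(probs, yb)
            if not np.isfinite(loss):
                logger.error("non-finite training loss at epoch %d; aborting", epoch + 1)
                aborted = True
                break
            dlogits = (probs - onehot[yb]) / xb.shape[0]
            net.backward(dlogits)
            opt.step(net.gradients())
            epoch_loss += loss
            n_batches += 1
        if aborted:
            break
        val_probs = _eval_in_batches(net, X_val3)
        v_loss = cross_entropy(val_probs, y_val)
        v_acc = _accuracy(val_probs, y_val)
        history.train_loss.append(epoch_loss / max(n_batches, 1))
        history.val_loss.append(v_loss)
        history.val_accuracy.append(v_acc)
        if v_acc > history.best_val_accuracy:
            history.best_val_accuracy = v_acc
            history.best_epoch = epoch
            best_state = net.get_weights()
    if best_state is not None:
        net.set_weights(best_state)
    return net, history


def stratified_holdout(
    X: np.ndarray, y: np.ndarray, val_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Split (X, y) into train/validation parts, stratified and seeded."""
    rng = np.random.default_rng(seed)
    tr_idx, val_idx = [], []
    for cls in np.unique(y):
        rows = rng.permutation(np.nonzero(y == cls)[0])
        n_val = max(int(round(val_fraction * rows.size)), 1)
        val_idx.append(rows[:n_val])
        tr_idx.append(rows[n_val:])
    tr = np.sort(np.concatenate(tr_idx))
    val = np.sort(np.concatenate(val_idx))
    return X[tr], y[tr], X[val], y[val]


class FitnessCache(dict):
    """Maps decoded hyperparameters (plus seed) to fitness values."""

    @staticmethod
    def key(hp: HyperparameterVector, seed: int) -> tuple:
        return (
            hp.n_kernels,
            hp.kernel_size,
            hp.activation,
            round(hp.dropout, 12),
            round(float(np.log10(hp.learning_rate)), 12),
            hp.pool_size,
            seed,
        )


def evaluate_fitness(
    hp: HyperparameterVector,
    data: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    fit_cfg: FitnessConfig | None = None,
    seed: int = 0,
    cache: FitnessCache | None = None,
    n_classes: int | None = None,
) -> float:
    """Short-budget training score for one candidate: final validation loss.

    Identical (hp, data, seed) triples return identical values; with a cache
    supplied, repeats skip retraining entirely.  Any failure to build or
    train maps to +inf so the optimizer simply discards the candidate.
    """
    fit_cfg = fit_cfg or FitnessConfig()
    if cache is not None:
        k = FitnessCache.key(hp, seed)
        if k in cache:
            return cache[k]
    X_tr, y_tr, X_val, y_val = data
    if fit_cfg.max_train_samples is not None and X_tr.shape[0] > fit_cfg.max_train_samples:
        sub = np.random.default_rng(seed).choice(
            X_tr.shape[0], size=fit_cfg.max_train_samples, replace=False
        )
        sub.sort()
        X_tr, y_tr = X_tr[sub], y_tr[sub]
    k_classes = n_classes or int(np.max(y_tr)) + 1
    try:
        spec = build_model_spec(hp, input_len=X_tr.shape[1], n_classes=k_classes)
        cfg = TrainConfig(
            batch_size=min(fit_cfg.batch_size, X_tr.shape[0]),
            epochs=fit_cfg.search_epochs,
            seed=seed,
        )
        _, history = train_model(spec, (X_tr, y_tr, X_val, y_val), cfg)
        value = history.val_loss[-1] if history.val_loss else np.inf
    except ConfigurationError as exc:
        logger.warning("unbuildable candidate %s: %s", hp, exc)
        value = np.inf
    if not np.isfinite(value):
        value = np.inf
    if cache is not None:
        cache[k] = value
    return value


def batch_size_sweep(
    spec: ModelSpec,
    data: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    sizes: tuple[int, ...] = (32, 64, 128, 256, 512, 1024),
    epochs: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Train one model per batch size (shared seed) and tabulate loss curves.

    Returns a tidy DataFrame with columns batch_size, epoch, train_loss,
    val_loss — the harness for studying convergence against batch size.
    """
    n_train = data[0].shape[0]
    frames = []
    for size in sizes:
        if size < 1:
            raise ValueError("batch sizes must be positive")
        if size > n_train:
            raise ValueError(f"batch size {size} exceeds training-set size {n_train}")
        cfg = TrainConfig(batch_size=size, epochs=epochs, seed=seed)
        _, history = train_model(spec, data, cfg)
        frame = history.to_frame()
        frame.insert(0, "batch_size", size)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
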
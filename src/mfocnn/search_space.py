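"""The six-dimensional CNN hyperparameter space and its optimizer encoding.

The tuned vector is [delta, s, a, d, eta, m]:

* ``delta`` — number of convolution filters in the first block, 40..100
* ``s``    — convolution kernel size in taps, 1..20
* ``a``    — activation code: 0 = ReLU, 1 = sigmoid, 2 = tanh
* ``d``    — dropout probability, 0..0.6
* ``eta``  — learning rate, 1e-5 <= eta < 1, searched on a log10 scale
* ``m``    — max-pooling window, 2..20

The optimizer works on a plain 6-vector of reals; :func:`decode_position`
maps such a point to a concrete :class:`HyperparameterVector` (rounding the
integer dimensions half-away-from-zero, snapping the activation to a code,
and exponentiating the learning-rate coordinate, which is log10(eta)).
Out-of-range coordinates are silently clipped to the box first, so any point
the optimizer can produce decodes to a valid network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .mfo import round_half_away

__all__ = [
    "HyperparameterVector",
    "Dimension",
    "SpaceDefinition",
    "default_space",
    "decode_position",
    "encode_vector",
    "activation_name",
    "report_row",
]

ACTIVATIONS = {0: "relu", 1: "sigmoid", 2: "tanh"}

# Learning rate just below the open upper bound eta < 1.
_ETA_MAX = float(np.nextafter(1.0, 0.0))


@dataclass(frozen=True)
class HyperparameterVector:
    """A concrete, decoded set of the six tuned hyperparameters."""

    n_kernels: int = 50
    kernel_size: int = 10
    activation: int = 0
    dropout: float = 0.2
    learning_rate: float = 1e-3
    pool_size: int = 2

    def __post_init__(self) -> None:
        if not 40 <= self.n_kernels <= 100:
            raise ValueError(f"n_kernels {self.n_kernels} outside 40..100")
        if not 1 <= self.kernel_size <= 20:
            raise ValueError(f"kernel_size {self.kernel_size} outside 1..20")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"activation code {self.activation} not in {{0,1,2}}")
        if not 0.0 <= self.dropout <= 0.6:
            raise ValueError(f"dropout {self.dropout} outside 0..0.6")
        if not 1e-5 <= self.learning_rate < 1.0:
            raise ValueError(f"learning_rate {self.learning_rate} outside [1e-5, 1)")
        if not 2 <= self.pool_size <= 20:
            raise ValueError(f"pool_size {self.pool_size} outside 2..20")

    @property
    def activation_name(self) -> str:
        return ACTIVATIONS[self.activation]


@dataclass(frozen=True)
class Dimension:
    name: str
    kind: str  # integer | categorical | continuous | log-continuous
    low: float
    high: float


@dataclass(frozen=True)
class SpaceDefinition:
    """Ordered search dimensions; order is fixed to [delta, s, a, d, eta, m]."""

    dimensions: tuple[Dimension, ...]

    @property
    def bounds(self) -> list[tuple[float, float]]:
        return [(dim.low, dim.high) for dim in self.dimensions]


def default_space() -> SpaceDefinition:
    """The constrained hyperparameter box, with eta as log10(eta)."""
    return SpaceDefinition(
        dimensions=(
            Dimension("n_kernels", "integer", 40, 100),
            Dimension("kernel_size", "integer", 1, 20),
            Dimension("activation", "categorical", 0, 2),
            Dimension("dropout", "continuous", 0.0, 0.6),
            Dimension("log10_learning_rate", "log-continuous", -5.0, 0.0),
            Dimension("pool_size", "integer", 2, 20),
        )
    )


def decode_position(pos: Sequence[float]) -> HyperparameterVector:
    """Map a raw optimizer 6-vector to a valid hyperparameter vector.

    Coordinates are clipped into the box, integer dimensions rounded
    half-away-from-zero, the activation coordinate rounded to a code in
    {0, 1, 2}, and the fifth coordinate interpreted as log10(eta).
    """
    pos = np.asarray(pos, dtype=float)
    if pos.shape != (6,):
        raise ValueError(f"expected a 6-vector, got shape {pos.shape}")
    space = default_space()
    lo = np.array([d.low for d in space.dimensions])
    hi = np.array([d.high for d in space.dimensions])
    p = np.clip(pos, lo, hi)
    eta = min(10.0 ** p[4], _ETA_MAX)
    return HyperparameterVector(
        n_kernels=int(round_half_away(p[0])),
        kernel_size=int(round_half_away(p[1])),
        activation=int(np.clip(round_half_away(p[2]), 0, 2)),
        dropout=float(p[3]),
        learning_rate=float(eta),
        pool_size=int(round_half_away(p[5])),
    )


def encode_vector(hp: HyperparameterVector) -> np.ndarray:
    """Inverse of :func:`decode_position` up to decode idempotence."""
    return np.array(
        [
            float(hp.n_kernels),
            float(hp.kernel_size),
            float(hp.activation),
            hp.dropout,
            np.log10(hp.learning_rate),
            float(hp.pool_size),
        ]
    )


def activation_name(code: int) -> str:
    """Translate an activation code to its function name."""
    try:
        return ACTIVATIONS[int(code)]
    except (KeyError, TypeError, ValueError):
        raise ValueError(f"activation code must be 0, 1 or 2, got {code!r}") from None


def report_row(hp: HyperparameterVector) -> dict:
    """Render a decoded vector in the conventional six-column report order.

    ``d_index`` is the dropout probability as an integer tenths code
    (round(10*d)), the compact form used in hyperparameter summary tables.
    """
    return {
        "delta": hp.n_kernels,
        "s": hp.kernel_size,
        "a": hp.activation,
        "d": hp.dropout,
        "d_index": int(round_half_away(10.0 * hp.dropout)),
        "eta": hp.learning_rate,
        "m": hp.pool_size,
    }
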
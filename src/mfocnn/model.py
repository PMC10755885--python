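"""Declarative construction of the block-structured 1D-CNN.

The network is six repeated blocks of [Conv1D -> BatchNorm -> Dropout ->
MaxPool] followed by [Flatten -> Dense(softmax)], 26 layers at the defaults.
The first block uses the tuned filter count ``delta``; subsequent blocks
follow the decreasing schedule delta-10, delta-15, delta-20, delta-25,
delta-30 (clamped at one filter), read off the reference architecture and
generalized linearly.  Convolutions are stride-1 with length-preserving
padding; pooling halves (or /m) the length with a *ceiling* convention, so
an odd length L maps to (L+1)//2 rather than L//2 — e.g. 45 -> 23.

Shape inference here is pure arithmetic, independent of the tensor backend;
:func:`instantiate` builds the runnable numpy network, and the two are
cross-checked layer-for-layer in the test-suite.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

from .exceptions import ConfigurationError
from .search_space import HyperparameterVector

__all__ = [
    "LayerSpec",
    "ModelSpec",
    "FILTER_DECREMENTS",
    "build_model_spec",
    "infer_shapes",
    "instantiate",
]

# cumulative filter-count decrements per block relative to delta
FILTER_DECREMENTS = (0, 10, 15, 20, 25, 30)


@dataclass
class LayerSpec:
    kind: str  # conv | batch_norm | dropout | max_pool | flatten | dense
    params: dict = field(default_factory=dict)
    input_shape: Optional[tuple] = None
    output_shape: Optional[tuple] = None


@dataclass
class ModelSpec:
    layers: list[LayerSpec]
    input_len: int = 178
    n_classes: int = 5
    n_blocks: int = 6
    hyperparameters: Optional[HyperparameterVector] = None

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(
            {
                "input_len": self.input_len,
                "n_classes": self.n_classes,
                "n_blocks": self.n_blocks,
                "layers": [
                    {
                        "kind": l.kind,
                        "params": l.params,
                        "input_shape": l.input_shape,
                        "output_shape": l.output_shape,
                    }
                    for l in self.layers
                ],
            },
            indent=indent,
        )


def _filter_schedule(delta: int, n_blocks: int) -> list[int]:
    decs = list(FILTER_DECREMENTS)
    if n_blocks > len(decs):  # extend linearly: -5 per extra block
        decs += [decs[-1] + 5 * (i + 1) for i in range(n_blocks - len(decs))]
    return [max(delta - decs[i], 1) for i in range(n_blocks)]


def build_model_spec(
    hp: HyperparameterVector,
    input_len: int = 178,
    n_classes: int = 5,
    n_blocks: int = 6,
) -> ModelSpec:
    """Assemble the layer list for a hyperparameter vector (shapes unfilled)."""
    if input_len < 1:
        raise ConfigurationError(f"input_len must be >= 1, got {input_len}")
    if n_blocks < 1 or n_classes < 2:
        raise ConfigurationError("need n_blocks >= 1 and n_classes >= 2")
    layers: list[LayerSpec] = []
    for filters in _filter_schedule(hp.n_kernels, n_blocks):
        layers.append(
            LayerSpec(
                "conv",
                {
                    "filters": filters,
                    "kernel_size": hp.kernel_size,
                    "activation": hp.activation_name,
                },
            )
        )
        layers.append(LayerSpec("batch_norm", {}))
        layers.append(LayerSpec("dropout", {"rate": hp.dropout}))
        layers.append(LayerSpec("max_pool", {"pool": hp.pool_size}))
    layers.append(LayerSpec("flatten", {}))
    layers.append(LayerSpec("dense", {"units": n_classes, "activation": "softmax"}))
    spec = ModelSpec(
        layers=layers,
        input_len=input_len,
        n_classes=n_classes,
        n_blocks=n_blocks,
        hyperparameters=hp,
    )
    return infer_shapes(spec)


def infer_shapes(spec: ModelSpec) -> ModelSpec:
    """Fill every layer's input/output shape by pure arithmetic.

    Shapes are (length, channels) tuples until flatten, then (features,).
    Conv preserves length; pooling maps L to ceil(L/m); flatten multiplies.
    """
    shape: tuple = (spec.input_len, 1)
    for layer in spec.layers:
        layer.input_shape = shape
        if layer.kind == "conv":
            shape = (shape[0], layer.params["filters"])
        elif layer.kind in ("batch_norm", "dropout"):
            pass  # identity
        elif layer.kind == "max_pool":
            new_len = math.ceil(shape[0] / layer.params["pool"])
            if new_len < 1:
                raise ConfigurationError(
                    f"sequence length collapsed to {new_len} at a pooling layer"
                )
            shape = (new_len, shape[1])
        elif layer.kind == "flatten":
            shape = (shape[0] * shape[1],)
        elif layer.kind == "dense":
            shape = (layer.params["units"],)
        else:
            raise ConfigurationError(f"unknown layer kind {layer.kind!r}")
        layer.output_shape = shape
    return spec


def instantiate(spec: ModelSpec, seed: int = 0):
    """Build the runnable numpy network for a (shape-inferred) ModelSpec.

    Returns a :class:`mfocnn.nn.Network`: a callable mapping a batch of
    (input_len, 1) signals to a batch of class-probability rows (each
    summing to one).  Weight initialization is seeded.
    """
    import numpy as np

    from . import nn

    if any(l.output_shape is None for l in spec.layers):
        infer_shapes(spec)
    rng = np.random.default_rng(seed)
    layers = []
    for layer in spec.layers:
        in_shape = layer.input_shape
        if layer.kind == "conv":
            layers.append(
                nn.Conv1D(
                    in_channels=in_shape[1],
                    filters=layer.params["filters"],
                    kernel_size=layer.params["kernel_size"],
                    activation=layer.params["activation"],
                    rng=rng,
                )
            )
        elif layer.kind == "batch_norm":
            layers.append(nn.BatchNorm1D(channels=in_shape[1]))
        elif layer.kind == "dropout":
            layers.append(nn.Dropout(layer.params["rate"]))
        elif layer.kind == "max_pool":
            layers.append(nn.MaxPool1D(layer.params["pool"]))
        elif layer.kind == "flatten":
            layers.append(nn.Flatten())
        elif layer.kind == "dense":
            layers.append(nn.DenseSoftmax(in_features=in_shape[0], units=layer.params["units"], rng=rng))
    return nn.Network(layers, seed=seed)
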
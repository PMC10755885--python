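"""Flat key-value run configuration.

The config file is a YAML mapping whose keys are dotted names, e.g.::

    mfo.n_moths: 20
    mfo.max_iter: 30
    train.batch_size: 256
    fitness.search_epochs: 10

Unknown keys are rejected so typos fail fast.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .exceptions import ConfigurationError

__all__ = ["DEFAULTS", "load_config", "dump_config"]

DEFAULTS: dict[str, object] = {
    # moth-flame optimizer
    "mfo.n_moths": 20,
    "mfo.max_iter": 30,
    "mfo.spiral_b": 1.0,
    "mfo.seed": 0,
    # final training
    "train.batch_size": 256,
    "train.epochs": 500,
    "train.val_fraction": 0.1,
    # search-time fitness budget
    "fitness.search_epochs": 10,
    "fitness.batch_size": 256,
    "fitness.max_train_samples": None,
    # synthetic corpus
    "synth.n_segments": 100,
    "synth.n_samples": 4097,
    "synth.fs": 173.61,
    "synth.separability": 1.0,
    # windowing / partitioning
    "data.chunk_len": 178,
    "data.train_fraction": 0.8,
    "data.split_by_segment": False,
    # network structure
    "model.n_blocks": 6,
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Merge defaults, an optional config file, and explicit overrides."""
    cfg = dict(DEFAULTS)
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: expected a flat key-value mapping")
        for key, value in raw.items():
            if key not in DEFAULTS:
                raise ConfigurationError(f"{path}: unknown config key {key!r}")
            cfg[key] = value
    if overrides:
        for key, value in overrides.items():
            if key not in DEFAULTS:
                raise ConfigurationError(f"unknown config key {key!r}")
            if value is not None:
                cfg[key] = value
    return cfg


def dump_config(cfg: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))
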
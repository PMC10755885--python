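"""Plain-text I/O in the Bonn EEG layout: one sample per line, one file per
segment, one directory per subset.

The five Bonn subsets are published as Z, O, N, F and S; the literature
refers to them as A-E in that order, and this module accepts either name for
a subset directory.  File ordering inside a subset is lexicographic so that
dataset row order is deterministic regardless of filesystem listing order.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import DataError
from .windowing import DEFAULT_FS, SUBSET_LABELS, EEGSegment

__all__ = [
    "BONN_FOLDER_ALIASES",
    "read_segment_file",
    "load_subsets",
    "export_corpus",
    "write_manifest",
]

logger = logging.getLogger(__name__)

EXPECTED_SAMPLES = 4097

# canonical letter -> acceptable directory names (original Bonn codes first)
BONN_FOLDER_ALIASES: dict[str, tuple[str, ...]] = {
    "A": ("A", "Z", "SET_A", "setA"),
    "B": ("B", "O", "SET_B", "setB"),
    "C": ("C", "N", "SET_C", "setC"),
    "D": ("D", "F", "SET_D", "setD"),
    "E": ("E", "S", "SET_E", "setE"),
}


def read_segment_file(
    path, subset_label: str | None = None, strict: bool = False
) -> EEGSegment:
    """Parse one ASCII segment file (one numeric sample per line).

    In non-strict mode a sample count other than 4097 only logs a warning,
    because public mirrors of the corpus contain minor formatting variants;
    ``strict=True`` turns the mismatch into an error.
    """
    path = Path(path)
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            try:
                values.append(float(text))
            except ValueError:
                raise DataError(f"{path}:{lineno}: non-numeric sample {text!r}") from None
    if not values:
        raise DataError(f"{path}: empty segment file")
    if len(values) != EXPECTED_SAMPLES:
        msg = f"{path}: {len(values)} samples, expected {EXPECTED_SAMPLES}"
        if strict:
            raise DataError(msg)
        logger.warning(msg)
    return EEGSegment(samples=np.asarray(values), sampling_rate=DEFAULT_FS, subset_label=subset_label)


def _resolve_subset_dir(root: Path, label: str) -> Path:
    for alias in BONN_FOLDER_ALIASES[label]:
        candidate = root / alias
        if candidate.is_dir():
            return candidate
    raise DataError(
        f"subset {label} not found under {root} (tried {BONN_FOLDER_ALIASES[label]})"
    )


def load_subsets(
    root, wanted: Iterable[str] | None = None, strict: bool = False
) -> dict[str, list[EEGSegment]]:
    """Load the requested subsets as {letter: [segments]} in sorted file order."""
    root = Path(root)
    labels = tuple(wanted) if wanted is not None else SUBSET_LABELS
    out: dict[str, list[EEGSegment]] = {}
    for label in labels:
        if label not in BONN_FOLDER_ALIASES:
            raise ValueError(f"unknown subset label {label!r}")
        subset_dir = _resolve_subset_dir(root, label)
        files = sorted(p for p in subset_dir.iterdir() if p.is_file())
        if not files:
            raise DataError(f"subset directory {subset_dir} contains no files")
        out[label] = [read_segment_file(p, subset_label=label, strict=strict) for p in files]
        logger.info("subset %s: %d segments from %s", label, len(out[label]), subset_dir)
    return out


def _write_segment(path: Path, samples: np.ndarray) -> None:
    ints = np.rint(samples).astype(np.int64)
    path.write_text("\n".join(str(v) for v in ints) + "\n")


def export_corpus(corpus, root) -> list[dict]:
    """Write a corpus in Bonn ASCII layout; returns manifest records.

    Integer-valued samples round-trip bit-identically through
    :func:`read_segment_file`.
    """
    root = Path(root)
    records = []
    for label in sorted(corpus.subsets):
        subset_dir = root / label
        subset_dir.mkdir(parents=True, exist_ok=True)
        for i, seg in enumerate(corpus.subsets[label]):
            fname = f"{label}{i:03d}.txt"
            fpath = subset_dir / fname
            _write_segment(fpath, seg.samples)
            digest = hashlib.sha256(fpath.read_bytes()).hexdigest()
            records.append(
                {
                    "subset": label,
                    "filename": f"{label}/{fname}",
                    "n_samples": len(seg),
                    "checksum": digest,
                }
            )
    return records


def write_manifest(records: list[dict], path) -> None:
    pd.DataFrame.from_records(records).to_csv(path, sep="\t", index=False)
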
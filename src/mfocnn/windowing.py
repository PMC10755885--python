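"""Sliding-window segmentation of EEG records and dataset partitioning.

Long single-channel EEG segments (23.6 s, 4097 samples at 173.61 Hz) are cut
into fixed-length, non-overlapping chunks of 178 samples (about one second).
This multiplies the number of training examples and shortens the signal
length a detector needs before it can decide.  4097 samples yield exactly 23
chunks; the trailing 3 samples are discarded.

Labels follow the subset order A..E -> 0..4: A and B are healthy (eyes open /
closed), C and D interictal recordings from epileptogenic brain regions, and
E is ictal (during seizure).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .exceptions import DataError

__all__ = [
    "SUBSET_LABELS",
    "EEGSegment",
    "WindowedDataset",
    "window_segment",
    "build_windowed_dataset",
    "split_dataset",
    "kfold_indices",
    "subset_selector",
]

logger = logging.getLogger(__name__)

SUBSET_LABELS = ("A", "B", "C", "D", "E")
DEFAULT_CHUNK_LEN = 178
DEFAULT_FS = 173.61


@dataclass
class EEGSegment:
    """One single-channel EEG recording segment in microvolts."""

    samples: np.ndarray
    sampling_rate: float = DEFAULT_FS
    subset_label: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.subset_label is not None and self.subset_label not in SUBSET_LABELS:
            raise DataError(f"unknown subset label {self.subset_label!r}")

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class WindowedDataset:
    """Fixed-length chunks with integer class labels.

    ``X`` has one chunk per row; ``y`` holds labels 0..K-1.  When built from
    the five-subset corpus, label k corresponds to subset ``SUBSET_LABELS[k]``.
    """

    X: np.ndarray
    y: np.ndarray
    chunk_len: int = DEFAULT_CHUNK_LEN
    label_names: tuple[str, ...] = field(default=SUBSET_LABELS)
    segment_ids: np.ndarray | None = None  # source segment of each chunk

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise DataError(
                f"X rows ({self.X.shape}) must match label count ({self.y.shape})"
            )
        if self.segment_ids is not None:
            self.segment_ids = np.asarray(self.segment_ids, dtype=int)
            if self.segment_ids.shape != self.y.shape:
                raise DataError("segment_ids must align with labels")

    def __len__(self) -> int:
        return self.X.shape[0]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"X{i + 1}" for i in range(self.X.shape[1])]
        frame = pd.DataFrame(self.X, columns=cols)
        frame["y"] = self.y
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, label_names: tuple[str, ...] = SUBSET_LABELS):
        if "y" not in frame.columns:
            raise DataError("windowed dataset table must contain a 'y' column")
        X = frame.drop(columns="y").to_numpy(dtype=float)
        return cls(X=X, y=frame["y"].to_numpy(), chunk_len=X.shape[1], label_names=label_names)

    def save_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def load_csv(cls, path):
        return cls.from_frame(pd.read_csv(path))


def window_segment(segment, chunk_len: int = DEFAULT_CHUNK_LEN) -> np.ndarray:
    """Cut one segment into consecutive non-overlapping chunks.

    Returns a (n_chunks, chunk_len) array with n_chunks = floor(len/chunk_len);
    the trailing remainder shorter than ``chunk_len`` is discarded, so the
    concatenated chunks reproduce the segment prefix exactly.
    """
    if chunk_len < 1:
        raise ValueError("chunk_len must be >= 1")
    samples = segment.samples if isinstance(segment, EEGSegment) else np.asarray(segment, dtype=float).ravel()
    n_chunks = samples.size // chunk_len
    if n_chunks == 0:
        logger.warning(
            "segment of %d samples shorter than chunk_len=%d; no chunks produced",
            samples.size,
            chunk_len,
        )
        return np.empty((0, chunk_len))
    return samples[: n_chunks * chunk_len].reshape(n_chunks, chunk_len).copy()


def build_windowed_dataset(
    subsets: Mapping[str, Sequence] | Sequence[Sequence],
    chunk_len: int = DEFAULT_CHUNK_LEN,
) -> WindowedDataset:
    """Window every segment of every subset into one labeled dataset.

    ``subsets`` is either a mapping from subset letter to a list of segments
    or a plain sequence of segment lists taken in A..E order.  Labels are
    assigned in that fixed order.  With the full corpus (5 subsets x 100
    segments x 4097 samples) this yields 2300 chunks per subset, 11500 total.
    """
    if isinstance(subsets, Mapping):
        items = [(label, subsets[label]) for label in sorted(subsets)]
    else:
        items = list(zip(SUBSET_LABELS, subsets))
    blocks, labels, names, seg_ids = [], [], [], []
    next_seg = 0
    for class_idx, (name, segments) in enumerate(items):
        names.append(str(name))
        for seg_idx, seg in enumerate(segments):
            samples = seg.samples if isinstance(seg, EEGSegment) else np.asarray(seg).ravel()
            if samples.size < chunk_len:
                raise DataError(
                    f"segment {seg_idx} of subset {name!r} has {samples.size} samples,"
                    f" fewer than chunk_len={chunk_len}"
                )
            chunks = window_segment(samples, chunk_len)
            blocks.append(chunks)
            labels.append(np.full(chunks.shape[0], class_idx, dtype=int))
            seg_ids.append(np.full(chunks.shape[0], next_seg, dtype=int))
            next_seg += 1
    if not blocks:
        raise DataError("no segments supplied")
    return WindowedDataset(
        X=np.vstack(blocks), y=np.concatenate(labels), chunk_len=chunk_len,
        label_names=tuple(names), segment_ids=np.concatenate(seg_ids),
    )


def split_dataset(
    ds: WindowedDataset,
    train_fraction: float = 0.8,
    seed: int = 0,
    by_segment: bool = False,
) -> tuple[WindowedDataset, WindowedDataset]:
    """Stratified train/test split.

    Per class, a seeded shuffle assigns round(train_fraction * class size)
    rows to the training part; the split is disjoint and exhaustive.  With
    ``by_segment=True`` whole source segments are assigned to one side, so no
    recording contributes chunks to both train and test (leakage-free); this
    requires the dataset to carry ``segment_ids``.
    """
    if not 0.0 < train_fraction <= 1.0:
        raise ValueError("train_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    if by_segment:
        if ds.segment_ids is None:
            raise DataError("by_segment split requires segment_ids")
        for cls in np.unique(ds.y):
            segs = np.unique(ds.segment_ids[ds.y == cls])
            perm = rng.permutation(segs)
            n_train = int(round(train_fraction * segs.size))
            in_train = np.isin(ds.segment_ids, perm[:n_train]) & (ds.y == cls)
            in_test = np.isin(ds.segment_ids, perm[n_train:]) & (ds.y == cls)
            train_idx.append(np.nonzero(in_train)[0])
            test_idx.append(np.nonzero(in_test)[0])
    else:
        for cls in np.unique(ds.y):
            rows = np.nonzero(ds.y == cls)[0]
            if rows.size == 0:
                raise DataError(f"class {cls} has no rows")
            perm = rng.permutation(rows)
            n_train = int(round(train_fraction * rows.size))
            train_idx.append(perm[:n_train])
            test_idx.append(perm[n_train:])
    tr = np.sort(np.concatenate(train_idx))
    te = np.sort(np.concatenate(test_idx))

    def make(idx: np.ndarray) -> WindowedDataset:
        return WindowedDataset(
            X=ds.X[idx],
            y=ds.y[idx],
            chunk_len=ds.chunk_len,
            label_names=ds.label_names,
            segment_ids=None if ds.segment_ids is None else ds.segment_ids[idx],
        )

    return make(tr), make(te)


def kfold_indices(y: np.ndarray, k: int = 10, seed: int = 0) -> list[np.ndarray]:
    """Stratified k-fold membership: k disjoint, exhaustive index arrays."""
    y = np.asarray(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise DataError(f"smallest class has {counts.min()} rows, fewer than k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros_like(y), y)]


_GROUP_RE = re.compile(r"^[A-E]+$")


def subset_selector(ds: WindowedDataset, groups: str) -> WindowedDataset:
    """Select and relabel subsets for a sub-experiment like ``"AB vs CDE"``.

    Each side of ``vs`` names one or more of the subsets A-E; rows whose
    original subset belongs to group g are kept and relabeled g (0-based).
    Groups must be disjoint.  Requires a dataset whose labels still carry the
    A..E subset identity (i.e. built from the five-subset corpus).
    """
    parts = [p.strip().upper() for p in re.split(r"(?i)\bvs\.?\b", groups)]
    if len(parts) < 2 or any(not p for p in parts):
        raise ValueError(f"cannot parse group expression {groups!r}")
    seen: set[str] = set()
    for part in parts:
        if not _GROUP_RE.match(part):
            raise ValueError(f"group {part!r} must name subsets A-E only")
        if seen & set(part):
            raise ValueError(f"overlapping groups in {groups!r}")
        seen |= set(part)
    letter_of = {idx: name for idx, name in enumerate(ds.label_names)}
    new_label = {}
    for g, part in enumerate(parts):
        for letter in part:
            new_label[letter] = g
    keep, labels = [], []
    for i, lab in enumerate(ds.y):
        letter = letter_of.get(int(lab))
        if letter in new_label:
            keep.append(i)
            labels.append(new_label[letter])
    if not keep:
        raise DataError(f"no rows match groups {groups!r}")
    keep = np.asarray(keep)
    return WindowedDataset(
        X=ds.X[keep],
        y=np.asarray(labels, dtype=int),
        chunk_len=ds.chunk_len,
        label_names=tuple(parts),
        segment_ids=None if ds.segment_ids is None else ds.segment_ids[keep],
    )
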
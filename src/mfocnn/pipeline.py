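"""End-to-end orchestration: synth -> window -> optimize -> train/eval.

Each stage is a plain function over files plus a :class:`RunManifest` that
records the config snapshot, the derived per-stage seeds, artifact checksums
and timings.  One global seed fans out deterministically to per-stage seeds
(stable CRC mixing), so any stage can be re-run in isolation and two runs
with the same seed produce identical artifacts.  ``resume`` skips a stage
whose artifacts already exist and match their recorded checksums.
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import bonn, mfo, synthetic
from .config import load_config
from .exceptions import ConfigurationError, DataError
from .metrics import EvaluationReport, evaluate_predictions
from .model import build_model_spec
from .search_space import decode_position, default_space, report_row
from .training import (
    FitnessCache,
    FitnessConfig,
    TrainConfig,
    evaluate_fitness,
    stratified_holdout,
    train_model,
)
from .windowing import (
    WindowedDataset,
    build_windowed_dataset,
    kfold_indices,
    split_dataset,
    subset_selector,
)

__all__ = [
    "stage_seed",
    "RunManifest",
    "run_synth",
    "run_window",
    "run_optimize",
    "run_train_eval",
    "run_sweep_batch",
]


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a stable per-stage seed below 2**31 from the global seed."""
    mix = zlib.crc32(stage.encode()) ^ (int(global_seed) * 2654435761)
    return mix % (2**31)


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


class RunManifest:
    """JSON record of a run: config, seeds, per-stage artifacts and timings."""

    def __init__(self, path: str | Path, config: dict | None = None, seed: int | None = None):
        self.path = Path(path)
        if self.path.exists():
            self.data = json.loads(self.path.read_text())
            if config is not None:
                self.data["config"] = _jsonable(config)
            if seed is not None:
                self.data["seed"] = int(seed)
        else:
            self.data = {"config": _jsonable(config or {}), "seed": seed, "stages": {}, "timings": {}}

    def save(self) -> None:
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))

    def record_stage(self, name: str, artifacts: dict[str, str], elapsed: float, **extra) -> None:
        self.data["stages"][name] = {"artifacts": artifacts, **_jsonable(extra)}
        self.data["timings"][name] = round(elapsed, 3)
        self.save()

    def stage_complete(self, name: str) -> bool:
        stage = self.data["stages"].get(name)
        if not stage:
            return False
        for rel, digest in stage["artifacts"].items():
            p = self.path.parent / rel
            if not p.exists() or file_checksum(p) != digest:
                return False
        return True

    def fingerprint(self) -> dict:
        """Everything except wall-clock timings; equal across identical runs."""
        return {k: v for k, v in self.data.items() if k != "timings"}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _artifacts(base: Path, paths: list[Path]) -> dict[str, str]:
    return {str(p.relative_to(base)): file_checksum(p) for p in paths}


def run_synth(
    out_dir: str | Path,
    config: dict | None = None,
    seed: int = 0,
    subsets: str | None = None,
    force: bool = False,
    manifest: RunManifest | None = None,
) -> list[Path]:
    """Generate a synthetic corpus in Bonn ASCII layout plus a manifest table."""
    cfg = config or load_config()
    out_dir = Path(out_dir)
    wanted = tuple(subsets) if subsets else None
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise ConfigurationError(f"output directory {out_dir} not empty (use force)")
    t0 = time.perf_counter()
    corpus = synthetic.generate_corpus(
        n_segments=int(cfg["synth.n_segments"]),
        n_samples=int(cfg["synth.n_samples"]),
        fs=float(cfg["synth.fs"]),
        seed=stage_seed(seed, "synth"),
        separability=float(cfg["synth.separability"]),
    )
    if wanted:
        corpus.subsets = {k: v for k, v in corpus.subsets.items() if k in wanted}
    out_dir.mkdir(parents=True, exist_ok=True)
    records = bonn.export_corpus(corpus, out_dir)
    bonn.write_manifest(records, out_dir / "manifest.tsv")
    written = [out_dir / r["filename"] for r in records] + [out_dir / "manifest.tsv"]
    if manifest is not None:
        manifest.record_stage(
            "synth",
            _artifacts(manifest.path.parent, written),
            time.perf_counter() - t0,
            seed=stage_seed(seed, "synth"),
        )
    return written


def run_window(
    input_dir: str | Path,
    out_csv: str | Path,
    chunk_len: int = 178,
    manifest: RunManifest | None = None,
) -> WindowedDataset:
    """Window a Bonn-layout directory into one labeled CSV table."""
    input_dir = Path(input_dir)
    present = [
        label
        for label in bonn.BONN_FOLDER_ALIASES
        if any((input_dir / a).is_dir() for a in bonn.BONN_FOLDER_ALIASES[label])
    ]
    if not present:
        raise DataError(f"no subset directories found under {input_dir}")
    t0 = time.perf_counter()
    segments = bonn.load_subsets(input_dir, wanted=present)
    ds = build_windowed_dataset(segments, chunk_len=chunk_len)
    out_csv = Path(out_csv)
    out_csv.parent.mkdir(parents=True, exist_ok=True)
    ds.save_csv(out_csv)
    if manifest is not None:
        manifest.record_stage(
            "window",
            _artifacts(manifest.path.parent, [out_csv]),
            time.perf_counter() - t0,
            n_rows=len(ds),
            chunk_len=chunk_len,
        )
    return ds


def run_optimize(
    ds: WindowedDataset,
    config: dict | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    manifest: RunManifest | None = None,
):
    """Run the moth-flame hyperparameter search on a windowed dataset.

    Returns (best HyperparameterVector, OptimizationResult).  Writes the
    iteration trace, the decoded best vector in the six-column report
    format, and the winning architecture description when ``out_dir`` is
    given.
    """
    cfg = config or load_config()
    if int(cfg["fitness.search_epochs"]) < 1:
        raise ConfigurationError("fitness.search_epochs must be >= 1")
    if np.unique(ds.y).size < 2:
        raise DataError("optimization requires at least two classes")
    t0 = time.perf_counter()
    opt_seed = stage_seed(seed, "optimize")
    train, _ = split_dataset(
        ds,
        float(cfg["data.train_fraction"]),
        seed=stage_seed(seed, "split"),
        by_segment=bool(cfg["data.split_by_segment"]) and ds.segment_ids is not None,
    )
    data = stratified_holdout(train.X, train.y, float(cfg["train.val_fraction"]), opt_seed)
    fit_cfg = FitnessConfig(
        search_epochs=int(cfg["fitness.search_epochs"]),
        batch_size=int(cfg["fitness.batch_size"]),
        max_train_samples=cfg["fitness.max_train_samples"],
    )
    cache = FitnessCache()
    n_classes = int(np.unique(ds.y).size)

    def objective(pos):
        return evaluate_fitness(
            decode_position(pos), data, fit_cfg, seed=opt_seed, cache=cache, n_classes=n_classes
        )

    mfo_cfg = mfo.MFOConfig(
        bounds=default_space().bounds,
        n_moths=int(cfg["mfo.n_moths"]),
        max_iter=int(cfg["mfo.max_iter"]),
        spiral_b=float(cfg["mfo.spiral_b"]),
        seed=opt_seed,
    )
    result = mfo.run_mfo(objective, mfo_cfg)
    best_hp = decode_position(result.best_position)
    written = []
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        trace_path = out_dir / "mfo_trace.tsv"
        result.trace.to_csv(trace_path, sep="\t", index=False)
        best_path = out_dir / "best_hyperparameters.tsv"
        pd.DataFrame([report_row(best_hp)]).to_csv(best_path, sep="\t", index=False)
        spec = build_model_spec(best_hp, input_len=ds.chunk_len, n_classes=n_classes,
                                n_blocks=int(cfg["model.n_blocks"]))
        spec_path = out_dir / "model_spec.json"
        spec_path.write_text(spec.to_json())
        written = [trace_path, best_path, spec_path]
    if manifest is not None:
        manifest.record_stage(
            "optimize",
            _artifacts(manifest.path.parent, written),
            time.perf_counter() - t0,
            seed=opt_seed,
            best_fitness=result.best_fitness,
            best_hyperparameters=report_row(best_hp),
        )
    return best_hp, result


def _fit_and_report(train, test, hp, cfg, seed) -> tuple[EvaluationReport, object]:
    spec = build_model_spec(
        hp, input_len=train.chunk_len, n_classes=int(np.unique(train.y).size),
        n_blocks=int(cfg["model.n_blocks"]),
    )
    data = stratified_holdout(train.X, train.y, float(cfg["train.val_fraction"]), seed)
    tcfg = TrainConfig(
        batch_size=min(int(cfg["train.batch_size"]), data[0].shape[0]),
        epochs=int(cfg["train.epochs"]),
        val_fraction=float(cfg["train.val_fraction"]),
        seed=seed,
    )
    net, history = train_model(spec, data, tcfg)
    probs = np.vstack(
        [net(test.X[i : i + 1024, :, None].astype(np.float32)) for i in range(0, len(test), 1024)]
    )
    report = evaluate_predictions(test.y, probs.argmax(axis=1), n_classes=spec.n_classes)
    return report, history


def run_train_eval(
    ds: WindowedDataset,
    hp,
    config: dict | None = None,
    seed: int = 0,
    groups: str | None = None,
    cv: int | None = None,
    out_dir: str | Path | None = None,
    manifest: RunManifest | None = None,
) -> pd.DataFrame:
    """Full training of one hyperparameter vector and held-out evaluation.

    With ``groups`` (e.g. "AB vs CDE") the dataset is first reduced and
    relabeled; with ``cv=k`` a stratified k-fold evaluation replaces the
    single 80-20 split and the returned table carries one row per fold plus
    a mean row.
    """
    cfg = config or load_config()
    t0 = time.perf_counter()
    eval_seed = stage_seed(seed, "train_eval")
    if groups:
        ds = subset_selector(ds, groups)
    label = groups or " vs ".join(ds.label_names)
    rows = []
    if cv:
        folds = kfold_indices(ds.y, k=int(cv), seed=eval_seed)
        for f, test_idx in enumerate(folds):
            mask = np.zeros(len(ds), dtype=bool)
            mask[test_idx] = True
            train = WindowedDataset(ds.X[~mask], ds.y[~mask], ds.chunk_len, ds.label_names)
            test = WindowedDataset(ds.X[mask], ds.y[mask], ds.chunk_len, ds.label_names)
            report, _ = _fit_and_report(train, test, hp, cfg, eval_seed + f)
            frame = report.to_frame(group=f"fold {f + 1}", classes=label)
            rows.append(frame)
        table = pd.concat(rows, ignore_index=True)
        mean_row = table.mean(numeric_only=True).to_dict()
        mean_row.update({"Group": "mean", "Class": label})
        table = pd.concat([table, pd.DataFrame([mean_row])], ignore_index=True)
    else:
        train, test = split_dataset(
            ds,
            float(cfg["data.train_fraction"]),
            seed=stage_seed(seed, "split"),
            by_segment=bool(cfg["data.split_by_segment"]) and ds.segment_ids is not None,
        )
        report, _ = _fit_and_report(train, test, hp, cfg, eval_seed)
        table = report.to_frame(group="holdout", classes=label)
    written = []
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report_path = out_dir / "evaluation.tsv"
        table.to_csv(report_path, sep="\t", index=False)
        written = [report_path]
    if manifest is not None:
        manifest.record_stage(
            "train_eval",
            _artifacts(manifest.path.parent, written),
            time.perf_counter() - t0,
            seed=eval_seed,
            groups=label,
            accuracy=float(table["Accuracy"].iloc[-1]),
        )
    return table


def run_sweep_batch(
    ds: WindowedDataset,
    hp,
    config: dict | None = None,
    seed: int = 0,
    sizes: tuple[int, ...] = (32, 64, 128, 256, 512, 1024),
    epochs: int = 10,
    out_path: str | Path | None = None,
    manifest: RunManifest | None = None,
) -> pd.DataFrame:
    """Loss-curve table across batch sizes for a fixed architecture."""
    from .training import batch_size_sweep

    cfg = config or load_config()
    t0 = time.perf_counter()
    sweep_seed = stage_seed(seed, "sweep")
    train, _ = split_dataset(ds, float(cfg["data.train_fraction"]), seed=stage_seed(seed, "split"))
    data = stratified_holdout(train.X, train.y, float(cfg["train.val_fraction"]), sweep_seed)
    spec = build_model_spec(
        hp, input_len=ds.chunk_len, n_classes=int(np.unique(ds.y).size),
        n_blocks=int(cfg["model.n_blocks"]),
    )
    table = batch_size_sweep(spec, data, sizes=tuple(sizes), epochs=epochs, seed=sweep_seed)
    written = []
    if out_path is not None:
        out_path = Path(out_path)
        out_path.parent.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_path, sep="\t", index=False)
        written = [out_path]
    if manifest is not None:
        manifest.record_stage(
            "sweep_batch",
            _artifacts(manifest.path.parent, written),
            time.perf_counter() - t0,
            sizes=list(sizes),
        )
    return table
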
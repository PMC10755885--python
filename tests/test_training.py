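"""Loss function, checkpointing, fitness caching, and training controls."""

import math

import numpy as np
import pytest

from mfocnn.model import build_model_spec
from mfocnn.search_space import HyperparameterVector
from mfocnn.training import (
    FitnessCache,
    FitnessConfig,
    TrainConfig,
    batch_size_sweep,
    cross_entropy,
    evaluate_fitness,
    stratified_holdout,
    train_model,
)

FAST_HP = HyperparameterVector(
    n_kernels=40, kernel_size=5, activation=0, dropout=0.1, learning_rate=2e-3, pool_size=2
)


def _split(ds, seed=0):
    return stratified_holdout(ds.X, ds.y, 0.15, seed)


class TestCrossEntropy:
    def test_perfect_predictions_zero_loss(self):
        pred = np.eye(3)[[0, 1, 2]]
        assert cross_entropy(pred, [0, 1, 2]) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_five_class_is_ln5(self):
        pred = np.full((4, 5), 0.2)
        assert cross_entropy(pred, [0, 1, 2, 3, 4][:4]) == pytest.approx(math.log(5))

    def test_hand_computed_two_sample_batch(self):
        pred = np.array([[0.5, 0.5], [0.25, 0.75]])
        truth = [0, 0]
        expected = (-math.log(0.5) - math.log(0.25)) / 2
        assert cross_entropy(pred, truth) == pytest.approx(expected)

    def test_zero_probability_clamped_finite(self):
        pred = np.array([[1.0, 0.0]])
        assert np.isfinite(cross_entropy(pred, [1]))


class TestTrainModel:
    def test_single_epoch_history(self, small_two_class):
        data = _split(small_two_class)
        spec = build_model_spec(FAST_HP, n_classes=2, n_blocks=2)
        _, hist = train_model(spec, data, TrainConfig(batch_size=64, epochs=1, seed=0))
        assert len(hist.train_loss) == 1
        assert hist.best_epoch == 0

    def test_checkpoint_dominates_last_epoch(self, small_two_class):
        data = _split(small_two_class)
        spec = build_model_spec(FAST_HP, n_classes=2, n_blocks=2)
        net, hist = train_model(spec, data, TrainConfig(batch_size=64, epochs=8, seed=1))
        assert hist.best_val_accuracy == pytest.approx(max(hist.val_accuracy))
        assert hist.best_val_accuracy >= hist.val_accuracy[-1]
        # restored network reproduces the recorded best validation accuracy
        probs = net(data[2][:, :, None].astype(np.float32))
        acc = (probs.argmax(1) == data[3]).mean()
        assert acc == pytest.approx(hist.best_val_accuracy)

    def test_separable_two_class_learns(self, small_two_class):
        # A vs E differ hugely in amplitude; a short run should be near-perfect
        data = _split(small_two_class)
        spec = build_model_spec(FAST_HP, n_classes=2, n_blocks=2)
        _, hist = train_model(spec, data, TrainConfig(batch_size=64, epochs=10, seed=2))
        assert hist.best_val_accuracy >= 0.95

    def test_seeded_determinism(self, small_two_class):
        data = _split(small_two_class)
        spec = build_model_spec(FAST_HP, n_classes=2, n_blocks=2)
        cfg = TrainConfig(batch_size=64, epochs=3, seed=5)
        _, h1 = train_model(spec, data, cfg)
        _, h2 = train_model(spec, data, cfg)
        assert h1.train_loss == h2.train_loss
        assert h1.val_accuracy == h2.val_accuracy

    def test_chance_floor_on_shuffled_labels(self, mini_dataset):
        # five classes, labels shuffled: accuracy must hover near 20%
        accs = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            y_shuf = rng.permutation(mini_dataset.y)
            data = stratified_holdout(mini_dataset.X, y_shuf, 0.2, seed)
            spec = build_model_spec(FAST_HP, n_classes=5, n_blocks=2)
            _, hist = train_model(spec, data, TrainConfig(batch_size=64, epochs=4, seed=seed))
            accs.append(hist.val_accuracy[-1])
        assert 0.10 <= np.median(accs) <= 0.35


class TestEvaluateFitness:
    def test_no_signal_control_near_chance_loss(self):
        from mfocnn.synthetic import generate_corpus

        corpus = generate_corpus(n_segments=4, seed=3, separability=0.0)
        ds = corpus.to_windowed()
        data = stratified_holdout(ds.X, ds.y, 0.2, 0)
        value = evaluate_fitness(FAST_HP, data, FitnessConfig(search_epochs=3, batch_size=64), seed=0)
        assert value == pytest.approx(math.log(5), abs=0.2)

    def test_learnable_data_beats_chance_loss(self, small_two_class):
        data = _split(small_two_class)
        value = evaluate_fitness(FAST_HP, data, FitnessConfig(search_epochs=5, batch_size=64), seed=0)
        assert value < math.log(2)

    def test_cache_and_determinism(self, small_two_class):
        data = _split(small_two_class)
        cache = FitnessCache()
        cfg = FitnessConfig(search_epochs=2, batch_size=64)
        v1 = evaluate_fitness(FAST_HP, data, cfg, seed=3, cache=cache)
        assert len(cache) == 1
        v2 = evaluate_fitness(FAST_HP, data, cfg, seed=3, cache=cache)
        assert v1 == v2
        v3 = evaluate_fitness(FAST_HP, data, cfg, seed=3)  # no cache: recomputed
        assert v1 == pytest.approx(v3)


class TestBatchSizeSweep:
    def test_two_sizes_tiny_fixture(self, small_two_class):
        data = _split(small_two_class)
        spec = build_model_spec(FAST_HP, n_classes=2, n_blocks=2)
        table = batch_size_sweep(spec, data, sizes=(32, 64), epochs=2, seed=0)
        assert sorted(table["batch_size"].unique()) == [32, 64]
        assert (table.groupby("batch_size").size() == 2).all()

    def test_oversized_batch_rejected(self, small_two_class):
        data = _split(small_two_class)
        spec = build_model_spec(FAST_HP, n_classes=2, n_blocks=2)
        with pytest.raises(ValueError, match="exceeds"):
            batch_size_sweep(spec, data, sizes=(10**6,), epochs=1)

    def test_shared_seed_reproducible_curves(self, small_two_class):
        data = _split(small_two_class)
        spec = build_model_spec(FAST_HP, n_classes=2, n_blocks=2)
        t1 = batch_size_sweep(spec, data, sizes=(32,), epochs=2, seed=4)
        t2 = batch_size_sweep(spec, data, sizes=(32,), epochs=2, seed=4)
        assert t1.equals(t2)
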
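"""Network correctness (gradients), training loop, metrics and slide screening."""

import numpy as np
import pytest

from picslim.classify.data import LabeledDataset, split_dataset
from picslim.classify.network import (
    Adam,
    ClassifierConfig,
    NeuralClassifier,
    _softmax,
    build_network,
)
from picslim.classify.train import (
    ConfusionMatrix,
    evaluate,
    evaluate_holdout_slide,
    marginal_accuracies,
    task_label_names,
    train_classifier,
)
from picslim.synth import FiberTextureParams, generate_labeled_dataset
from picslim.types import TissueClassLabel


def test_backprop_matches_numeric_gradient():
    """Finite-difference check of the full backward pass, dropout disabled."""
    cfg = ClassifierConfig(task="joint", input_shape=(8, 8), dense_units=(6, 5),
                           dropout=0.0, backbone="tinycnn", seed=0)
    rng = np.random.default_rng(0)
    layers = build_network(cfg, rng)
    x = rng.normal(size=(3, 1, 8, 8))
    y = np.array([0, 2, 3])

    def loss_of(params_flat=None):
        out = x
        for l in layers:
            out = l.forward(out, train=False)
        p = _softmax(out)
        return -np.log(p[np.arange(3), y]).mean()

    # analytic grads
    out = x
    for l in layers:
        out = l.forward(out, train=False)
    p = _softmax(out)
    dy = p.copy()
    dy[np.arange(3), y] -= 1
    g = dy / 3
    for l in reversed(layers):
        g = l.backward(g)

    eps = 1e-6
    checked = 0
    for l in layers:
        for param, grad in zip(l.params, l.grads):
            flat = param.ravel()
            gflat = grad.ravel()
            for k in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[k]
                flat[k] = orig + eps
                lp = loss_of()
                flat[k] = orig - eps
                lm = loss_of()
                flat[k] = orig
                num = (lp - lm) / (2 * eps)
                assert abs(num - gflat[k]) < 1e-5 * max(1.0, abs(num))
                checked += 1
    assert checked > 10


class TestConfusionMatrix:
    def test_row_percent_sums_to_100(self):
        cm = ConfusionMatrix(labels=["a", "b"], counts=np.array([[3, 1], [0, 6]]))
        assert np.allclose(cm.row_percent.sum(axis=1), 100.0)

    def test_counts_sum_to_evaluated_items(self):
        y_true = ["a", "b", "a", "b", "a"]
        y_pred = ["a", "a", "a", "b", "b"]
        cm = ConfusionMatrix.from_predictions(y_true, y_pred, ["a", "b"])
        assert cm.counts.sum() == 5
        assert cm.accuracy() == pytest.approx(3 / 5)

    def test_empty_row_percent_zero(self):
        cm = ConfusionMatrix(labels=["a", "b"], counts=np.array([[0, 0], [1, 1]]))
        assert np.all(cm.row_percent[0] == 0.0)


class _StubModel:
    """Fixed-output classifier exposing the NeuralClassifier surface."""

    def __init__(self, task, predict_name):
        self.config = ClassifierConfig(task=task)
        self.class_names = task_label_names(task)
        self._name = predict_name

    def predict_proba(self, images, batch_size=256):
        proba = np.full((len(images), len(self.class_names)), 1e-6)
        proba[:, self.class_names.index(self._name)] = 1.0
        return proba / proba.sum(axis=1, keepdims=True)

    def predict(self, images):
        return np.array([self._name] * len(images), dtype=object)


def four_class_dataset(n_per_class=8, n_slides=2):
    labels, images, slides = [], [], []
    for size in ("AGA", "SGA"):
        for diet in ("CON", "HF"):
            for i in range(n_per_class):
                labels.append(TissueClassLabel(size, diet))
                images.append(np.zeros((4, 4)))
                slides.append(f"{size}-{diet}-s{i % n_slides}")
    return LabeledDataset(images=images, labels=labels, slides=slides)


class TestEvaluate:
    def test_constant_predictor_on_balanced_set(self):
        ds = four_class_dataset()
        ds.split = np.array(["test"] * len(ds), dtype=object)
        res = evaluate(_StubModel("joint", "AGA-CON"), ds, "test")
        assert res.accuracy == pytest.approx(0.25)
        col = res.confusion.labels.index("AGA-CON")
        nonzero_cols = np.flatnonzero(res.confusion.counts.sum(axis=0))
        assert list(nonzero_cols) == [col]

    def test_row_percent_invariant_on_evaluation(self):
        ds = four_class_dataset()
        ds.split = np.array(["test"] * len(ds), dtype=object)
        res = evaluate(_StubModel("diet", "HF"), ds, "test")
        sums = res.confusion.row_percent.sum(axis=1)
        assert np.allclose(sums[res.confusion.counts.sum(axis=1) > 0], 100.0)

    def test_empty_split_rejected(self):
        ds = four_class_dataset()
        ds.split = np.array([""] * len(ds), dtype=object)
        with pytest.raises(ValueError):
            evaluate(_StubModel("diet", "HF"), ds, "test")


class TestHoldoutSlide:
    def test_perfect_predictor_rates(self):
        ds = four_class_dataset()
        slide = "SGA-HF-s1"

        class Perfect(_StubModel):
            def predict(self, images):
                # all images on that slide are SGA-HF
                return np.array(["SGA-HF"] * len(images), dtype=object)

        rates = evaluate_holdout_slide(Perfect("joint", "SGA-HF"), ds, slide)
        assert rates == {"joint": 1.0, "diet": 1.0, "size": 1.0}

    def test_constant_wrong_diet_predictor(self):
        ds = four_class_dataset()
        rates = evaluate_holdout_slide(_StubModel("joint", "SGA-CON"), ds, "SGA-HF-s0")
        assert rates == {"joint": 0.0, "diet": 0.0, "size": 1.0}

    def test_joint_bounded_by_marginals(self):
        rng = np.random.default_rng(0)
        names = task_label_names("joint")
        y_true = [names[i] for i in rng.integers(0, 4, 50)]
        y_pred = [names[i] for i in rng.integers(0, 4, 50)]
        rates = marginal_accuracies(y_true, y_pred)
        assert rates["joint"] <= min(rates["diet"], rates["size"])

    def test_leak_detected(self):
        ds = four_class_dataset()
        ds.split = np.array(["train"] * len(ds), dtype=object)
        with pytest.raises(ValueError, match="leak"):
            evaluate_holdout_slide(_StubModel("joint", "SGA-HF"), ds, "SGA-HF-s0")

    def test_marginal_model_rejected(self):
        ds = four_class_dataset()
        with pytest.raises(ValueError, match="joint"):
            evaluate_holdout_slide(_StubModel("diet", "HF"), ds, "SGA-HF-s0")


@pytest.fixture(scope="module")
def small_dataset():
    params = FiberTextureParams(image_shape=(48, 64), diet_effect=2.5, size_effect=1.0)
    ds = generate_labeled_dataset(params, 20, seed=6)
    return split_dataset(ds, 48, 16, 16, seed=0)


class TestTraining:
    def test_training_is_deterministic(self, small_dataset):
        cfg = ClassifierConfig(task="diet", epochs=1, seed=3, backbone="pooled")
        _, h1 = train_classifier(small_dataset, cfg)
        _, h2 = train_classifier(small_dataset, cfg)
        assert h1.train_loss == h2.train_loss
        assert h1.val_accuracy == h2.val_accuracy

    def test_history_lengths_and_bounds(self, small_dataset):
        cfg = ClassifierConfig(task="diet", epochs=2, seed=3, backbone="pooled")
        model, hist = train_classifier(small_dataset, cfg)
        assert hist.epochs == 2
        assert len(hist.val_loss) == 2
        assert all(0 <= a <= 1 for a in hist.train_accuracy + hist.val_accuracy)

    def test_one_batch_overfit(self):
        params = FiberTextureParams(image_shape=(48, 64), diet_effect=2.0)
        ds = generate_labeled_dataset(params, 2, seed=1)
        ds.split = np.array(["train"] * len(ds), dtype=object)
        cfg = ClassifierConfig(task="diet", epochs=200, batch_size=8, seed=0,
                               augment=False, backbone="pooled")
        _, hist = train_classifier(ds, cfg)
        assert hist.train_accuracy[-1] == 1.0

    def test_missing_split_rejected(self):
        ds = four_class_dataset()
        with pytest.raises(ValueError, match="split"):
            train_classifier(ds, ClassifierConfig(task="diet", epochs=1))

    def test_checkpoint_round_trip(self, small_dataset, tmp_path):
        cfg = ClassifierConfig(task="diet", epochs=1, seed=3, backbone="pooled")
        model, _ = train_classifier(small_dataset, cfg)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = NeuralClassifier.load(path)
        idx = small_dataset.indices("val")
        images = [small_dataset.images[i] for i in idx]
        assert np.allclose(model.predict_proba(images), loaded.predict_proba(images))
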
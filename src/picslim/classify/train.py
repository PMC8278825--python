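"""Training loop, evaluation metrics, confusion matrices, held-out-slide screen.

Three output models share one dataset: ``diet`` (CON vs HF), ``size``
(AGA vs SGA) and ``joint`` (all four classes).  The joint model's
predictions decompose into the two marginals, so joint accuracy can never
exceed either marginal accuracy computed from the same predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from picslim.classify.data import LabeledDataset, augment
from picslim.classify.network import Adam, ClassifierConfig, NeuralClassifier
from picslim.types import TissueClassLabel

__all__ = [
    "TrainingHistory",
    "ConfusionMatrix",
    "EvaluationResult",
    "task_label_names",
    "task_target",
    "train_classifier",
    "evaluate",
    "evaluate_holdout_slide",
]

JOINT_ORDER = ("AGA-CON", "AGA-HF", "SGA-CON", "SGA-HF")


def task_label_names(task: str) -> list[str]:
    """Softmax output order for a task."""
    if task == "diet":
        return ["CON", "HF"]
    if task == "size":
        return ["AGA", "SGA"]
    if task == "joint":
        return list(JOINT_ORDER)
    raise ValueError(f"unknown task {task!r}")


def task_target(label: TissueClassLabel, task: str) -> str:
    """The class name a label maps to under a task."""
    if task == "diet":
        return label.diet
    if task == "size":
        return label.size
    if task == "joint":
        return label.name
    raise ValueError(f"unknown task {task!r}")


@dataclass
class TrainingHistory:
    """Per-epoch accuracy and cross-entropy on the train and validation splits."""

    train_accuracy: list[float] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)

    @property
    def epochs(self) -> int:
        return len(self.train_accuracy)


@dataclass
class ConfusionMatrix:
    """Square confusion matrix: rows = true class, columns = predicted."""

    labels: list[str]
    counts: np.ndarray
    row_percent: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square and match labels")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        row_sums = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.counts / row_sums
        self.row_percent = np.where(row_sums > 0, pct, 0.0)

    @classmethod
    def from_predictions(cls, y_true, y_pred, labels) -> "ConfusionMatrix":
        idx = {name: i for i, name in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
        for t, p in zip(y_true, y_pred):
            counts[idx[t], idx[p]] += 1
        return cls(labels=list(labels), counts=counts)

    def accuracy(self) -> float:
        total = self.counts.sum()
        return float(np.trace(self.counts) / total) if total else 0.0


@dataclass
class EvaluationResult:
    accuracy: float
    loss: float
    confusion: ConfusionMatrix


def _encode(dataset: LabeledDataset, idx: np.ndarray, task: str) -> np.ndarray:
    names = task_label_names(task)
    lut = {n: i for i, n in enumerate(names)}
    return np.array([lut[task_target(dataset.labels[i], task)] for i in idx])


def _eval_arrays(model: NeuralClassifier, images, y: np.ndarray) -> tuple[float, float]:
    proba = model.predict_proba(images)
    acc = float((proba.argmax(axis=1) == y).mean())
    loss = float(-np.log(np.clip(proba[np.arange(len(y)), y], 1e-12, None)).mean())
    return acc, loss


def train_classifier(
    dataset: LabeledDataset,
    config: ClassifierConfig,
) -> tuple[NeuralClassifier, TrainingHistory]:
    """Train the task's network on the dataset's train split.

    Minibatch cross-entropy with Adam; one optional random augmentation
    (180-degree rotation / axis flips) per training image per epoch.  Epoch-end
    accuracies are computed in inference mode (dropout off) on the full train
    and validation splits.  Fully seeded: identical dataset + config reproduce
    the run bit for bit.
    """
    if dataset.split is None:
        raise ValueError("dataset needs a split; call split_dataset first")
    train_idx = dataset.indices("train")
    val_idx = dataset.indices("val")
    if len(train_idx) == 0:
        raise ValueError("empty training split")
    model = NeuralClassifier(config, task_label_names(config.task))
    model.fit_norm([dataset.images[i] for i in train_idx])
    y_train = _encode(dataset, train_idx, config.task)
    y_val = _encode(dataset, val_idx, config.task) if len(val_idx) else None

    x_train = model.preprocess([dataset.images[i] for i in train_idx])
    optimizer = Adam(model.layers, lr=config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xBA7C)))
    history = TrainingHistory()
    n = len(train_idx)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            sel = order[start : start + config.batch_size]
            xb = x_train[sel]
            if config.augment:
                xb = np.stack([augment(img, rng=rng) for img in xb[:, 0]])[:, None]
            model.train_step(xb, y_train[sel], optimizer)
        train_images = [dataset.images[i] for i in train_idx]
        acc, loss = _eval_arrays(model, train_images, y_train)
        history.train_accuracy.append(acc)
        history.train_loss.append(loss)
        if y_val is not None:
            acc, loss = _eval_arrays(model, [dataset.images[i] for i in val_idx], y_val)
            history.val_accuracy.append(acc)
            history.val_loss.append(loss)
    return model, history


def evaluate(
    model: NeuralClassifier,
    dataset: LabeledDataset,
    split: str = "test",
) -> EvaluationResult:
    """Accuracy, mean cross-entropy and confusion matrix on one split."""
    idx = dataset.indices(split) if dataset.split is not None else np.arange(len(dataset))
    if len(idx) == 0:
        raise ValueError(f"split {split!r} is empty")
    task = model.config.task
    names = task_label_names(task)
    if set(model.class_names) != set(names):
        raise ValueError(f"model classes {model.class_names} do not match task {task!r}")
    y = _encode(dataset, idx, task)
    images = [dataset.images[i] for i in idx]
    proba = model.predict_proba(images)
    pred = proba.argmax(axis=1)
    acc = float((pred == y).mean())
    loss = float(-np.log(np.clip(proba[np.arange(len(y)), y], 1e-12, None)).mean())
    cm = ConfusionMatrix.from_predictions(
        [names[t] for t in y], [model.class_names[p] for p in pred], names
    )
    return EvaluationResult(accuracy=acc, loss=loss, confusion=cm)


def marginal_accuracies(result_labels_true, result_labels_pred) -> dict[str, float]:
    """Diet-only / size-only / joint accuracies from joint class names."""
    true_pairs = [tuple(t.split("-")) for t in result_labels_true]
    pred_pairs = [tuple(p.split("-")) for p in result_labels_pred]
    n = len(true_pairs)
    joint = sum(t == p for t, p in zip(true_pairs, pred_pairs)) / n
    size = sum(t[0] == p[0] for t, p in zip(true_pairs, pred_pairs)) / n
    diet = sum(t[1] == p[1] for t, p in zip(true_pairs, pred_pairs)) / n
    return {"joint": joint, "diet": diet, "size": size}


def evaluate_holdout_slide(
    model: NeuralClassifier,
    dataset: LabeledDataset,
    slide: str,
) -> dict[str, float]:
    """Screen a slide that took no part in training or validation.

    Returns the fractions of the slide's images labeled correctly for both
    factors (``joint``), for diet alone and for size alone.  Raises if the
    slide leaked into the train or validation split, or if the model is not
    the joint four-class one (marginal rates need the full prediction).
    """
    if model.config.task != "joint":
        raise ValueError("held-out-slide screening requires the joint four-class model")
    mask = np.array([s == slide for s in dataset.slides])
    if not mask.any():
        raise ValueError(f"slide {slide!r} not present in the dataset")
    if dataset.split is not None:
        leaked = mask & np.isin(dataset.split, ("train", "val"))
        if leaked.any():
            raise ValueError(
                f"slide {slide!r} leaked into training/validation "
                f"({int(leaked.sum())} items)"
            )
    idx = np.flatnonzero(mask)
    y_true = [dataset.labels[i].name for i in idx]
    y_pred = model.predict([dataset.images[i] for i in idx])
    return marginal_accuracies(y_true, list(y_pred))
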
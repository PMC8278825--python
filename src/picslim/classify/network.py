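"""Compact seeded neural network for phase-map classification.

The classification head follows the screening design: two dropout layers at
rate 0.75 wrapped around dense layers, ending in a softmax of 2 units (diet
or size task) or 4 units (joint task).  The feature extractor is pluggable —
``tinycnn`` (two 3x3 conv + average-pool stages) is the desk-scale default,
``pooled`` (block-average downsampling, no learned features) a faster
baseline; any backbone exposing the same layer protocol can be substituted.

Everything is plain numpy with explicit forward/backward passes and an Adam
optimizer, so training is deterministic given the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["ClassifierConfig", "NeuralClassifier", "build_network"]

TASKS = ("diet", "size", "joint")


@dataclass
class ClassifierConfig:
    """Training configuration.

    ``dropout`` defaults to the screening head's 0.75; ``dense_units`` are the
    widths of the two dense layers between the dropouts.  ``fine_tune_all``
    keeps every weight trainable (no frozen backbone); with the compact
    default backbones a frozen variant trains the head only.
    """

    task: str = "diet"
    backbone: str = "tinycnn"
    input_shape: tuple[int, int] = (48, 64)
    dense_units: tuple[int, int] = (128, 64)
    dropout: float = 0.75
    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    augment: bool = True
    fine_tune_all: bool = True

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}, got {self.task!r}")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")

    @property
    def n_classes(self) -> int:
        return 4 if self.task == "joint" else 2


class Layer:
    """Protocol: forward(x, train, rng) -> y; backward(dy) -> dx."""

    params: list
    grads: list

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x, train=False, rng=None):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)  # He init, relu-friendly
        self.W = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.W.T


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout: active only in training mode."""

    def __init__(self, rate: float):
        super().__init__()
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Conv3x3(Layer):
    """3x3 same-padding convolution, stride 1, via im2col."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / (c_in * 9))
        self.W = rng.normal(0.0, scale, size=(c_out, c_in, 3, 3))
        self.b = np.zeros(c_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    @staticmethod
    def _im2col(x: np.ndarray) -> np.ndarray:
        # x (N, C, H, W) -> (N*H*W, C*9) of 3x3 patches, zero-padded
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N, C, H, W, 3, 3)
        n, c, h, w = x.shape
        return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * 9)

    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        n, c, h, w = x.shape
        self._cols = self._im2col(x)
        out = self._cols @ self.W.reshape(len(self.b), -1).T + self.b
        return out.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, dy):
        n, c, h, w = self._shape
        dflat = dy.transpose(0, 2, 3, 1).reshape(n * h * w, -1)
        self.grads[0][...] = (dflat.T @ self._cols).reshape(self.W.shape)
        self.grads[1][...] = dflat.sum(axis=0)
        # dx = full correlation of dy with spatially flipped, channel-swapped W
        w_flip = self.W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (Cin, Cout, 3, 3)
        dyp = np.pad(dy, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = sliding_window_view(dyp, (3, 3), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, -1)
        dx = cols @ w_flip.reshape(c, -1).T
        return dx.reshape(n, h, w, c).transpose(0, 3, 1, 2)


class AvgPool2(Layer):
    """2x2 average pooling, stride 2 (input H, W must be even)."""

    def forward(self, x, train=False, rng=None):
        n, c, h, w = x.shape
        self._shape = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.repeat(np.repeat(dy, 2, axis=2), 2, axis=3) / 4.0


class BlockPool(Layer):
    """Non-learned block-average downsampling by an integer factor."""

    def __init__(self, factor: int):
        super().__init__()
        self.factor = factor

    def forward(self, x, train=False, rng=None):
        n, c, h, w = x.shape
        f = self.factor
        self._shape = x.shape
        return x.reshape(n, c, h // f, f, w // f, f).mean(axis=(3, 5))

    def backward(self, dy):
        f = self.factor
        return np.repeat(np.repeat(dy, f, axis=2), f, axis=3) / (f * f)


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


def build_network(config: ClassifierConfig, rng: np.random.Generator) -> list[Layer]:
    """Assemble backbone + two-dropout classification head."""
    h, w = config.input_shape
    if config.backbone == "tinycnn":
        if h % 4 or w % 4:
            raise ValueError("tinycnn needs input dimensions divisible by 4")
        layers: list[Layer] = [
            Conv3x3(1, 8, rng), ReLU(), AvgPool2(),
            Conv3x3(8, 16, rng), ReLU(), AvgPool2(),
            Flatten(),
        ]
        n_feat = 16 * (h // 4) * (w // 4)
    elif config.backbone == "pooled":
        factor = 4
        if h % factor or w % factor:
            raise ValueError("pooled backbone needs input dimensions divisible by 4")
        layers = [BlockPool(factor), Flatten()]
        n_feat = (h // factor) * (w // factor)
    else:
        raise ValueError(f"unknown backbone {config.backbone!r}")
    d1, d2 = config.dense_units
    layers += [
        Dense(n_feat, d1, rng), ReLU(), Dropout(config.dropout),
        Dense(d1, d2, rng), ReLU(), Dropout(config.dropout),
        Dense(d2, config.n_classes, rng),
    ]
    return layers


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Adam:
    """Adaptive-moment optimizer over all layer parameters."""

    def __init__(self, layers: Sequence[Layer], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = layers
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [[np.zeros_like(p) for p in l.params] for l in layers]
        self.v = [[np.zeros_like(p) for p in l.params] for l in layers]

    def step(self) -> None:
        self.t += 1
        for li, layer in enumerate(self.layers):
            for pi, (p, g) in enumerate(zip(layer.params, layer.grads)):
                m = self.m[li][pi]
                v = self.v[li][pi]
                m[...] = self.b1 * m + (1 - self.b1) * g
                v[...] = self.b2 * v + (1 - self.b2) * g**2
                mhat = m / (1 - self.b1**self.t)
                vhat = v / (1 - self.b2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class NeuralClassifier:
    """A trained (or trainable) network bound to a task and preprocessing.

    ``class_names`` fixes the label order of the softmax outputs;
    ``norm`` holds the (lo, hi) phase range mapped linearly onto [0, 1]
    (computed on the training split; out-of-range values pass through
    unclipped).
    """

    def __init__(self, config: ClassifierConfig, class_names: Sequence[str]):
        self.config = config
        self.class_names = list(class_names)
        if len(self.class_names) != config.n_classes:
            raise ValueError("class_names must match the task's output units")
        self.rng = np.random.default_rng(config.seed)
        self.layers = build_network(config, self.rng)
        self.norm: tuple[float, float] = (0.0, 1.0)

    # -- preprocessing ----------------------------------------------------
    def preprocess(self, images: Sequence[np.ndarray]) -> np.ndarray:
        """Resize to the network input shape and rescale to the train range."""
        from skimage.transform import resize

        h, w = self.config.input_shape
        out = np.empty((len(images), 1, h, w))
        for i, img in enumerate(images):
            if img.shape != (h, w):
                img = resize(img, (h, w), anti_aliasing=True, preserve_range=True)
            out[i, 0] = img
        lo, hi = self.norm
        return (out - lo) / (hi - lo) if hi > lo else out - lo

    def fit_norm(self, images: Sequence[np.ndarray]) -> None:
        lo = min(float(np.min(im)) for im in images)
        hi = max(float(np.max(im)) for im in images)
        self.norm = (lo, hi)

    # -- forward passes ---------------------------------------------------
    def _forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=self.rng)
        return x

    def _backward(self, dy: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    def train_step(self, x: np.ndarray, y: np.ndarray, optimizer: Adam) -> float:
        """One minibatch update; returns the batch cross-entropy."""
        logits = self._forward(x, train=True)
        probs = _softmax(logits)
        n = len(y)
        loss = -np.log(np.clip(probs[np.arange(n), y], 1e-12, None)).mean()
        dy = probs
        dy[np.arange(n), y] -= 1.0
        self._backward(dy / n)
        if self.config.fine_tune_all:
            optimizer.step()
        else:  # head-only: zero backbone grads before stepping
            head_start = next(
                i for i, l in enumerate(self.layers) if isinstance(l, Dense)
            )
            for l in self.layers[:head_start]:
                for g in l.grads:
                    g[...] = 0.0
            optimizer.step()
        return float(loss)

    def predict_proba(self, images: Sequence[np.ndarray], batch_size: int = 256) -> np.ndarray:
        """Class probabilities in ``class_names`` order (dropout inactive)."""
        x = self.preprocess(images)
        outs = []
        for i in range(0, len(x), batch_size):
            outs.append(_softmax(self._forward(x[i : i + batch_size], train=False)))
        return np.concatenate(outs)

    def predict(self, images: Sequence[np.ndarray]) -> np.ndarray:
        """Predicted class names."""
        proba = self.predict_proba(images)
        return np.asarray(self.class_names, dtype=object)[proba.argmax(axis=1)]

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        """Checkpoint weights + config to an .npz file."""
        import json

        arrays = {}
        for li, layer in enumerate(self.layers):
            for pi, p in enumerate(layer.params):
                arrays[f"p_{li}_{pi}"] = p
        arrays["_meta"] = np.array(
            json.dumps(
                {
                    "config": {
                        k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in vars(self.config).items()
                    },
                    "class_names": self.class_names,
                    "norm": list(self.norm),
                }
            )
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "NeuralClassifier":
        import json

        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["_meta"]))
        cfg = meta["config"]
        for k in ("input_shape", "dense_units"):
            cfg[k] = tuple(cfg[k])
        model = cls(ClassifierConfig(**cfg), meta["class_names"])
        model.norm = tuple(meta["norm"])
        for li, layer in enumerate(model.layers):
            for pi in range(len(layer.params)):
                layer.params[pi][...] = data[f"p_{li}_{pi}"]
        return model
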
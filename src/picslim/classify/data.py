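"""Labeled phase-map datasets: container, reproducible splits, augmentation.

Augmentation uses the shape-preserving symmetries of a rectangular frame:
180-degree rotation and the two axis flips.  Because rot180 = flip_x . flip_y,
the group they generate has four distinct elements, so each image has at most
four augmented variants — pixel histograms are invariant under all of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from picslim.types import TissueClassLabel

__all__ = ["LabeledDataset", "split_dataset", "augment", "AUGMENT_OPS"]

AUGMENT_OPS = ("rot180", "flip_x", "flip_y")
SPLIT_NAMES = ("train", "val", "test")


@dataclass
class LabeledDataset:
    """Phase-map images with class labels, source-slide ids and optional split.

    ``split[i]`` is one of ``"train"``, ``"val"``, ``"test"`` or ``""``
    (unassigned); the three named splits are disjoint by construction.
    """

    images: list[np.ndarray]
    labels: list[TissueClassLabel]
    slides: list[str]
    split: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.images)
        if not (len(self.labels) == len(self.slides) == n):
            raise ValueError("images, labels and slides must have equal length")
        if self.split is not None:
            self.split = np.asarray(self.split, dtype=object)
            if len(self.split) != n:
                raise ValueError("split must assign every item")
            bad = set(self.split) - set(SPLIT_NAMES) - {""}
            if bad:
                raise ValueError(f"unknown split names: {bad}")

    def __len__(self) -> int:
        return len(self.images)

    def indices(self, split: str) -> np.ndarray:
        """Indices of the items assigned to a split."""
        if self.split is None:
            raise ValueError("dataset has no split assignment")
        return np.flatnonzero(self.split == split)

    def subset(self, idx: Sequence[int]) -> "LabeledDataset":
        idx = np.asarray(idx, dtype=int)
        return LabeledDataset(
            images=[self.images[i] for i in idx],
            labels=[self.labels[i] for i in idx],
            slides=[self.slides[i] for i in idx],
            split=None if self.split is None else self.split[idx],
        )

    def manifest(self) -> pd.DataFrame:
        """Tabular view (size, diet, slide, split) for CSV export."""
        return pd.DataFrame(
            {
                "index": np.arange(len(self)),
                "size": [l.size for l in self.labels],
                "diet": [l.diet for l in self.labels],
                "slide": self.slides,
                "split": self.split if self.split is not None else [""] * len(self),
            }
        )


def _stratified_quota(n: int, class_order: list, rng: np.random.Generator) -> dict:
    """Split a quota of n as evenly as possible across classes; remainder
    assigned to a seeded random subset of classes."""
    k = len(class_order)
    base, rem = divmod(n, k)
    quota = {c: base for c in class_order}
    for c in rng.permutation(k)[:rem]:
        quota[class_order[c]] += 1
    return quota


def split_dataset(
    dataset: LabeledDataset,
    n_train: int,
    n_val: int,
    n_test: int,
    seed: int = 0,
    stratify: bool = True,
) -> LabeledDataset:
    """Assign a reproducible random train/val/test split.

    With ``stratify=True`` each split's quota is balanced across the classes
    as evenly as the counts allow.  Items beyond the three quotas stay
    unassigned.  Returns a new dataset sharing the image arrays.
    """
    n = len(dataset)
    if n_train + n_val + n_test > n:
        raise ValueError(
            f"requested {n_train}+{n_val}+{n_test} items from a dataset of {n}"
        )
    rng = np.random.default_rng(seed)
    split = np.array([""] * n, dtype=object)
    if not stratify:
        order = rng.permutation(n)
        bounds = np.cumsum([n_train, n_val, n_test])
        for name, lo, hi in zip(SPLIT_NAMES, [0, *bounds[:-1]], bounds):
            split[order[lo:hi]] = name
    else:
        class_order = sorted({l.name for l in dataset.labels})
        by_class = {
            c: rng.permutation([i for i, l in enumerate(dataset.labels) if l.name == c])
            for c in class_order
        }
        cursors = {c: 0 for c in class_order}
        for name, quota_n in zip(SPLIT_NAMES, (n_train, n_val, n_test)):
            quota = _stratified_quota(quota_n, class_order, rng)
            for c in class_order:
                lo, hi = cursors[c], cursors[c] + quota[c]
                if hi > len(by_class[c]):
                    raise ValueError(
                        f"class {c!r} has only {len(by_class[c])} items; "
                        "cannot satisfy the stratified quotas"
                    )
                split[by_class[c][lo:hi]] = name
                cursors[c] = hi
    return LabeledDataset(
        images=dataset.images, labels=dataset.labels, slides=dataset.slides, split=split
    )


def augment(
    image: np.ndarray,
    ops: Sequence[str] = AUGMENT_OPS,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Randomly augment one image: each op applied independently with p = 1/2.

    ``flip_x`` mirrors across the vertical axis (reverses columns), ``flip_y``
    across the horizontal axis (reverses rows), ``rot180`` rotates by 180
    degrees — all shape-preserving on rectangular frames.
    """
    rng = np.random.default_rng() if rng is None else rng
    out = image
    for op in ops:
        if op not in AUGMENT_OPS:
            raise ValueError(f"unknown op {op!r}; valid: {AUGMENT_OPS}")
        if rng.random() < 0.5:
            if op == "rot180":
                out = out[::-1, ::-1]
            elif op == "flip_x":
                out = out[:, ::-1]
            else:
                out = out[::-1, :]
    return np.ascontiguousarray(out)
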
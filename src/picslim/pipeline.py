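"""End-to-end pipeline runner with validated config and structured logging.

A run executes, as requested: synthetic tissue generation -> interferogram
simulation -> phase reconstruction -> quantification (dry mass, histograms,
pairwise overlaps) -> classifier training -> evaluation.  Every stage logs
its seed, parameters and output hashes as line-delimited JSON, and all
randomness flows from the single config seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from picslim import quantify
from picslim.classify import ClassifierConfig, split_dataset, train_classifier, evaluate
from picslim.classify.train import evaluate_holdout_slide
from picslim.optics import reconstruct_phase
from picslim.synth import (
    CLASS_LABELS,
    FiberTextureParams,
    generate_interferogram_dataset,
    generate_labeled_dataset,
)
from picslim.types import PhaseMap

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    out_dir: str
    seed: int = 0
    n_per_class: int = 12
    image_shape: tuple[int, int] = (96, 128)
    size_effect: float = 1.5
    diet_effect: float = 1.3
    beta_scale: float = 0.5
    camera_noise_sd: float = 0.0
    wavelength: float = quantify.DEFAULT_WAVELENGTH_UM
    refractive_increment: float = quantify.DEFAULT_REFRACTIVE_INCREMENT
    n_bins: int = 64
    task: str = "diet"
    epochs: int = 4
    batch_size: int = 16
    learning_rate: float = 1e-3
    holdout_slide: str | None = None
    stages: tuple[str, ...] = ("synth", "optics", "quantify", "classify")

    def __post_init__(self) -> None:
        for name in ("wavelength", "refractive_increment"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.beta_scale <= 1:
            raise ValueError("beta_scale must lie in (0, 1]")
        unknown = set(self.stages) - {"synth", "optics", "quantify", "classify"}
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        for key in ("image_shape", "stages"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                k: list(v) if isinstance(v, tuple) else v
                for k, v in vars(self).items()
                if k != "out_dir"  # hash covers the science, not the destination
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _hash_array(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


class _RunLog:
    def __init__(self, path: Path, config: RunConfig):
        self.path = path
        self.config_hash = config.config_hash()
        self.path.write_text("")

    def event(self, stage: str, **fields) -> None:
        rec = {"time": time.time(), "stage": stage, "config": self.config_hash, **fields}
        with self.path.open("a") as fh:
            fh.write(json.dumps(rec) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns a summary dict (also on disk).

    Any stage failure aborts with the stage name attached to the exception.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _RunLog(out / "log.jsonl", config)
    summary: dict = {"config_hash": config.config_hash(), "seed": config.seed}
    params = FiberTextureParams(
        image_shape=config.image_shape,
        size_effect=config.size_effect,
        diet_effect=config.diet_effect,
        seed=config.seed,
    )
    stage = "synth"
    try:
        dataset = generate_labeled_dataset(params, config.n_per_class, seed=config.seed)
        log.event(stage, n_items=len(dataset), seed=config.seed,
                  data_hash=_hash_array(np.stack(dataset.images)))
        summary["n_items"] = len(dataset)

        if "optics" in config.stages:
            stage = "optics"
            records = generate_interferogram_dataset(
                params, max(1, config.n_per_class // 4),
                beta_scale=config.beta_scale,
                noise_sd=config.camera_noise_sd, seed=config.seed,
            )
            errs = []
            for rec in records:
                pm = reconstruct_phase(rec.stack)
                oracle = np.angle(1.0 + config.beta_scale * np.exp(1j * rec.truth.delta_phi))
                errs.append(float(np.sqrt(np.mean((pm.phi - oracle) ** 2))))
            summary["reconstruction_rms_error"] = float(np.mean(errs))
            log.event(stage, n_stacks=len(records), rms_error=summary["reconstruction_rms_error"])

        if "quantify" in config.stages:
            stage = "quantify"
            edges = np.linspace(-0.5, 3.0, config.n_bins + 1)
            by_class = {
                lbl.name: [
                    PhaseMap(phi=dataset.images[i], pixel_pitch=0.157)
                    for i in range(len(dataset))
                    if dataset.labels[i] == lbl
                ]
                for lbl in CLASS_LABELS
            }
            overlaps = quantify.group_pairwise_overlaps(by_class, edges)
            rows = [{"class_a": a, "class_b": b, "overlap": v} for (a, b), v in overlaps.items()]
            pd.DataFrame(rows).to_csv(out / "overlaps.csv", index=False)
            pm0 = by_class[CLASS_LABELS[0].name][0]
            mass = quantify.phase_to_dry_mass(pm0, config.wavelength, config.refractive_increment)
            mask = quantify.myelin_mask(pm0, method="otsu")
            stats = quantify.masked_dry_mass_stats(mass, mask)
            (out / "drymass.json").write_text(json.dumps(stats, indent=2))
            summary["overlaps"] = {f"{a}|{b}": v for (a, b), v in overlaps.items()}
            summary["drymass_example"] = stats
            log.event(stage, n_pairs=len(overlaps))

        if "classify" in config.stages:
            stage = "classify"
            if config.holdout_slide is not None:
                # keep the held-out slide entirely out of the split
                keep = np.flatnonzero(
                    np.array(dataset.slides, dtype=object) != config.holdout_slide
                )
                sub = dataset.subset(keep)
                n = len(sub)
                n_train, n_val = int(0.6 * n), int(0.2 * n)
                sub = split_dataset(sub, n_train, n_val, n - n_train - n_val,
                                    seed=config.seed, stratify=False)
                full_split = np.array([""] * len(dataset), dtype=object)
                full_split[keep] = sub.split
                dataset.split = full_split
            else:
                n = len(dataset)
                n_train = int(0.6 * n)
                n_val = int(0.2 * n)
                n_test = n - n_train - n_val
                dataset = split_dataset(dataset, n_train, n_val, n_test,
                                        seed=config.seed, stratify=False)
            dataset.manifest().to_csv(out / "manifest.csv", index=False)
            cfg = ClassifierConfig(
                task=config.task, epochs=config.epochs, batch_size=config.batch_size,
                learning_rate=config.learning_rate, seed=config.seed,
            )
            model, history = train_classifier(dataset, cfg)
            result = evaluate(model, dataset, "test")
            model.save(out / "model.npz")
            metrics = {
                "task": config.task,
                "history": vars(history),
                "test_accuracy": result.accuracy,
                "test_loss": result.loss,
            }
            (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
            cm = result.confusion
            pd.DataFrame(cm.counts, index=cm.labels, columns=cm.labels).to_csv(
                out / "confusion_counts.csv"
            )
            pd.DataFrame(cm.row_percent, index=cm.labels, columns=cm.labels).to_csv(
                out / "confusion_row_percent.csv"
            )
            summary["test_accuracy"] = result.accuracy
            summary["test_loss"] = result.loss
            log.event(stage, test_accuracy=result.accuracy, epochs=cfg.epochs)
            if config.holdout_slide is not None and config.task == "joint":
                rates = evaluate_holdout_slide(model, dataset, config.holdout_slide)
                summary["holdout"] = rates
                log.event("holdout", slide=config.holdout_slide, **rates)
    except Exception as exc:
        log.event(stage, error=str(exc))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
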
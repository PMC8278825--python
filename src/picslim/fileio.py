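"""TIFF/PNG image IO with JSON sidecar metadata.

Phase maps are stored as 32-bit float TIFF in radians; intensity frames as
16-bit unsigned with a recorded scale factor.  Acquisition metadata (pixel
pitch um, wavelength, units, provenance) travels in a ``<file>.json`` sidecar
next to the image, which is more portable than vendor TIFF tags.  A
four-frame interferogram stack is a 4-page TIFF (or four ``_f0/_f90/_f180/
_f270`` files).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from picslim.types import InterferogramStack, PhaseMap

__all__ = [
    "read_image",
    "write_image",
    "write_phase_map",
    "read_phase_map",
    "write_stack",
    "read_stack",
]

FRAME_SUFFIXES = ("_f0", "_f90", "_f180", "_f270")


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_image(path, image: np.ndarray, metadata: dict | None = None) -> None:
    """Write a 2-D (or paged 3-D) array as TIFF/PNG with a JSON sidecar.

    Float arrays go out as float32 (lossless round trip for phase data);
    integer arrays keep their dtype.
    """
    path = Path(path)
    image = np.asarray(image)
    if path.suffix.lower() in (".tif", ".tiff"):
        out = image.astype(np.float32) if np.issubdtype(image.dtype, np.floating) else image
        tifffile.imwrite(path, out, photometric="minisblack")
    elif path.suffix.lower() == ".png":  # preview only
        from PIL import Image

        lo, hi = float(image.min()), float(image.max())
        scaled = np.zeros_like(image, dtype=np.uint8) if hi == lo else (
            (255 * (image - lo) / (hi - lo)).astype(np.uint8)
        )
        Image.fromarray(scaled).save(path)
    else:
        raise ValueError(f"unsupported format: {path.suffix!r} (use .tif/.tiff/.png)")
    if metadata is not None:
        _sidecar(path).write_text(json.dumps(metadata, indent=2, sort_keys=True))


def read_image(path) -> tuple[np.ndarray, dict]:
    """Read an image and its sidecar metadata (empty dict if none)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        image = tifffile.imread(path)
    elif path.suffix.lower() == ".png":
        from PIL import Image

        image = np.asarray(Image.open(path))
    else:
        raise ValueError(f"unsupported format: {path.suffix!r}")
    sc = _sidecar(path)
    metadata = json.loads(sc.read_text()) if sc.exists() else {}
    return image, metadata


def write_phase_map(path, phase: PhaseMap) -> None:
    meta = dict(phase.metadata)
    meta.update({"pixel_pitch_um": phase.pixel_pitch, "units": "radians", "kind": "phase"})
    write_image(path, phase.phi, meta)


def read_phase_map(path) -> PhaseMap:
    image, meta = read_image(path)
    return PhaseMap(
        phi=np.asarray(image, dtype=float),
        pixel_pitch=float(meta.get("pixel_pitch_um", 1.0)),
        metadata=meta,
    )


def write_stack(path, stack: InterferogramStack, scale: float | None = None) -> None:
    """Write a four-frame stack as a 4-page TIFF.

    With ``scale`` given, frames are stored as 16-bit unsigned after
    multiplication by ``scale`` (recorded in the sidecar); otherwise as
    float32.
    """
    path = Path(path)
    meta = {
        "pixel_pitch_um": stack.pixel_pitch,
        "kind": "interferogram_stack",
        "modulations_rad": [0.0, np.pi / 2, np.pi, 3 * np.pi / 2],
    }
    if scale is not None:
        frames = np.clip(stack.frames * scale, 0, 65535).astype(np.uint16)
        meta["intensity_scale"] = scale
        tifffile.imwrite(path, frames, photometric="minisblack")
    else:
        tifffile.imwrite(path, stack.frames.astype(np.float32), photometric="minisblack")
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_stack(path) -> InterferogramStack:
    """Read a 4-page TIFF stack (or the four ``_f*`` single frames)."""
    path = Path(path)
    if path.exists():
        frames, meta = read_image(path)
        if frames.ndim != 3 or frames.shape[0] != 4:
            raise ValueError(f"{path} is not a four-page stack (shape {frames.shape})")
    else:
        parts = [path.with_name(path.stem + sfx + path.suffix) for sfx in FRAME_SUFFIXES]
        missing = [p.name for p in parts if not p.exists()]
        if missing:
            raise FileNotFoundError(f"stack {path} not found and frames missing: {missing}")
        imgs, meta = zip(*(read_image(p) for p in parts))
        frames, meta = np.stack(imgs), meta[0]
    frames = np.asarray(frames, dtype=float)
    if "intensity_scale" in meta:
        frames = frames / float(meta["intensity_scale"])
    return InterferogramStack(frames=frames, pixel_pitch=float(meta.get("pixel_pitch_um", 1.0)))
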
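"""Slide-scan planning, focus interpolation, tiling and mosaic stitching.

A whole-slide SLIM scan rasters an ``n_rows x n_cols`` grid of camera frames
(1624 x 1224 px natively) with lateral steps smaller than the frame, leaving
overlap strips for stitching.  Focus is set at the four corners of the
scanned area and interpolated bilinearly to every tile position.

Coordinate convention: row-major, origin top-left, y downward, 0-based
indices, half-open crop intervals.  Note on the native geometry: with a
1624 x 1224 px frame, steps of 1580 and 1180 (read in pixels) leave 44-px
overlap strips on both axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["ScanPlan", "TileRecord", "plan_scan", "interpolate_focus", "tile_image", "stitch"]

BLEND_MODES = ("overwrite", "average", "feather")


@dataclass
class ScanPlan:
    """Geometry of a tiled scan.

    ``corner_focus`` holds the four focus z-values (um) in the order
    (top-left, top-right, bottom-left, bottom-right).
    """

    n_rows: int
    n_cols: int
    tile_shape: tuple[int, int]  # (height, width) px
    step_x: int
    step_y: int
    corner_focus: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    pixel_pitch: float = 1.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        th, tw = self.tile_shape
        if th < 1 or tw < 1:
            raise ValueError("tile dimensions must be >= 1")
        if self.step_y > th or self.step_x > tw:
            raise ValueError(
                f"no overlap: steps ({self.step_y}, {self.step_x}) exceed tile shape {self.tile_shape}"
            )
        if self.step_x < 1 or self.step_y < 1:
            raise ValueError("steps must be >= 1")
        if len(self.corner_focus) != 4:
            raise ValueError("corner_focus needs exactly four values (TL, TR, BL, BR)")

    @property
    def overlap(self) -> tuple[int, int]:
        """Overlap (y, x) in pixels between adjacent tiles."""
        return self.tile_shape[0] - self.step_y, self.tile_shape[1] - self.step_x

    @property
    def mosaic_shape(self) -> tuple[int, int]:
        return (
            self.step_y * (self.n_rows - 1) + self.tile_shape[0],
            self.step_x * (self.n_cols - 1) + self.tile_shape[1],
        )


@dataclass
class TileRecord:
    """One tile of a scan: grid position, mosaic origin, focus, optional image."""

    row: int
    col: int
    origin: tuple[int, int]  # (y, x) px in mosaic coordinates
    focus_z: float
    image: np.ndarray | None = None


def interpolate_focus(
    corner_focus: Sequence[float], u: float, v: float
) -> float:
    """Bilinear focus at fractional position (u across columns, v across rows).

    Reproduces the corners exactly: (0,0) -> TL, (1,0) -> TR, (0,1) -> BL,
    (1,1) -> BR.
    """
    if not (0.0 <= u <= 1.0 and 0.0 <= v <= 1.0):
        raise ValueError(f"(u, v) must lie in [0, 1]^2, got ({u}, {v})")
    z_tl, z_tr, z_bl, z_br = corner_focus
    return float(
        (1 - u) * (1 - v) * z_tl + u * (1 - v) * z_tr + (1 - u) * v * z_bl + u * v * z_br
    )


def plan_scan(
    n_rows: int,
    n_cols: int,
    tile_shape: tuple[int, int] = (1224, 1624),
    step_x: int = 1580,
    step_y: int = 1180,
    corner_focus: Sequence[float] = (0.0, 0.0, 0.0, 0.0),
    pixel_pitch: float = 1.0,
) -> tuple[ScanPlan, list[TileRecord]]:
    """Lay out an ``n_rows x n_cols`` scan with interpolated focus per tile.

    Tiles come back in row-major order with origins on the planned grid and
    focus from the bilinear blend of the four corner values (a 1x1 grid sits
    at the top-left corner).
    """
    plan = ScanPlan(
        n_rows=n_rows,
        n_cols=n_cols,
        tile_shape=tuple(tile_shape),
        step_x=step_x,
        step_y=step_y,
        corner_focus=tuple(corner_focus),
        pixel_pitch=pixel_pitch,
    )
    tiles = []
    for r in range(n_rows):
        v = r / (n_rows - 1) if n_rows > 1 else 0.0
        for c in range(n_cols):
            u = c / (n_cols - 1) if n_cols > 1 else 0.0
            tiles.append(
                TileRecord(
                    row=r,
                    col=c,
                    origin=(r * step_y, c * step_x),
                    focus_z=interpolate_focus(plan.corner_focus, u, v),
                )
            )
    return plan, tiles


def tile_image(image: np.ndarray, plan: ScanPlan) -> list[TileRecord]:
    """Cut a large field into the plan's tiles (exact crops, row-major).

    The inverse of :func:`stitch` on the covered region; used to exercise the
    stitcher without stage hardware.
    """
    image = np.asarray(image)
    th, tw = plan.tile_shape
    req_h, req_w = plan.mosaic_shape
    if image.shape[0] < req_h or image.shape[1] < req_w:
        raise ValueError(
            f"image {image.shape} too small for plan; needs at least ({req_h}, {req_w})"
        )
    _, records = plan_scan(
        plan.n_rows, plan.n_cols, plan.tile_shape, plan.step_x, plan.step_y,
        plan.corner_focus, plan.pixel_pitch,
    )
    for rec in records:
        y, x = rec.origin
        rec.image = image[y : y + th, x : x + tw].copy()
    return records


def _feather_weight(plan: ScanPlan, row: int, col: int) -> np.ndarray:
    """Separable linear ramp over the overlap strips facing a neighbor."""
    th, tw = plan.tile_shape
    ov_y, ov_x = plan.overlap
    wy = np.ones(th)
    wx = np.ones(tw)
    if ov_y > 0:
        ramp = np.arange(1, ov_y + 1) / (ov_y + 1)
        if row > 0:
            wy[:ov_y] = ramp
        if row < plan.n_rows - 1:
            wy[-ov_y:] = ramp[::-1]
    if ov_x > 0:
        ramp = np.arange(1, ov_x + 1) / (ov_x + 1)
        if col > 0:
            wx[:ov_x] = ramp
        if col < plan.n_cols - 1:
            wx[-ov_x:] = ramp[::-1]
    return np.outer(wy, wx)


def stitch(
    tiles: Sequence[TileRecord],
    plan: ScanPlan,
    blend: str = "feather",
) -> np.ndarray:
    """Assemble a complete grid of tiles into one mosaic.

    Blend modes for overlap strips: ``overwrite`` (later tile wins, row-major),
    ``average`` (unweighted mean of contributing tiles), ``feather`` (linear
    ramp across the overlap).  Where overlapping tiles agree exactly all modes
    return that value, so consistent tiles round-trip bit-exactly.
    """
    if blend not in BLEND_MODES:
        raise ValueError(f"unknown blend {blend!r}; expected one of {BLEND_MODES}")
    by_pos = {(t.row, t.col): t for t in tiles if t.image is not None}
    for r in range(plan.n_rows):
        for c in range(plan.n_cols):
            if (r, c) not in by_pos:
                raise ValueError(f"missing tile at (row, col) = ({r}, {c})")
    th, tw = plan.tile_shape
    mosaic = np.zeros(plan.mosaic_shape)
    if blend == "overwrite":
        for r in range(plan.n_rows):
            for c in range(plan.n_cols):
                t = by_pos[(r, c)]
                y, x = r * plan.step_y, c * plan.step_x
                mosaic[y : y + th, x : x + tw] = t.image
        return mosaic
    weight = np.zeros(plan.mosaic_shape)
    for r in range(plan.n_rows):
        for c in range(plan.n_cols):
            t = by_pos[(r, c)]
            y, x = r * plan.step_y, c * plan.step_x
            w = _feather_weight(plan, r, c) if blend == "feather" else np.ones((th, tw))
            mosaic[y : y + th, x : x + tw] += w * t.image
            weight[y : y + th, x : x + tw] += w
    return mosaic / weight
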
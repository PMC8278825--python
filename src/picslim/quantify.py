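"""Dry-mass densitometry, stain normalization, myelin masks and phase histograms.

Phase converts to dry-mass surface density through the refractive increment:
``rho = lambda * phi / (2 pi gamma)`` with ``lambda`` the central illumination
wavelength (um) and ``gamma ~ 0.2 um^3/pg`` the standard protein/lipid
refractive increment.  Group comparisons pool pixels per class into
histograms; the pairwise histogram-intersection coefficient
``sum_i min(p_i, q_i)`` quantifies how much the class distributions overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from skimage.filters import threshold_otsu

from picslim.types import PhaseMap

__all__ = [
    "DryMassMap",
    "MyelinMask",
    "PhaseHistogram",
    "stain_normalize",
    "phase_to_dry_mass",
    "myelin_mask",
    "masked_dry_mass_stats",
    "phase_histogram",
    "histogram_overlap",
    "group_pairwise_overlaps",
    "DEFAULT_WAVELENGTH_UM",
    "DEFAULT_REFRACTIVE_INCREMENT",
    "DEFAULT_BIN_EDGES",
]

logger = logging.getLogger(__name__)

#: Central wavelength of the broadband white-light illumination (um).
DEFAULT_WAVELENGTH_UM = 0.55
#: Protein/lipid refractive increment (um^3/pg), ~0.2 mL/g.
DEFAULT_REFRACTIVE_INCREMENT = 0.2
#: Default histogram binning: 256 uniform bins over -0.5..3.0 rad.
DEFAULT_BIN_EDGES = np.linspace(-0.5, 3.0, 257)


@dataclass
class DryMassMap:
    """Dry-mass surface density map, pg/um^2."""

    density: np.ndarray
    wavelength: float
    refractive_increment: float
    pixel_pitch: float = 1.0

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        if not np.all(np.isfinite(self.density)):
            raise ValueError("density must be finite")
        if self.wavelength <= 0 or self.refractive_increment <= 0:
            raise ValueError("wavelength and refractive_increment must be positive")


@dataclass
class MyelinMask:
    """Binary myelin mask with the phase threshold that produced it."""

    mask: np.ndarray
    threshold: float
    method: str

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class PhaseHistogram:
    """Pooled pixel histogram of phase values."""

    bin_edges: np.ndarray
    counts: np.ndarray
    normalized: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValueError("len(counts) must equal len(bin_edges) - 1")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        total = self.counts.sum()
        self.normalized = self.counts / total if total > 0 else np.zeros_like(self.counts, float)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def stain_normalize(phase: PhaseMap, gain: float, offset: float = 0.0) -> PhaseMap:
    """Apply the global affine stain correction ``phi' = gain * phi + offset``.

    Histological stains (LFB here) add optical path length; this removes their
    first-order effect so phase maps from stained and unstained sections are
    comparable.  The coefficients applied are recorded in the output metadata.
    """
    if gain == 0:
        raise ValueError("gain must be nonzero")
    meta = dict(phase.metadata)
    meta["stain_normalization"] = {"gain": gain, "offset": offset}
    return PhaseMap(
        phi=gain * phase.phi + offset,
        pixel_pitch=phase.pixel_pitch,
        beta=phase.beta,
        valid=phase.valid,
        metadata=meta,
    )


def phase_to_dry_mass(
    phase: PhaseMap,
    wavelength: float = DEFAULT_WAVELENGTH_UM,
    refractive_increment: float = DEFAULT_REFRACTIVE_INCREMENT,
) -> DryMassMap:
    """Convert phase (rad) to dry-mass surface density rho (pg/um^2)."""
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    if refractive_increment <= 0:
        raise ValueError("refractive_increment must be positive")
    density = wavelength * phase.phi / (2.0 * np.pi * refractive_increment)
    return DryMassMap(
        density=density,
        wavelength=wavelength,
        refractive_increment=refractive_increment,
        pixel_pitch=phase.pixel_pitch,
    )


def myelin_mask(
    phase: PhaseMap,
    method: str = "otsu",
    threshold: float | None = None,
) -> MyelinMask:
    """Binary myelin mask: True where ``phi >= threshold``.

    ``method="fixed"`` uses the supplied threshold; ``method="otsu"`` selects
    it by between-class variance maximization on the phase histogram.  A
    constant image has no Otsu threshold — the mask is all-False and a warning
    is logged.
    """
    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires a threshold")
        thr = float(threshold)
    elif method == "otsu":
        if np.ptp(phase.phi) == 0:
            logger.warning("constant phase map: Otsu threshold undefined, mask all-False")
            return MyelinMask(mask=np.zeros(phase.shape, bool), threshold=np.inf, method=method)
        thr = float(threshold_otsu(phase.phi))
    else:
        raise ValueError(f"unknown method {method!r}; expected 'fixed' or 'otsu'")
    return MyelinMask(mask=phase.phi >= thr, threshold=thr, method=method)


def masked_dry_mass_stats(mass: DryMassMap, mask: MyelinMask) -> dict[str, float]:
    """Dry-mass summary over the masked (myelin) pixels.

    Returns total mass (pg), mean density (pg/um^2), masked area (um^2) and
    masked pixel count; zeros for an empty mask.
    """
    if mass.density.shape != mask.mask.shape:
        raise ValueError(
            f"shape mismatch: density {mass.density.shape} vs mask {mask.mask.shape}"
        )
    n = int(mask.mask.sum())
    px_area = mass.pixel_pitch**2
    if n == 0:
        return {"total_mass_pg": 0.0, "mean_density": 0.0, "area_um2": 0.0, "pixel_count": 0}
    vals = mass.density[mask.mask]
    return {
        "total_mass_pg": float(vals.sum() * px_area),
        "mean_density": float(vals.mean()),
        "area_um2": float(n * px_area),
        "pixel_count": n,
    }


def phase_histogram(
    phases: Iterable[PhaseMap] | PhaseMap,
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> PhaseHistogram:
    """Pool all pixels of the given phase maps into one histogram.

    Bins are half-open ``[e_i, e_{i+1})`` with the last bin closed, as in
    :func:`numpy.histogram`.  Pixels outside the edge range are dropped.
    """
    if isinstance(phases, PhaseMap):
        phases = [phases]
    phases = list(phases)
    if not phases:
        raise ValueError("need at least one phase map")
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing with >= 2 entries")
    pooled = np.concatenate([p.phi.ravel() for p in phases])
    counts, _ = np.histogram(pooled, bins=edges)
    return PhaseHistogram(bin_edges=edges, counts=counts)


def histogram_overlap(h1: PhaseHistogram, h2: PhaseHistogram) -> float:
    """Histogram-intersection coefficient ``sum_i min(p_i, q_i)`` in [0, 1].

    Symmetric; 1 iff the normalized histograms are identical, 0 for disjoint
    support.
    """
    if h1.bin_edges.shape != h2.bin_edges.shape or not np.allclose(h1.bin_edges, h2.bin_edges):
        raise ValueError("histograms must share identical bin edges")
    return float(np.minimum(h1.normalized, h2.normalized).sum())


def group_pairwise_overlaps(
    class_phases: Mapping[str, Iterable[PhaseMap]],
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
    required_classes: Sequence[str] = ("AGA-CON", "AGA-HF", "SGA-CON", "SGA-HF"),
) -> dict[tuple[str, str], float]:
    """All six pairwise histogram overlaps over the four tissue classes.

    ``class_phases`` maps each class name to its phase maps; pixels are pooled
    per class.  Raises if a required class is missing, naming it.
    """
    for cls in required_classes:
        if cls not in class_phases:
            raise ValueError(f"missing class: {cls!r}")
    hists = {cls: phase_histogram(class_phases[cls], bin_edges) for cls in required_classes}
    return {
        (c1, c2): histogram_overlap(hists[c1], hists[c2])
        for c1, c2 in combinations(required_classes, 2)
    }
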
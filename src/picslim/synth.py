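"""Synthetic fiber-textured tissue phase maps for the four-class screen.

No deposited piglet image set exists, so every downstream stage is exercised
on a generative stand-in for internal-capsule white matter: a Poisson field
of line-segment kernels ("fibers") with von Mises-distributed orientations
around a per-map dominant direction, Gaussian cross-sections, additive phase
accumulation, a background level and camera noise.

The two binary factors modulate the expected fiber count multiplicatively:
AGA tissue carries ``size_effect`` times more fibers than SGA, and the
hydrolyzed-fat diet ``diet_effect`` times more than control — encoding the
direction "AGA and HF have more myelin".  With both multipliers at 1 the four
classes are statistically identical (the null construction); the per-pixel
phase histograms of the classes overlap heavily even at strong effect sizes,
so class information lives mostly in texture density, as in real tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from picslim.optics import simulate_interferograms
from picslim.types import FieldDecomposition, InterferogramStack, PhaseMap, TissueClassLabel

__all__ = [
    "TissueClassLabel",
    "FiberTextureParams",
    "CLASS_LABELS",
    "InterferogramRecord",
    "generate_fiber_phase_map",
    "generate_labeled_dataset",
    "generate_interferogram_dataset",
]

#: Canonical class order used everywhere (seed derivation, reports).
CLASS_LABELS: tuple[TissueClassLabel, ...] = (
    TissueClassLabel("AGA", "CON"),
    TissueClassLabel("AGA", "HF"),
    TissueClassLabel("SGA", "CON"),
    TissueClassLabel("SGA", "HF"),
)


@dataclass(frozen=True)
class FiberTextureParams:
    """Knobs of the fiber-texture generator.

    Defaults target a desk-scale 256 x 192 px frame (the 4:3 aspect of the
    native 1624 x 1224 px camera frame) with a dense myelin-like texture:
    mean phase a few tenths of a radian, fiber crossings peaking around
    1.5-2 rad.
    """

    image_shape: tuple[int, int] = (192, 256)  # (h, w) px
    fiber_count: float = 360.0  # expected segments per (default-size) frame
    fiber_width_px: float = 3.0  # Gaussian FWHM-ish cross-section scale
    fiber_length_px: float = 40.0  # mean segment length
    fiber_length_shape: float = 4.0  # gamma shape of the length distribution
    orientation_kappa: float = 4.0  # von Mises concentration about the tract axis
    phase_amplitude: float = 0.2  # peak phase per fiber, rad
    background_phase: float = 0.05  # rad
    noise_sd: float = 0.02  # additive Gaussian noise, rad
    size_effect: float = 1.5  # fiber-count multiplier, AGA vs SGA
    diet_effect: float = 1.3  # fiber-count multiplier, HF vs CON
    slide_sigma: float = 0.01  # slide-level background jitter, rad
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_shape
        if h < 1 or w < 1:
            raise ValueError("image_shape must be positive")
        if self.fiber_length_shape <= 0:
            raise ValueError("fiber_length_shape must be positive")
        for name in (
            "fiber_count", "fiber_width_px", "fiber_length_px", "orientation_kappa",
            "phase_amplitude", "noise_sd", "slide_sigma",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.size_effect < 1 or self.diet_effect < 1:
            raise ValueError("effect multipliers must be >= 1 (AGA/HF are the high-myelin arms)")

    def expected_fibers(self, label: TissueClassLabel) -> float:
        """Expected fiber count for a class (SGA-CON is the reference arm).

        ``fiber_count`` is quoted for the default 192 x 256 px frame and
        scales with frame area, so texture density is size-invariant
        (a Poisson line process has a per-area intensity).
        """
        h, w = self.image_shape
        n = self.fiber_count * (h * w) / (192 * 256)
        if label.size == "AGA":
            n *= self.size_effect
        if label.diet == "HF":
            n *= self.diet_effect
        return n


@dataclass
class LabeledPhaseMap:
    """One dataset item: a phase map plus its class label and source slide."""

    phase: PhaseMap
    label: TissueClassLabel
    slide: str
    seed: int


@dataclass
class InterferogramRecord:
    """A simulated four-frame stack with its label and ground-truth field."""

    stack: InterferogramStack
    label: TissueClassLabel
    slide: str
    truth: FieldDecomposition


def _render_fibers(rng: np.random.Generator, params: FiberTextureParams, n_fibers: int) -> np.ndarray:
    h, w = params.image_shape
    phi = np.zeros((h, w))
    if n_fibers == 0:
        return phi
    sigma = params.fiber_width_px / 2.0
    pad = max(1.0, 3.0 * sigma)
    mu = rng.uniform(-np.pi, np.pi)  # dominant tract orientation of this map
    centers = rng.uniform([0, 0], [h, w], size=(n_fibers, 2))
    thetas = rng.vonmises(mu, params.orientation_kappa, size=n_fibers)
    # gamma lengths: mean fiber_length_px, tighter than exponential so the
    # per-map compound-Poisson variance stays small
    lengths = rng.gamma(
        params.fiber_length_shape, params.fiber_length_px / params.fiber_length_shape,
        size=n_fibers,
    )
    amps = params.phase_amplitude * rng.uniform(0.85, 1.15, size=n_fibers)
    for (cy, cx), theta, length, amp in zip(centers, thetas, lengths, amps):
        dy, dx = 0.5 * length * np.sin(theta), 0.5 * length * np.cos(theta)
        y0, y1 = cy - dy, cy + dy
        x0, x1 = cx - dx, cx + dx
        ylo = max(0, int(np.floor(min(y0, y1) - pad)))
        yhi = min(h, int(np.ceil(max(y0, y1) + pad)) + 1)
        xlo = max(0, int(np.floor(min(x0, x1) - pad)))
        xhi = min(w, int(np.ceil(max(x0, x1) + pad)) + 1)
        if ylo >= yhi or xlo >= xhi:
            continue
        yy, xx = np.mgrid[ylo:yhi, xlo:xhi]
        # distance from each pixel to the segment (y0,x0)-(y1,x1)
        vy, vx = y1 - y0, x1 - x0
        seg2 = vy * vy + vx * vx
        if seg2 == 0:
            d2 = (yy - y0) ** 2 + (xx - x0) ** 2
        else:
            t = np.clip(((yy - y0) * vy + (xx - x0) * vx) / seg2, 0.0, 1.0)
            d2 = (yy - (y0 + t * vy)) ** 2 + (xx - (x0 + t * vx)) ** 2
        phi[ylo:yhi, xlo:xhi] += amp * np.exp(-d2 / (2.0 * sigma**2))
    return phi


def generate_fiber_phase_map(
    params: FiberTextureParams,
    label: TissueClassLabel,
    seed: int | None = None,
    background_offset: float = 0.0,
    pixel_pitch: float = 0.157,
) -> PhaseMap:
    """Draw one synthetic phase map for a tissue class.

    The map is reproducible from ``(params, label, seed)``: the generator
    stream is keyed on the seed together with the class index, so the same
    seed yields class-consistent but distinct fields across labels.

    Parameters
    ----------
    seed : int, optional
        Overrides ``params.seed``.
    background_offset : float
        Extra constant phase, used for slide-level variation.
    pixel_pitch : float
        Pixel size in micrometres (native frame geometry by default).
    """
    base_seed = params.seed if seed is None else seed
    class_idx = CLASS_LABELS.index(label)
    rng = np.random.default_rng(np.random.SeedSequence((base_seed, class_idx)))
    n = int(rng.poisson(params.expected_fibers(label)))
    phi = _render_fibers(rng, params, n)
    phi += params.background_phase + background_offset
    if params.noise_sd > 0:
        phi += rng.normal(0.0, params.noise_sd, size=phi.shape)
    return PhaseMap(
        phi=phi,
        pixel_pitch=pixel_pitch,
        metadata={"label": label.name, "seed": base_seed, "n_fibers": n},
    )


def _per_map_seed(master_seed: int, class_idx: int, map_idx: int) -> int:
    """Stable per-map seed: low 31 bits of the keyed SeedSequence entropy."""
    ss = np.random.SeedSequence((master_seed, class_idx, map_idx))
    return int(ss.generate_state(1, np.uint64)[0] & 0x7FFFFFFF)


def generate_labeled_dataset(
    params: FiberTextureParams,
    n_per_class: int,
    seed: int = 0,
    n_slides_per_class: int = 4,
):
    """Generate a balanced labeled dataset over the four classes.

    Each class contributes ``n_per_class`` maps spread round-robin over
    ``n_slides_per_class`` synthetic source slides; each slide carries a small
    random background offset (``params.slide_sigma``) so slides are weakly
    correlated, as serial sections from one animal would be.  Per-map seeds
    derive deterministically from ``(seed, class index, map index)``.

    Returns
    -------
    LabeledDataset
        Items in class-major, index-minor order.
    """
    from picslim.classify.data import LabeledDataset

    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    images, labels, slides = [], [], []
    for c, label in enumerate(CLASS_LABELS):
        slide_rng = np.random.default_rng(np.random.SeedSequence((seed, c, 0x51DE)))
        offsets = slide_rng.normal(0.0, params.slide_sigma, size=n_slides_per_class)
        for i in range(n_per_class):
            s = i % n_slides_per_class
            pm = generate_fiber_phase_map(
                params,
                label,
                seed=_per_map_seed(seed, c, i),
                background_offset=float(offsets[s]),
            )
            images.append(pm.phi)
            labels.append(label)
            slides.append(f"{label.name}-s{s}")
    return LabeledDataset(images=images, labels=labels, slides=slides)


def generate_interferogram_dataset(
    params: FiberTextureParams,
    n_per_class: int,
    beta_scale: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[InterferogramRecord]:
    """Drive the interferometric forward model at dataset scale.

    Each synthetic phase map becomes a field decomposition with unit incident
    amplitude, scattered amplitude ``beta_scale`` and phase difference equal
    to the map (wrapped), then passes through the four-frame simulator with
    camera noise ``noise_sd``.
    """
    if not 0 < beta_scale <= 1:
        raise ValueError("beta_scale must lie in (0, 1]")
    dataset = generate_labeled_dataset(params, n_per_class, seed=seed)
    records = []
    for i in range(len(dataset)):
        phi = dataset.images[i]
        decomp = FieldDecomposition(
            a_incident=np.ones_like(phi),
            b_scattered=np.full_like(phi, beta_scale),
            delta_phi=phi,
            pixel_pitch=0.157,
        )
        stack = simulate_interferograms(decomp, noise_sd=noise_sd, seed=_per_map_seed(seed, 5, i))
        records.append(
            InterferogramRecord(
                stack=stack, label=dataset.labels[i], slide=dataset.slides[i], truth=decomp
            )
        )
    return records
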
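"""Core domain containers for four-frame phase-shifting interferometry.

A SLIM acquisition decomposes the image field into an incident (unscattered)
component ``U_i`` and a scattered component ``U_s``.  The spatial light
modulator imposes four extra phase delays ``phi_m in {0, pi/2, pi, 3pi/2}``
between the two components; the camera records one intensity frame per delay.
These containers carry the ground-truth field decomposition, the four
recorded frames, and the reconstructed phase map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Modulator phase delays, in acquisition order (radians).
MODULATION_PHASES: tuple[float, ...] = (0.0, np.pi / 2, np.pi, 3 * np.pi / 2)


@dataclass(frozen=True)
class TissueClassLabel:
    """One of the four tissue classes of the two-factor screen.

    ``size`` is the gestational-size factor (AGA = appropriate, SGA = small
    for gestational age); ``diet`` is the dietary factor (CON = control,
    HF = hydrolyzed fat).
    """

    size: str
    diet: str

    def __post_init__(self) -> None:
        if self.size not in ("AGA", "SGA"):
            raise ValueError(f"size must be 'AGA' or 'SGA', got {self.size!r}")
        if self.diet not in ("CON", "HF"):
            raise ValueError(f"diet must be 'CON' or 'HF', got {self.diet!r}")

    @property
    def name(self) -> str:
        return f"{self.size}-{self.diet}"

    def __str__(self) -> str:
        return self.name


def wrap_phase(phi: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles into the interval (-pi, pi]."""
    wrapped = np.mod(-np.asarray(phi) + np.pi, 2 * np.pi)
    return np.pi - wrapped


@dataclass
class FieldDecomposition:
    """Ground truth of the interferometric forward model.

    Parameters
    ----------
    a_incident : ndarray
        2-D map of the incident-field amplitude ``|U_i|`` (arbitrary units,
        nonnegative).
    b_scattered : ndarray
        2-D map of the scattered-field amplitude ``|U_s|`` (same units).
    delta_phi : ndarray
        2-D map of the phase difference between scattered and incident field,
        wrapped to (-pi, pi] (radians).
    pixel_pitch : float
        Physical size of one pixel (micrometres).
    """

    a_incident: np.ndarray
    b_scattered: np.ndarray
    delta_phi: np.ndarray
    pixel_pitch: float = 1.0

    def __post_init__(self) -> None:
        self.a_incident = np.asarray(self.a_incident, dtype=float)
        self.b_scattered = np.asarray(self.b_scattered, dtype=float)
        self.delta_phi = np.asarray(self.delta_phi, dtype=float)
        if not (self.a_incident.shape == self.b_scattered.shape == self.delta_phi.shape):
            raise ValueError(
                "a_incident, b_scattered and delta_phi must share one shape; got "
                f"{self.a_incident.shape}, {self.b_scattered.shape}, {self.delta_phi.shape}"
            )
        if self.a_incident.ndim != 2:
            raise ValueError("field maps must be 2-D")
        if np.any(self.a_incident < 0) or np.any(self.b_scattered < 0):
            raise ValueError("field amplitudes must be nonnegative")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        self.delta_phi = np.asarray(wrap_phase(self.delta_phi), dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.a_incident.shape


@dataclass
class InterferogramStack:
    """Four co-registered intensity frames at modulations {0, pi/2, pi, 3pi/2}."""

    frames: np.ndarray  # shape (4, H, W)
    pixel_pitch: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] != 4:
            raise ValueError(f"expected four 2-D frames, got array of shape {self.frames.shape}")
        if np.any(self.frames < 0):
            raise ValueError("intensities must be nonnegative")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")

    def frame(self, modulation: float) -> np.ndarray:
        """Return the frame recorded at modulator phase ``modulation`` (radians)."""
        for i, m in enumerate(MODULATION_PHASES):
            if np.isclose(modulation, m):
                return self.frames[i]
        raise KeyError(f"no frame at modulation {modulation!r}; valid: {MODULATION_PHASES}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class PhaseMap:
    """Reconstructed phase of the total field relative to the incident field.

    ``beta`` is the amplitude ratio ``|U_s| / |U_i|`` in [0, 1]; ``valid`` marks
    pixels where the reconstruction was well conditioned (no modulation signal
    or an inconsistent stack clears the flag).
    """

    phi: np.ndarray
    pixel_pitch: float = 1.0
    beta: np.ndarray | None = None
    valid: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.ndim != 2:
            raise ValueError("phi must be a 2-D map")
        if not np.all(np.isfinite(self.phi)):
            raise ValueError("phi must be finite everywhere")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if self.beta is not None:
            self.beta = np.asarray(self.beta, dtype=float)
            if self.beta.shape != self.phi.shape:
                raise ValueError("beta must match phi in shape")
            if np.any(self.beta < 0) or np.any(self.beta > 1):
                raise ValueError("beta must lie in [0, 1]")
        if self.valid is not None:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.phi.shape:
                raise ValueError("valid must match phi in shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.phi.shape
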
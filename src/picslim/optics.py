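"""Forward simulation and exact inversion of four-frame SLIM interferograms.

The recorded intensity at modulator phase ``phi_m`` is the interference law

    I(phi_m) = a^2 + b^2 + 2 a b cos(delta_phi - phi_m)

with ``a = |U_i|`` the incident amplitude, ``b = |U_s|`` the scattered
amplitude and ``delta_phi`` their phase difference.  Four frames at
``phi_m in {0, pi/2, pi, 3pi/2}`` over-determine the three unknowns, so the
inversion is closed-form:

    delta_phi = atan2(I(pi/2) - I(3pi/2), I(0) - I(pi))
    4 a b     = hypot(I(0) - I(pi), I(pi/2) - I(3pi/2))
    4(a^2+b^2)= sum of the four frames

and the phase of the total field relative to the incident field is

    phi = arg(1 + beta * exp(i delta_phi)),   beta = b / a.

The sign convention (modulation subtracted from ``delta_phi``) is fixed here;
any self-consistent choice round-trips exactly.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from picslim.types import MODULATION_PHASES, FieldDecomposition, InterferogramStack, PhaseMap

__all__ = [
    "simulate_interferograms",
    "reconstruct_delta_phi",
    "estimate_beta",
    "reconstruct_phase",
]

#: Relative tolerance below which the modulation amplitude counts as zero.
_DEGENERATE_RTOL = 1e-12


class DeltaPhiResult(NamedTuple):
    delta_phi: np.ndarray
    valid: np.ndarray


class BetaResult(NamedTuple):
    beta: np.ndarray
    valid: np.ndarray


def simulate_interferograms(
    decomp: FieldDecomposition,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> InterferogramStack:
    """Simulate the four phase-shifted intensity frames of a SLIM acquisition.

    Parameters
    ----------
    decomp : FieldDecomposition
        Ground-truth incident/scattered amplitudes and phase difference.
    noise_sd : float
        Standard deviation of additive Gaussian camera noise, in the same
        intensity units as the frames.  Noisy intensities are clamped at zero.
    seed : int, optional
        Seed for the noise generator; required for reproducibility whenever
        ``noise_sd > 0``.

    Returns
    -------
    InterferogramStack
        Frames ordered by modulation {0, pi/2, pi, 3pi/2}.
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be nonnegative, got {noise_sd}")
    a = decomp.a_incident
    b = decomp.b_scattered
    dphi = decomp.delta_phi
    frames = np.stack(
        [a**2 + b**2 + 2 * a * b * np.cos(dphi - m) for m in MODULATION_PHASES]
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        frames = frames + rng.normal(0.0, noise_sd, size=frames.shape)
        np.clip(frames, 0.0, None, out=frames)
    # interference law can dip microscopically below zero from rounding
    np.clip(frames, 0.0, None, out=frames)
    return InterferogramStack(frames=frames, pixel_pitch=decomp.pixel_pitch)


def _quadratures(stack: InterferogramStack) -> tuple[np.ndarray, np.ndarray]:
    """Cosine and sine quadratures 4ab*cos(dphi), 4ab*sin(dphi)."""
    f0, f90, f180, f270 = stack.frames
    return f0 - f180, f90 - f270


def reconstruct_delta_phi(stack: InterferogramStack) -> DeltaPhiResult:
    """Recover the scattered-to-incident phase difference from a four-frame stack.

    Pixels with no modulation signal (both quadratures zero, e.g. no scattered
    light) get ``delta_phi = 0`` and a cleared validity flag, keeping the map
    total instead of NaN-poisoned.

    Returns
    -------
    DeltaPhiResult
        ``delta_phi`` in (-pi, pi] and a boolean validity mask.
    """
    cos_q, sin_q = _quadratures(stack)
    scale = np.max(np.abs(stack.frames)) or 1.0
    degenerate = (np.abs(cos_q) <= _DEGENERATE_RTOL * scale) & (
        np.abs(sin_q) <= _DEGENERATE_RTOL * scale
    )
    delta_phi = np.arctan2(sin_q, cos_q)
    delta_phi[degenerate] = 0.0
    # atan2 returns -pi for (x<0, y=-0); fold onto (-pi, pi]
    delta_phi[delta_phi <= -np.pi] = np.pi
    return DeltaPhiResult(delta_phi=delta_phi, valid=~degenerate)


def estimate_beta(stack: InterferogramStack) -> BetaResult:
    """Recover the amplitude ratio ``beta = |U_s| / |U_i|`` from a stack.

    Uses ``S = sum(frames) = 4(a^2 + b^2)`` and the modulation amplitude
    ``C = 4ab``; ``a^2`` and ``b^2`` are the roots of
    ``t^2 - (S/4) t + (C/4)^2 = 0``.  The branch with ``a >= b`` is taken —
    SLIM assumes the unscattered field dominates.  Inconsistent pixels
    (negative discriminant beyond rounding, e.g. heavy noise) are clamped to
    the repeated root and flagged; ``S = 0`` pixels return ``beta = 0``.
    """
    S = np.sum(stack.frames, axis=0)
    cos_q, sin_q = _quadratures(stack)
    C = np.hypot(cos_q, sin_q)
    p = S / 4.0  # a^2 + b^2
    q = (C / 4.0) ** 2  # a^2 * b^2
    disc = p**2 - 4.0 * q
    scale = np.max(p**2) or 1.0
    inconsistent = disc < -1e-9 * scale
    disc = np.clip(disc, 0.0, None)
    root = np.sqrt(disc)
    a2 = (p + root) / 2.0
    b2 = (p - root) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.sqrt(np.where(a2 > 0, b2 / np.where(a2 > 0, a2, 1.0), 0.0))
    beta[S <= 0] = 0.0
    np.clip(beta, 0.0, 1.0, out=beta)
    return BetaResult(beta=beta, valid=~inconsistent)


def reconstruct_phase(stack: InterferogramStack) -> PhaseMap:
    """Reconstruct the SLIM phase map ``phi = arg(1 + beta e^{i delta_phi})``.

    This is the phase of the total field ``U_i + U_s`` relative to the
    incident field, the quantity SLIM reports.  The validity mask combines
    the degenerate-pixel mask of the phase-difference step and the
    consistency mask of the amplitude-ratio step.
    """
    dphi, dphi_valid = reconstruct_delta_phi(stack)
    beta, beta_valid = estimate_beta(stack)
    phi = np.arctan2(beta * np.sin(dphi), 1.0 + beta * np.cos(dphi))
    return PhaseMap(
        phi=phi,
        pixel_pitch=stack.pixel_pitch,
        beta=beta,
        valid=dphi_valid & beta_valid,
    )
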
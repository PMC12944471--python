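"""Phase processing: unwrapping, B1+ phase estimation, bilateral denoising.

The measured steady-state echo phases carry twice the transmit (B1+) phase
plus equal-and-opposite B0/chemical-shift terms:

    phi_S+ = 2*phi+ + delta,    phi_S- = 2*phi+ - delta.

Averaging the two unwrapped echo phases cancels delta exactly; halving the
remaining total B1 phase (the transceive assumption) gives

    phi+ = (phi_S+ + phi_S-) / 4.
"""

from __future__ import annotations

import numpy as np

from ._unwrap import _unwrap_core
from .errors import DegenerateInputError, ParameterError, ShapeError
from .volumes import PhaseVolume, wrap_phase

__all__ = ["unwrap_region_growing", "estimate_b1_phase", "bilateral_filter"]


def unwrap_region_growing(
    phase: PhaseVolume, magnitude: np.ndarray, seed_index: tuple[int, int, int] | None = None
) -> PhaseVolume:
    """Unwrap a wrapped 3D phase field by quality-guided region growing.

    Voxels are visited in descending magnitude priority starting from the
    voxel of maximum magnitude (or an explicit ``seed_index``); each is
    unwrapped by adding the integer multiple of 2*pi that minimises its
    difference to the mean of the already-unwrapped 6-neighbours.

    The output satisfies wrap(output) == input everywhere; on smooth fields
    the result is independent of the seed up to one global 2*pi multiple.
    """
    if not phase.wrapped:
        raise ParameterError("unwrap_region_growing expects a wrapped PhaseVolume")
    magnitude = np.asarray(magnitude, dtype=float)
    if magnitude.shape != phase.shape:
        raise ShapeError(
            f"magnitude shape {magnitude.shape} != phase shape {phase.shape}"
        )
    if not np.any(magnitude > 0):
        raise DegenerateInputError("all-zero magnitude: no quality guidance possible")

    nx, ny, nz = phase.shape
    if seed_index is None:
        seed = int(np.argmax(magnitude))
    else:
        seed = int(np.ravel_multi_index(seed_index, phase.shape))
    out = _unwrap_core(
        np.ascontiguousarray(phase.values, dtype=np.float64).ravel(),
        np.ascontiguousarray(magnitude, dtype=np.float64).ravel(),
        nx,
        ny,
        nz,
        seed,
    ).reshape(phase.shape)
    return PhaseVolume(values=out, spacing_mm=phase.spacing_mm, wrapped=False)


def estimate_b1_phase(
    phi_s_plus: PhaseVolume,
    phi_s_minus: PhaseVolume,
    transmit_fraction: float = 0.5,
) -> PhaseVolume:
    """Average the two unwrapped echo phases and take the transmit share.

    Returns ``transmit_fraction * (phi_S+ + phi_S-) / 2``; with the default
    transceive split of 0.5 this is the canonical (phi_S+ + phi_S-)/4.
    B0-inhomogeneity and chemical-shift phase, entering the echoes with
    opposite signs, cancel algebraically.
    """
    if phi_s_plus.shape != phi_s_minus.shape:
        raise ShapeError(
            f"echo phase shapes differ: {phi_s_plus.shape} vs {phi_s_minus.shape}"
        )
    if phi_s_plus.spacing_mm != phi_s_minus.spacing_mm:
        raise ShapeError("echo phase volumes have different voxel spacing")
    if phi_s_plus.wrapped or phi_s_minus.wrapped:
        raise ParameterError("estimate_b1_phase expects unwrapped inputs")
    vals = transmit_fraction * (phi_s_plus.values + phi_s_minus.values) / 2.0
    return PhaseVolume(values=vals, spacing_mm=phi_s_plus.spacing_mm, wrapped=False)


def bilateral_filter(
    phase: PhaseVolume,
    degree_of_smoothing: float = 3.0,
    spatial_sigma: float = 1.0,
) -> PhaseVolume:
    """Edge-preserving 3D bilateral smoothing of an unwrapped phase field.

    Each voxel becomes the normalised weighted mean of its neighbours within
    +/- ceil(3*spatial_sigma) voxels per axis, with weights

        Gaussian(spatial distance in voxels; spatial_sigma)
        * Gaussian(value difference; range_sigma),

    where ``range_sigma = degree_of_smoothing * robust_std`` and the robust
    std is the MAD-based estimate 1.4826 * median(|phi - median(phi)|).
    The output is a convex combination of input values, hence bounded by the
    input's min/max; a constant field passes through unchanged.
    """
    if degree_of_smoothing <= 0 or spatial_sigma <= 0:
        raise ParameterError("degree_of_smoothing and spatial_sigma must be positive")
    if phase.wrapped:
        raise ParameterError("bilateral_filter expects an unwrapped PhaseVolume")

    v = phase.values
    med = np.median(v)
    robust_std = 1.4826 * np.median(np.abs(v - med))
    range_sigma = degree_of_smoothing * robust_std
    if range_sigma == 0.0:
        return PhaseVolume(values=v.copy(), spacing_mm=phase.spacing_mm, wrapped=False)

    r = int(np.ceil(3.0 * spatial_sigma))
    pad = np.pad(v, r, mode="reflect")
    num = np.zeros_like(v)
    den = np.zeros_like(v)
    inv_range = -0.5 / range_sigma**2
    inv_spatial = -0.5 / spatial_sigma**2
    nx, ny, nz = v.shape
    for dx in range(-r, r + 1):
        for dy in range(-r, r + 1):
            for dz in range(-r, r + 1):
                w_s = np.exp(inv_spatial * (dx * dx + dy * dy + dz * dz))
                shifted = pad[
                    r + dx : r + dx + nx, r + dy : r + dy + ny, r + dz : r + dz + nz
                ]
                d = shifted - v
                w = w_s * np.exp(inv_range * (d * d))
                num += w * shifted
                den += w
    return PhaseVolume(values=num / den, spacing_mm=phase.spacing_mm, wrapped=False)
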
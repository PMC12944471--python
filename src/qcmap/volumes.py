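"""Core in-memory containers for volumetric phase/conductivity data.

All volumes are plain 3D numpy arrays wrapped in light dataclasses that carry
voxel spacing (mm) and the metadata the reconstruction needs.  Spacing is kept
in millimetres at the container level — the reconstruction converts to metres
exactly once, where second derivatives (rad/m^2) are formed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, ShapeError

__all__ = [
    "EchoRole",
    "EchoVolume",
    "PhaseVolume",
    "ConductivityMap",
    "LabelMask",
    "AcquisitionContext",
    "wrap_phase",
]

MU0 = 4e-7 * np.pi  # vacuum permeability, H/m


def wrap_phase(values: np.ndarray | float) -> np.ndarray:
    """Wrap phase values into (-pi, pi], with the boundary mapped to +pi.

    Idempotent: wrapping an already-wrapped field returns it unchanged
    (up to the -pi -> +pi boundary convention).
    """
    return np.pi - np.mod(np.pi - np.asarray(values, dtype=float), 2.0 * np.pi)


def _check_spacing(spacing_mm) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing_mm)
    if len(spacing) != 3:
        raise ParameterError(f"spacing must have 3 components, got {len(spacing)}")
    if any(s <= 0 for s in spacing):
        raise ParameterError(f"spacing components must be positive, got {spacing}")
    return spacing


def _check_3d(name: str, arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim != 3:
        raise ShapeError(f"{name} must be a 3D array, got ndim={arr.ndim}")
    return arr


class EchoRole(str, enum.Enum):
    """Which steady-state echo a volume holds: the FID-like S+ or the
    time-reversed (spin/stimulated-echo-like) S-."""

    S_PLUS = "S_plus"
    S_MINUS = "S_minus"


@dataclass
class EchoVolume:
    """One complex echo image stored as magnitude + wrapped phase.

    The magnitude is the intensity later used for outlier rejection inside the
    sliding reconstruction kernel; the phase is wrapped to (-pi, pi].
    """

    magnitude: np.ndarray
    phase: np.ndarray
    spacing_mm: tuple[float, float, float]
    echo_role: EchoRole

    def __post_init__(self) -> None:
        self.magnitude = _check_3d("magnitude", self.magnitude).astype(float)
        self.phase = _check_3d("phase", self.phase).astype(float)
        if self.magnitude.shape != self.phase.shape:
            raise ShapeError(
                f"magnitude {self.magnitude.shape} and phase {self.phase.shape} "
                "must have identical dimensions"
            )
        if np.any(self.magnitude < 0):
            raise ParameterError("magnitude must be non-negative")
        if self.phase.size and (
            self.phase.max() > np.pi + 1e-12 or self.phase.min() <= -np.pi - 1e-12
        ):
            raise ParameterError("phase must be wrapped to (-pi, pi]")
        self.echo_role = EchoRole(self.echo_role)
        self.spacing_mm = _check_spacing(self.spacing_mm)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.magnitude.shape

    @property
    def complex(self) -> np.ndarray:
        return self.magnitude * np.exp(1j * self.phase)


@dataclass
class PhaseVolume:
    """A real-valued 3D phase field (rad); ``wrapped`` records whether values
    are still confined to (-pi, pi]."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    wrapped: bool

    def __post_init__(self) -> None:
        self.values = _check_3d("values", self.values).astype(float)
        self.spacing_mm = _check_spacing(self.spacing_mm)
        if self.wrapped and self.values.size and (
            self.values.max() > np.pi + 1e-12
            or self.values.min() <= -np.pi - 1e-12
        ):
            raise ParameterError("wrapped PhaseVolume has values outside (-pi, pi]")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


@dataclass
class ConductivityMap:
    """3D conductivity field sigma (S/m) plus a validity mask.

    Invalid voxels (kernel left the volume, insufficient support, failed fit,
    excluded label) carry NaN, never a finite value.
    """

    sigma: np.ndarray
    valid: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.sigma = _check_3d("sigma", self.sigma).astype(float)
        self.valid = _check_3d("valid", self.valid).astype(bool)
        if self.sigma.shape != self.valid.shape:
            raise ShapeError("sigma and valid must have identical dimensions")
        self.spacing_mm = _check_spacing(self.spacing_mm)
        self.sigma = np.where(self.valid, self.sigma, np.nan)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.sigma.shape


@dataclass
class LabelMask:
    """Integer tissue/region labels; 0 means background/excluded."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = _check_3d("labels", self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ParameterError("labels must be an integer array")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    def present_labels(self) -> list[int]:
        """Nonzero labels present, in ascending order."""
        vals = np.unique(self.labels)
        return [int(v) for v in vals if v != 0]


@dataclass
class AcquisitionContext:
    """Acquisition constants entering the conductivity relation
    sigma = lap(phi+) / (omega * mu0).

    omega is always derived from the Larmor frequency, never stored.
    Default frequency is the proton Larmor frequency at 3 T (127.7 MHz).
    """

    larmor_freq_hz: float = 127.7e6
    mu0: float = MU0
    spacing_mm: tuple[float, float, float] = field(default=(0.5, 0.5, 0.5))

    def __post_init__(self) -> None:
        if self.larmor_freq_hz <= 0:
            raise ParameterError("larmor_freq_hz must be positive")
        self.spacing_mm = _check_spacing(self.spacing_mm)

    @property
    def omega(self) -> float:
        """Larmor angular frequency, rad/s."""
        return 2.0 * np.pi * self.larmor_freq_hz

    @property
    def omega_mu0(self) -> float:
        """omega * mu0 — the rad/m^2 per S/m conversion constant
        (~1.008e3 at 127.7 MHz)."""
        return self.omega * self.mu0
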
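"""Digital conductivity phantom: geometry, forward phase model, echo synthesis.

The phantom emulates a saline calibration object: three cylindrical
inclusions of increasing NaCl concentration (hence conductivity) embedded in
a homogeneous agarose-gel background.  From a known conductivity field the
clean transmit phase is generated by inverting the conductivity relation as
a discrete Poisson problem,

    lap(phi+) = omega * mu0 * (sigma - mean(sigma)),

solved spectrally with periodic boundaries, so the ground-truth phase has
*exactly* the 7-point discrete Laplacian the estimators measure.  Echo
volumes are then synthesised as

    phi_S+ = 2*phi+ + delta,   phi_S- = 2*phi+ - delta,

with delta a smooth random B0-like phase plus a constant chemical-shift
term, complex Gaussian noise added per echo, and phases wrapped to (-pi, pi].

The zero-mean (periodic) gauge means estimators recover sigma minus its
volume mean; differences and linearity between regions are unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import fft as sp_fft
from scipy import ndimage

from .errors import GeometryError, ParameterError
from .volumes import (
    AcquisitionContext,
    EchoRole,
    EchoVolume,
    LabelMask,
    wrap_phase,
)

__all__ = [
    "Background",
    "Cylinder",
    "Box",
    "ConfoundSpec",
    "PhantomSpec",
    "GroundTruth",
    "rasterize",
    "forward_phase",
    "synthesize_echoes",
    "default_three_tube_phantom",
    "simulate",
]


@dataclass
class Background:
    """Fills every voxel not claimed by a later region; label 0."""

    sigma: float
    magnitude: float


@dataclass
class Cylinder:
    """Axis-aligned (z) cylinder; centre/radius/height in mm, world
    coordinates measured from the volume centre at voxel centres."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    height_mm: float
    sigma: float
    magnitude: float


@dataclass
class Box:
    """Axis-aligned box; centre and edge lengths in mm."""

    center_mm: tuple[float, float, float]
    size_mm: tuple[float, float, float]
    sigma: float
    magnitude: float


@dataclass
class ConfoundSpec:
    """Non-B1 phase confounds entering the two echoes with opposite signs.

    b0_phase_amplitude: peak amplitude (rad) of the smooth B0-like field.
    b0_smoothness_mm: Gaussian correlation length of that field.
    chemical_shift_phase: spatially constant phase offset (rad);
        on-resonance water model, no spatially varying fat term.
    """

    b0_phase_amplitude: float = 3.0
    b0_smoothness_mm: float = 12.0
    chemical_shift_phase: float = 0.5


@dataclass
class PhantomSpec:
    """Full description of one synthetic phantom realisation."""

    grid_shape: tuple[int, int, int] = (128, 128, 128)
    spacing_mm: tuple[float, float, float] = (0.5, 0.5, 0.5)
    regions: list = field(default_factory=list)
    confound: ConfoundSpec = field(default_factory=ConfoundSpec)
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.regions:
            raise ParameterError("regions must be non-empty")
        if not any(isinstance(r, Background) for r in self.regions):
            raise ParameterError("regions must include a Background")
        for r in self.regions:
            sigma = getattr(r, "sigma")
            if sigma < 0:
                raise ParameterError("sigma_true must be non-negative")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["regions"] = [
            {"kind": type(r).__name__.lower(), **asdict(r)} for r in self.regions
        ]
        return d


@dataclass
class GroundTruth:
    """Known truth for one phantom realisation.

    ``sigma`` is the specified conductivity; because the forward phase uses
    the zero-mean periodic gauge, the discrete Laplacian of
    ``phi_plus_clean`` equals omega*mu0*(sigma - mean(sigma)) — exposed as
    ``sigma_contrast`` — at every voxel.
    """

    sigma: np.ndarray
    phi_plus_clean: np.ndarray
    labels: np.ndarray
    spacing_mm: tuple[float, float, float]

    @property
    def sigma_contrast(self) -> np.ndarray:
        return self.sigma - self.sigma.mean()

    @property
    def label_mask(self) -> LabelMask:
        return LabelMask(labels=self.labels)


def _world_coords(grid_shape, spacing_mm):
    """Voxel-centre world coordinates (mm) per axis, origin at volume centre."""
    return [
        (np.arange(n) - (n - 1) / 2.0) * h for n, h in zip(grid_shape, spacing_mm)
    ]


def rasterize(spec: PhantomSpec):
    """Voxel-centre membership rasterisation of the region list.

    Later regions overwrite earlier ones; non-background regions get labels
    1..k in list order.  Returns (sigma, labels, magnitude) grids.
    """
    shape = tuple(spec.grid_shape)
    cx, cy, cz = _world_coords(shape, spec.spacing_mm)
    half_extent = [c[-1] + h / 2.0 for c, h in zip((cx, cy, cz), spec.spacing_mm)]

    bg = next(r for r in spec.regions if isinstance(r, Background))
    sigma = np.full(shape, float(bg.sigma))
    magnitude = np.full(shape, float(bg.magnitude))
    labels = np.zeros(shape, dtype=np.int32)

    X = cx[:, None, None]
    Y = cy[None, :, None]
    Z = cz[None, None, :]
    lab = 0
    for region in spec.regions:
        if isinstance(region, Background):
            continue
        lab += 1
        if isinstance(region, Cylinder):
            x0, y0, z0 = region.center_mm
            if (
                abs(x0) + region.radius_mm > half_extent[0]
                or abs(y0) + region.radius_mm > half_extent[1]
                or abs(z0) + region.height_mm / 2.0 > half_extent[2]
            ):
                raise GeometryError(f"cylinder {lab} extends outside the grid")
            member = ((X - x0) ** 2 + (Y - y0) ** 2 <= region.radius_mm**2) & (
                np.abs(Z - z0) <= region.height_mm / 2.0
            )
        elif isinstance(region, Box):
            x0, y0, z0 = region.center_mm
            sx, sy, sz = region.size_mm
            if (
                abs(x0) + sx / 2.0 > half_extent[0]
                or abs(y0) + sy / 2.0 > half_extent[1]
                or abs(z0) + sz / 2.0 > half_extent[2]
            ):
                raise GeometryError(f"box {lab} extends outside the grid")
            member = (
                (np.abs(X - x0) <= sx / 2.0)
                & (np.abs(Y - y0) <= sy / 2.0)
                & (np.abs(Z - z0) <= sz / 2.0)
            )
        else:
            raise ParameterError(f"unknown region type {type(region).__name__}")
        sigma[member] = region.sigma
        magnitude[member] = region.magnitude
        labels[member] = lab
    return sigma, labels, magnitude


def forward_phase(sigma: np.ndarray, ctx: AcquisitionContext) -> np.ndarray:
    """Clean transmit phase whose 7-point discrete Laplacian equals
    omega*mu0*(sigma - mean(sigma)) to spectral (machine) precision.

    Periodic-boundary Poisson solve via the exact eigenvalues of the
    discrete Laplacian; zero-mean solution.
    """
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim != 3 or min(sigma.shape) < 8:
        raise ParameterError("forward_phase expects a 3D grid of at least 8^3")
    h = np.asarray(ctx.spacing_mm, dtype=float) * 1e-3
    rhs = ctx.omega_mu0 * (sigma - sigma.mean())
    shape = sigma.shape
    eig = np.zeros(shape)
    for axis, (n, ha) in enumerate(zip(shape, h)):
        k = np.arange(n)
        lam = -4.0 * np.sin(np.pi * k / n) ** 2 / ha**2
        sh = [1, 1, 1]
        sh[axis] = n
        eig = eig + lam.reshape(sh)
    rhs_hat = sp_fft.fftn(rhs)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_hat = np.where(eig != 0, rhs_hat / eig, 0.0)
    phi = sp_fft.ifftn(phi_hat).real
    return phi - phi.mean()


def synthesize_echoes(
    phi_plus_clean: np.ndarray,
    magnitude: np.ndarray,
    confound: ConfoundSpec,
    noise_sd: float,
    seed: int,
    spacing_mm,
    background_magnitude: float | None = None,
) -> tuple[EchoVolume, EchoVolume]:
    """Build the wrapped, noisy S+/S- echo pair from the clean B1+ phase.

    Complex Gaussian noise with per-channel std ``noise_sd *
    background_magnitude`` is added independently to each echo; the B0-like
    field delta (peak-normalised smoothed white noise) plus the constant
    chemical-shift phase enters the echoes with opposite signs.
    """
    if noise_sd < 0:
        raise ParameterError("noise_sd must be non-negative")
    phi = np.asarray(phi_plus_clean, dtype=float)
    magnitude = np.asarray(magnitude, dtype=float)
    if phi.shape != magnitude.shape:
        raise ParameterError("phase and magnitude grids must agree in shape")
    if background_magnitude is None:
        background_magnitude = float(np.median(magnitude))

    rng = np.random.default_rng(seed)
    if confound.b0_phase_amplitude > 0:
        g = rng.standard_normal(phi.shape)
        sig_vox = [confound.b0_smoothness_mm / s for s in spacing_mm]
        g = ndimage.gaussian_filter(g, sigma=sig_vox, mode="wrap")
        peak = np.abs(g).max()
        delta = (g / peak) * confound.b0_phase_amplitude if peak > 0 else g
    else:
        delta = np.zeros_like(phi)
    delta = delta + confound.chemical_shift_phase

    echoes = []
    for sign, role in ((1.0, EchoRole.S_PLUS), (-1.0, EchoRole.S_MINUS)):
        total_phase = 2.0 * phi + sign * delta
        signal = magnitude * np.exp(1j * total_phase)
        if noise_sd > 0:
            sd = noise_sd * background_magnitude
            signal = signal + sd * (
                rng.standard_normal(phi.shape) + 1j * rng.standard_normal(phi.shape)
            )
        echoes.append(
            EchoVolume(
                magnitude=np.abs(signal),
                phase=wrap_phase(np.angle(signal)),
                spacing_mm=tuple(spacing_mm),
                echo_role=role,
            )
        )
    return echoes[0], echoes[1]


def default_three_tube_phantom(
    seed: int = 0,
    noise_sd: float = 0.02,
    grid: int = 128,
    spacing_mm: float = 0.5,
) -> PhantomSpec:
    """The reference three-tube saline phantom.

    Desk-scale analogue of a 0/0.5/1 % NaCl syringe phantom in agarose gel:
    background sigma 0.2 S/m, three 8 mm-radius, 40 mm-tall cylinders with
    conductivity contrasts (0.04, 0.54, 1.28) S/m over the background.
    Tube magnitudes (1.0) differ from the gel (0.7), standing in for the
    relaxation-doped signal difference.  noise_sd 0.02 gives SNR ~ 50.
    """
    extent = grid * spacing_mm
    ring = 0.28 * extent  # tube centres sit on this radius around the axis
    tubes = []
    contrasts = (0.04, 0.54, 1.28)
    for ang, c in zip((90.0, 210.0, 330.0), contrasts):
        a = np.deg2rad(ang)
        tubes.append(
            Cylinder(
                center_mm=(ring * np.cos(a), ring * np.sin(a), 0.0),
                radius_mm=0.125 * extent,
                height_mm=0.625 * extent,
                sigma=0.2 + c,
                magnitude=1.0,
            )
        )
    return PhantomSpec(
        grid_shape=(grid, grid, grid),
        spacing_mm=(spacing_mm, spacing_mm, spacing_mm),
        regions=[Background(sigma=0.2, magnitude=0.7), *tubes],
        confound=ConfoundSpec(),
        noise_sd=noise_sd,
        seed=seed,
    )


def simulate(
    spec: PhantomSpec, ctx: AcquisitionContext | None = None
) -> tuple[EchoVolume, EchoVolume, GroundTruth]:
    """Rasterise, solve the forward phase model, synthesise the echo pair."""
    ctx = ctx or AcquisitionContext(spacing_mm=tuple(spec.spacing_mm))
    sigma, labels, magnitude = rasterize(spec)
    phi = forward_phase(sigma, ctx)
    bg = next(r for r in spec.regions if isinstance(r, Background))
    s_plus, s_minus = synthesize_echoes(
        phi,
        magnitude,
        spec.confound,
        spec.noise_sd,
        spec.seed,
        spec.spacing_mm,
        background_magnitude=bg.magnitude,
    )
    truth = GroundTruth(
        sigma=sigma,
        phi_plus_clean=phi,
        labels=labels,
        spacing_mm=tuple(spec.spacing_mm),
    )
    return s_plus, s_minus, truth
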
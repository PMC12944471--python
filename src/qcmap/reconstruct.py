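"""Conductivity reconstruction from the B1+ phase.

Under the piecewise-homogeneity assumption the tissue conductivity at the
Larmor frequency follows from the Laplacian of the transmit phase,

    sigma = lap(phi+) / (omega * mu0)        [S/m],

and the two standard local estimators of that Laplacian are implemented:

* parabolic fitting — within a sliding kernel, magnitude outliers are
  rejected and the surviving phase samples are least-squares fitted to a full
  3D second-order polynomial; the curvature 2*(a+b+c) estimates lap(phi+);

* integral (boundary-flux) form — sigma = (closed-surface flux of grad phi+)
  / (V * omega * mu0) over the kernel restricted to the centre voxel's
  segmentation label; by the discrete divergence theorem this equals the
  region mean of the 7-point Laplacian, which is how the sliding-window map
  is computed.

Spacing enters in millimetres and is converted to metres exactly once here;
all Laplacians are rad/m^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ParameterError, ShapeError
from .volumes import AcquisitionContext, ConductivityMap, LabelMask, PhaseVolume

__all__ = [
    "KernelSpec",
    "PolyCoefficients",
    "sigma_from_laplacian",
    "discrete_laplacian",
    "region_boundary_flux",
    "sigma_region_integral",
    "magnitude_outlier_mask",
    "fit_parabolic_kernel",
    "qcm_parabolic",
    "qcm_integral",
    "otsu_foreground",
]

# design-matrix column exponents (x^p y^q z^r) in the order a..j of the
# quadratic model a x^2 + b y^2 + c z^2 + d xy + e yz + f xz + g x + h y + i z + j
_COLUMNS = [
    (2, 0, 0),
    (0, 2, 0),
    (0, 0, 2),
    (1, 1, 0),
    (0, 1, 1),
    (1, 0, 1),
    (1, 0, 0),
    (0, 1, 0),
    (0, 0, 1),
    (0, 0, 0),
]
_N_COEF = 10
_MM2_TO_M2 = 1.0e6  # rad/mm^2 -> rad/m^2


@dataclass
class KernelSpec:
    """Sliding-kernel geometry and data-selection rules.

    size_mm: physical kernel edge lengths (default 8 mm isotropic).
    min_support_fraction: minimum fraction of kernel voxels that must survive
        masking/outlier removal for a voxel to be estimated.
    outlier_threshold: relative magnitude deviation above which a voxel is
        excluded from the parabolic fit (default 0.20, strict ">").
    """

    size_mm: tuple[float, float, float] = (8.0, 8.0, 8.0)
    min_support_fraction: float = 0.5
    outlier_threshold: float = 0.20

    def __post_init__(self) -> None:
        self.size_mm = tuple(float(s) for s in self.size_mm)
        if len(self.size_mm) != 3 or any(s <= 0 for s in self.size_mm):
            raise ParameterError(f"kernel size_mm must be 3 positive values, got {self.size_mm}")
        if not 0 < self.min_support_fraction <= 1:
            raise ParameterError("min_support_fraction must be in (0, 1]")
        if self.outlier_threshold <= 0:
            raise ParameterError("outlier_threshold must be positive")

    def extent(self, spacing_mm) -> tuple[int, int, int]:
        """Realised odd voxel extent per axis: the largest odd integer not
        exceeding size_mm/spacing_mm, floored at 3 (8 mm at 0.5 mm -> 15)."""
        ext = []
        for size, h in zip(self.size_mm, spacing_mm):
            n = int(np.floor(size / h))
            if n % 2 == 0:
                n -= 1
            ext.append(max(n, 3))
        return tuple(ext)


@dataclass
class PolyCoefficients:
    """Coefficients of the local quadratic model in SI units
    (a..f rad/m^2, g..i rad/m, j rad)."""

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float
    g: float
    h: float
    i: float
    j: float

    @property
    def curvature(self) -> float:
        """Laplacian of the fitted polynomial, 2*(a + b + c) [rad/m^2]."""
        return 2.0 * (self.a + self.b + self.c)


def sigma_from_laplacian(laplacian, ctx: AcquisitionContext):
    """Map a phase Laplacian (rad/m^2) to conductivity: sigma = lap/(omega*mu0)."""
    return np.asarray(laplacian, dtype=float) / ctx.omega_mu0


def discrete_laplacian(values: np.ndarray, spacing_mm) -> np.ndarray:
    """7-point discrete Laplacian in rad/m^2; the outermost voxel shell,
    where central differences are undefined, is NaN."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 3:
        raise ShapeError("discrete_laplacian expects a 3D array")
    h = np.asarray(spacing_mm, dtype=float) * 1e-3
    lap = np.zeros_like(v)
    lap[1:-1, :, :] += (v[2:, :, :] - 2.0 * v[1:-1, :, :] + v[:-2, :, :]) / h[0] ** 2
    lap[:, 1:-1, :] += (v[:, 2:, :] - 2.0 * v[:, 1:-1, :] + v[:, :-2, :]) / h[1] ** 2
    lap[:, :, 1:-1] += (v[:, :, 2:] - 2.0 * v[:, :, 1:-1] + v[:, :, :-2]) / h[2] ** 2
    lap[0, :, :] = lap[-1, :, :] = np.nan
    lap[:, 0, :] = lap[:, -1, :] = np.nan
    lap[:, :, 0] = lap[:, :, -1] = np.nan
    return lap


def region_boundary_flux(values: np.ndarray, region: np.ndarray, spacing_mm) -> float:
    """Net outward flux of grad(phi) through the closed surface of a voxel
    region: sum over boundary faces of the central (face-centred) normal
    derivative times face area [rad * m].

    The region must not touch the volume border (the normal derivative needs
    the phase one voxel outside each boundary face).
    """
    v = np.asarray(values, dtype=float)
    region = np.asarray(region, dtype=bool)
    if v.shape != region.shape:
        raise ShapeError("values and region shapes differ")
    if not region.any():
        raise ParameterError("region is empty")
    border = (
        region[0].any() or region[-1].any()
        or region[:, 0].any() or region[:, -1].any()
        or region[:, :, 0].any() or region[:, :, -1].any()
    )
    if border:
        raise ParameterError("region touches the volume border; flux undefined")
    h = np.asarray(spacing_mm, dtype=float) * 1e-3
    areas = (h[1] * h[2], h[0] * h[2], h[0] * h[1])
    flux = 0.0
    for axis in range(3):
        nbr_plus = np.roll(region, -1, axis)
        nbr_minus = np.roll(region, 1, axis)
        faces_plus = region & ~nbr_plus
        faces_minus = region & ~nbr_minus
        v_plus = np.roll(v, -1, axis)
        v_minus = np.roll(v, 1, axis)
        flux += (v_plus - v)[faces_plus].sum() * areas[axis] / h[axis]
        flux += (v_minus - v)[faces_minus].sum() * areas[axis] / h[axis]
    return float(flux)


def sigma_region_integral(
    values: np.ndarray, region: np.ndarray, spacing_mm, ctx: AcquisitionContext
) -> float:
    """Integral-form conductivity of one region: boundary flux of grad(phi)
    divided by (region volume * omega * mu0)."""
    flux = region_boundary_flux(values, region, spacing_mm)
    h = np.asarray(spacing_mm, dtype=float) * 1e-3
    volume = float(np.count_nonzero(region)) * float(np.prod(h))
    return flux / (volume * ctx.omega_mu0)


def magnitude_outlier_mask(magnitudes: np.ndarray, threshold: float = 0.20) -> np.ndarray:
    """Single-pass intensity outlier rule: a sample survives unless its
    magnitude differs from the mean of all samples by strictly more than
    ``threshold`` (relative).  Deviations exactly at the threshold are kept.
    """
    m = np.asarray(magnitudes, dtype=float)
    mean = m.mean()
    if mean == 0.0:
        return np.abs(m - mean) <= 0.0
    return np.abs(m - mean) <= threshold * mean


def _design_matrix(coords_mm: tuple[np.ndarray, np.ndarray, np.ndarray]) -> np.ndarray:
    """(K, 10) quadratic design matrix on the kernel offsets, mm units,
    flattened in C order to match window flattening."""
    ox, oy, oz = np.meshgrid(*coords_mm, indexing="ij")
    ox, oy, oz = ox.ravel(), oy.ravel(), oz.ravel()
    cols = [ox**p * oy**q * oz**r for (p, q, r) in _COLUMNS]
    return np.stack(cols, axis=1)


def fit_parabolic_kernel(
    phase_patch: np.ndarray,
    magnitude_patch: np.ndarray,
    coords_m: tuple[np.ndarray, np.ndarray, np.ndarray],
    threshold: float = 0.20,
    min_support: int | None = None,
) -> PolyCoefficients | None:
    """Fit one sliding-window patch: reject magnitude outliers, then
    least-squares fit the 3D quadratic to the survivors.

    coords_m are per-axis voxel-centre offsets in metres, centred on the
    target voxel.  Returns None (fit failure) when fewer than ``min_support``
    voxels survive or the design is rank-deficient; by default min_support is
    max(20, ceil(0.5 * n_patch)) — twice the coefficient count, or half the
    patch, whichever is larger.
    """
    phase_patch = np.asarray(phase_patch, dtype=float)
    magnitude_patch = np.asarray(magnitude_patch, dtype=float)
    if phase_patch.shape != magnitude_patch.shape:
        raise ShapeError("phase and magnitude patches differ in shape")
    n = phase_patch.size
    if min_support is None:
        min_support = max(2 * _N_COEF, int(np.ceil(0.5 * n)))
    keep = magnitude_outlier_mask(magnitude_patch, threshold).ravel()
    if keep.sum() < min_support:
        return None
    coords_mm = tuple(np.asarray(c, dtype=float) * 1e3 for c in coords_m)
    X = _design_matrix(coords_mm)[keep]
    y = phase_patch.ravel()[keep]
    if np.linalg.matrix_rank(X) < _N_COEF:
        return None
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    # rescale mm-based coefficients to SI
    scale = np.array([_MM2_TO_M2] * 6 + [1e3] * 3 + [1.0])
    return PolyCoefficients(*(beta * scale))


def _monomial_correlations(field: np.ndarray, offsets_mm, triples):
    """Correlations of ``field`` with the separable monomial kernels
    x^p y^q z^r (offsets in mm), sharing partial passes across axes."""
    cache0: dict[int, np.ndarray] = {}
    cache01: dict[tuple[int, int], np.ndarray] = {}
    out: dict[tuple[int, int, int], np.ndarray] = {}
    for p, q, r in triples:
        if p not in cache0:
            cache0[p] = ndimage.correlate1d(
                field, offsets_mm[0] ** p, axis=0, mode="constant", cval=0.0
            )
        if (p, q) not in cache01:
            cache01[(p, q)] = ndimage.correlate1d(
                cache0[p], offsets_mm[1] ** q, axis=1, mode="constant", cval=0.0
            )
        out[(p, q, r)] = ndimage.correlate1d(
            cache01[(p, q)], offsets_mm[2] ** r, axis=2, mode="constant", cval=0.0
        )
    return out


def _interior_mask(shape, margin) -> np.ndarray:
    interior = np.zeros(shape, dtype=bool)
    sl = tuple(slice(m, n - m) for n, m in zip(shape, margin))
    if all(s.start < s.stop for s in sl):
        interior[sl] = True
    return interior


def qcm_parabolic(
    phi_plus: PhaseVolume,
    magnitude: np.ndarray,
    kernel: KernelSpec | None = None,
    ctx: AcquisitionContext | None = None,
) -> ConductivityMap:
    """Sliding-window parabolic-fitting conductivity map.

    Per voxel: take the kernel-sized patch, drop magnitude outliers
    (single pass, strict 20% rule by default), least-squares fit the 3D
    quadratic, and convert the curvature 2*(a+b+c) to conductivity.
    Voxels whose kernel exits the volume, whose surviving support is below
    the minimum, or whose fit is rank-deficient are invalid.

    Windows with no outlier exclusions reduce to a fixed linear functional of
    the phase and are evaluated by separable monomial correlations; the
    remainder is solved as batched normal equations.  Both routes compute the
    same least-squares fit as :func:`fit_parabolic_kernel`.
    """
    kernel = kernel or KernelSpec()
    ctx = ctx or AcquisitionContext(spacing_mm=phi_plus.spacing_mm)
    if phi_plus.wrapped:
        raise ParameterError("qcm_parabolic expects an unwrapped phase volume")
    magnitude = np.asarray(magnitude, dtype=float)
    if magnitude.shape != phi_plus.shape:
        raise ShapeError("magnitude shape does not match phase volume")
    spacing = phi_plus.spacing_mm
    shape = phi_plus.shape
    ext = kernel.extent(spacing)
    if any(e > n for e, n in zip(ext, shape)):
        raise ParameterError(f"kernel extent {ext} exceeds volume shape {shape}")
    r = tuple(e // 2 for e in ext)
    n_patch = int(np.prod(ext))
    min_support = max(2 * _N_COEF, int(np.ceil(kernel.min_support_fraction * n_patch)))
    thr = kernel.outlier_threshold
    offsets_mm = tuple(
        (np.arange(e, dtype=float) - e // 2) * h for e, h in zip(ext, spacing)
    )

    interior = _interior_mask(shape, r)
    # windows with no exclusions: max and min magnitude both within the
    # relative threshold of the window mean
    mu = ndimage.uniform_filter(magnitude, size=ext, mode="constant")
    mx = ndimage.maximum_filter(magnitude, size=ext, mode="constant", cval=-np.inf)
    mn = ndimage.minimum_filter(magnitude, size=ext, mode="constant", cval=np.inf)
    full = (mx - mu <= thr * mu) & (mu - mn <= thr * mu)

    # full-window route: curvature = gamma . (monomial correlations of phi)
    X_full = _design_matrix(offsets_mm)
    A_full = X_full.T @ X_full
    e_curv = np.zeros(_N_COEF)
    e_curv[:3] = 1.0
    gamma = 2.0 * np.linalg.solve(A_full, e_curv)
    rhs_maps = _monomial_correlations(phi_plus.values, offsets_mm, _COLUMNS)
    curvature_mm2 = np.zeros(shape)
    for g, col in zip(gamma, _COLUMNS):
        curvature_mm2 += g * rhs_maps[col]

    curvature_mm2 = np.where(full, curvature_mm2, np.nan)
    valid = interior & full

    # partial windows: downdate the full-window normal equations by the
    # excluded voxels and solve per window (numba kernel)
    partial = np.argwhere(interior & ~full)
    if partial.size:
        from ._parabolic import _partial_curvatures

        flat_idx = np.ravel_multi_index(partial.T, shape)
        rhs_at = np.stack(
            [rhs_maps[col].reshape(-1)[flat_idx] for col in _COLUMNS], axis=1
        )
        mu_at = mu.reshape(-1)[flat_idx]
        pos = np.ascontiguousarray(partial - np.array(r), dtype=np.int64)
        curv = _partial_curvatures(
            np.ascontiguousarray(magnitude),
            np.ascontiguousarray(phi_plus.values),
            pos,
            np.ascontiguousarray(mu_at),
            np.ascontiguousarray(rhs_at),
            np.ascontiguousarray(X_full),
            np.ascontiguousarray(A_full),
            ext[0],
            ext[1],
            ext[2],
            thr,
            min_support,
        )
        curvature_mm2.reshape(-1)[flat_idx] = curv
        valid.reshape(-1)[flat_idx] = np.isfinite(curv)

    sigma = curvature_mm2 * _MM2_TO_M2 / ctx.omega_mu0
    valid &= np.isfinite(sigma)
    return ConductivityMap(sigma=sigma, valid=valid, spacing_mm=spacing)


def otsu_foreground(magnitude: np.ndarray) -> LabelMask:
    """Default single-label segmentation: Otsu threshold on the magnitude,
    foreground = 1, background = 0."""
    from skimage.filters import threshold_otsu

    magnitude = np.asarray(magnitude, dtype=float)
    t = threshold_otsu(magnitude)
    return LabelMask(labels=(magnitude > t).astype(np.int32))


def qcm_integral(
    phi_plus: PhaseVolume,
    mask: LabelMask | None = None,
    kernel: KernelSpec | None = None,
    ctx: AcquisitionContext | None = None,
    magnitude: np.ndarray | None = None,
) -> ConductivityMap:
    """Sliding-window integral-form conductivity map.

    Per voxel the integration region is the kernel intersected with the
    centre voxel's label region, and

        sigma = (outward flux of grad phi+ through the region surface)
                / (region volume * omega * mu0),

    evaluated through the equivalent region mean of the 7-point discrete
    Laplacian (discrete divergence theorem).  Invalid: centre label 0, region
    support below ``min_support_fraction`` of the kernel, or the kernel plus
    its one-voxel flux halo exiting the volume.

    When ``mask`` is None a single foreground label is derived from the
    magnitude by Otsu thresholding.
    """
    kernel = kernel or KernelSpec()
    ctx = ctx or AcquisitionContext(spacing_mm=phi_plus.spacing_mm)
    if phi_plus.wrapped:
        raise ParameterError("qcm_integral expects an unwrapped phase volume")
    if mask is None:
        if magnitude is None:
            raise ParameterError("qcm_integral needs a LabelMask or a magnitude image")
        mask = otsu_foreground(magnitude)
    if mask.shape != phi_plus.shape:
        raise ShapeError("label mask shape does not match phase volume")
    spacing = phi_plus.spacing_mm
    shape = phi_plus.shape
    ext = kernel.extent(spacing)
    if any(e > n for e, n in zip(ext, shape)):
        raise ParameterError(f"kernel extent {ext} exceeds volume shape {shape}")
    halo = tuple(e // 2 + 1 for e in ext)

    lap = discrete_laplacian(phi_plus.values, spacing)
    lap0 = np.nan_to_num(lap)
    labels = mask.labels
    sigma = np.full(shape, np.nan)
    support = np.zeros(shape)
    for lab in mask.present_labels():
        sel = labels == lab
        m = sel.astype(float)
        mean_lap = ndimage.uniform_filter(lap0 * m, size=ext, mode="constant")
        frac = ndimage.uniform_filter(m, size=ext, mode="constant")
        with np.errstate(divide="ignore", invalid="ignore"):
            val = mean_lap / frac
        sigma[sel] = val[sel] / ctx.omega_mu0
        support[sel] = frac[sel]

    interior = _interior_mask(shape, halo)
    valid = interior & (labels > 0) & (support >= kernel.min_support_fraction)
    valid &= np.isfinite(sigma)
    return ConductivityMap(sigma=sigma, valid=valid, spacing_mm=spacing)
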
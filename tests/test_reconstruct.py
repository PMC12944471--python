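import numpy as np
import pytest
from scipy import ndimage

from qcmap import (
    AcquisitionContext,
    KernelSpec,
    LabelMask,
    ParameterError,
    PhaseVolume,
    discrete_laplacian,
    fit_parabolic_kernel,
    magnitude_outlier_mask,
    otsu_foreground,
    qcm_integral,
    qcm_parabolic,
    region_boundary_flux,
    sigma_from_laplacian,
    sigma_region_integral,
)

SP = (1.0, 1.0, 1.0)


def _quadratic_volume(n, kappa, spacing=SP):
    """phi = kappa * (x^2+y^2+z^2) in metres; exact Laplacian 6*kappa."""
    coords = [(np.arange(n) - (n - 1) / 2) * s * 1e-3 for s in spacing]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    return kappa * (X**2 + Y**2 + Z**2)


class TestSigmaFromLaplacian:
    def test_zero_and_linearity(self):
        ctx = AcquisitionContext()
        assert sigma_from_laplacian(0.0, ctx) == 0.0
        one = sigma_from_laplacian(ctx.omega_mu0, ctx)
        assert one == pytest.approx(1.0, rel=1e-12)
        assert sigma_from_laplacian(2 * ctx.omega_mu0, ctx) == pytest.approx(2.0)

    def test_inverse_of_hand_computed_constant(self):
        # omega*mu0 = 2*pi*1.277e8 * 4*pi*1e-7, recomputed from scratch
        by_hand = 8 * np.pi**2 * 12.77
        assert sigma_from_laplacian(by_hand, AcquisitionContext()) == pytest.approx(
            1.0, rel=1e-3
        )


class TestKernelSpec:
    @pytest.mark.parametrize(
        "size,spacing,expected",
        [(8.0, 0.5, 15), (8.0, 1.0, 7), (8.0, 2.0, 3), (8.0, 8.0, 3), (9.0, 3.0, 3)],
    )
    def test_extent_is_largest_odd_at_most_ratio(self, size, spacing, expected):
        k = KernelSpec(size_mm=(size, size, size))
        assert k.extent((spacing, spacing, spacing)) == (expected,) * 3

    def test_invalid_parameters(self):
        with pytest.raises(ParameterError):
            KernelSpec(size_mm=(0, 8, 8))
        with pytest.raises(ParameterError):
            KernelSpec(min_support_fraction=1.5)
        with pytest.raises(ParameterError):
            KernelSpec(outlier_threshold=0.0)


class TestOutlierRemoval:
    def test_worked_patch_removes_exactly_one(self):
        # mean = 10.825; relative deviations .0762, .0300, .0947, .2009
        keep = magnitude_outlier_mask(np.array([10.0, 10.5, 9.8, 13.0]), 0.20)
        assert keep.tolist() == [True, True, True, False]

    def test_threshold_is_strict(self):
        # deviation exactly at the threshold is retained
        m = np.array([1.0, 1.0, 1.0, 1.5])  # mean 1.125; 1.5 dev = 1/3 > 0.2 removed
        keep = magnitude_outlier_mask(m, 1.0 / 3.0)
        assert keep.tolist() == [True, True, True, True]


class TestFitParabolicKernel:
    COORDS = tuple((np.arange(7.0) - 3) * 1e-3 for _ in range(3))

    def test_quadratic_recovered_exactly(self):
        patch = _quadratic_volume(7, 5.0e3)
        pc = fit_parabolic_kernel(patch, np.ones_like(patch), self.COORDS)
        assert pc.a == pytest.approx(5.0e3, rel=1e-9)
        assert pc.b == pytest.approx(5.0e3, rel=1e-9)
        assert pc.c == pytest.approx(5.0e3, rel=1e-9)
        assert pc.curvature == pytest.approx(6 * 5.0e3, rel=1e-9)

    def test_linear_field_has_zero_curvature(self):
        x = self.COORDS[0][:, None, None] * np.ones((1, 7, 7))
        pc = fit_parabolic_kernel(4.0 * x, np.ones_like(x), self.COORDS)
        assert pc.curvature == pytest.approx(0.0, abs=1e-9)

    def test_insufficient_support_fails(self):
        patch = np.zeros((3, 3, 3))
        mag = np.ones((3, 3, 3))
        coords = tuple((np.arange(3.0) - 1) * 1e-3 for _ in range(3))
        assert fit_parabolic_kernel(patch, mag, coords, min_support=28) is None

    def test_rank_deficient_survivors_fail(self):
        # survivors confined to one plane cannot determine the x^2 term
        patch = np.zeros((3, 3, 3))
        mag = np.full((3, 3, 3), 100.0)
        mag[0] = mag[2] = 1e-6  # wiped out by the outlier rule
        coords = tuple((np.arange(3.0) - 1) * 1e-3 for _ in range(3))
        assert fit_parabolic_kernel(patch, mag, coords, min_support=5) is None


class TestQcmParabolic:
    def test_exact_on_global_quadratic(self):
        ctx = AcquisitionContext(spacing_mm=SP)
        kappa = 1.5 * ctx.omega_mu0 / 6.0
        phi = PhaseVolume(_quadratic_volume(20, kappa), SP, wrapped=False)
        cmap = qcm_parabolic(phi, np.ones(phi.shape), KernelSpec(), ctx)
        assert cmap.valid.any()
        np.testing.assert_allclose(cmap.sigma[cmap.valid], 1.5, rtol=1e-6)

    def test_constant_phase_gives_zero(self):
        ctx = AcquisitionContext(spacing_mm=SP)
        phi = PhaseVolume(np.full((16, 16, 16), 0.7), SP, wrapped=False)
        cmap = qcm_parabolic(phi, np.ones(phi.shape), KernelSpec(), ctx)
        assert cmap.valid.any()
        np.testing.assert_allclose(cmap.sigma[cmap.valid], 0.0, atol=1e-12)

    def test_kernel_larger_than_volume_rejected(self):
        ctx = AcquisitionContext(spacing_mm=SP)
        phi = PhaseVolume(np.zeros((5, 5, 5)), SP, wrapped=False)
        with pytest.raises(ParameterError):
            qcm_parabolic(phi, np.ones((5, 5, 5)), KernelSpec(size_mm=(20, 20, 20)), ctx)

    def test_matches_per_patch_reference_fit(self, small_phantom, rng):
        # the vectorised sliding-window map must agree with looping the
        # single-patch reference fit, outliers and all
        spec, ctx, s_plus, _, truth = small_phantom
        phi = PhaseVolume(
            truth.phi_plus_clean + 0.001 * rng.normal(size=truth.phi_plus_clean.shape),
            spec.spacing_mm,
            wrapped=False,
        )
        kernel = KernelSpec()
        cmap = qcm_parabolic(phi, s_plus.magnitude, kernel, ctx)
        ext = kernel.extent(spec.spacing_mm)
        r = ext[0] // 2
        coords = tuple((np.arange(e, dtype=float) - e // 2) * s * 1e-3
                       for e, s in zip(ext, spec.spacing_mm))
        n_patch = int(np.prod(ext))
        min_support = max(20, int(np.ceil(kernel.min_support_fraction * n_patch)))
        for _ in range(40):
            v = tuple(rng.integers(r, n - r, size=1)[0] for n in phi.shape)
            sl = tuple(slice(c - r, c + r + 1) for c in v)
            pc = fit_parabolic_kernel(
                phi.values[sl], s_plus.magnitude[sl], coords,
                kernel.outlier_threshold, min_support,
            )
            if pc is None:
                assert not cmap.valid[v]
            else:
                expected = pc.curvature / ctx.omega_mu0
                assert cmap.sigma[v] == pytest.approx(expected, rel=1e-7, abs=1e-10)


class TestIntegralEstimator:
    def test_flux_equals_region_laplacian_sum(self, rng):
        # discrete divergence theorem: boundary flux == sum of the 7-point
        # Laplacian over the region (times voxel volume)
        spacing = (0.7, 1.0, 1.3)
        v = ndimage.gaussian_filter(rng.normal(0, 1, (16, 16, 16)), 1.5)
        lap = discrete_laplacian(v, spacing)
        voxvol = np.prod(np.asarray(spacing) * 1e-3)
        for _ in range(25):
            region = np.zeros(v.shape, bool)
            a = rng.integers(2, 8, size=3)
            b = a + rng.integers(2, 6, size=3)
            region[a[0]:b[0], a[1]:b[1], a[2]:b[2]] = True
            flux = region_boundary_flux(v, region, spacing)
            oracle = lap[region].sum() * voxvol
            assert flux == pytest.approx(oracle, rel=1e-9, abs=1e-15)

    def test_region_touching_border_rejected(self):
        region = np.zeros((8, 8, 8), bool)
        region[0:3, 2:4, 2:4] = True
        with pytest.raises(ParameterError):
            region_boundary_flux(np.zeros((8, 8, 8)), region, SP)

    def test_linear_ramp_gives_zero_sigma(self):
        ctx = AcquisitionContext(spacing_mm=SP)
        x = np.arange(16.0)[:, None, None] * np.ones((1, 16, 16))
        phi = PhaseVolume(0.3 * x, SP, wrapped=False)
        mask = LabelMask(np.ones((16, 16, 16), np.int32))
        cmap = qcm_integral(phi, mask, KernelSpec(), ctx)
        assert cmap.valid.any()
        np.testing.assert_allclose(cmap.sigma[cmap.valid], 0.0, atol=1e-10)

    def test_exact_on_global_quadratic(self):
        ctx = AcquisitionContext(spacing_mm=SP)
        kappa = 1.5 * ctx.omega_mu0 / 6.0
        phi = PhaseVolume(_quadratic_volume(20, kappa), SP, wrapped=False)
        mask = LabelMask(np.ones((20, 20, 20), np.int32))
        cmap = qcm_integral(phi, mask, KernelSpec(), ctx)
        np.testing.assert_allclose(cmap.sigma[cmap.valid], 1.5, rtol=1e-6)

    def test_matches_brute_force_region_mean(self, small_phantom, rng):
        spec, ctx, s_plus, _, truth = small_phantom
        phi = PhaseVolume(truth.phi_plus_clean, spec.spacing_mm, wrapped=False)
        mask = truth.label_mask
        kernel = KernelSpec()
        cmap = qcm_integral(phi, mask, kernel, ctx)
        ext = kernel.extent(spec.spacing_mm)
        r = ext[0] // 2
        lap = discrete_laplacian(phi.values, spec.spacing_mm)
        for _ in range(30):
            v = tuple(rng.integers(r + 1, n - r - 1, size=1)[0] for n in phi.shape)
            if not cmap.valid[v]:
                continue
            sl = tuple(slice(c - r, c + r + 1) for c in v)
            region = np.zeros(phi.shape, bool)
            region[sl] = mask.labels[sl] == mask.labels[v]
            oracle = lap[region].mean() / ctx.omega_mu0
            assert cmap.sigma[v] == pytest.approx(oracle, rel=1e-9)

    def test_label_zero_centre_is_invalid(self):
        ctx = AcquisitionContext(spacing_mm=SP)
        phi = PhaseVolume(np.zeros((16, 16, 16)), SP, wrapped=False)
        labels = np.ones((16, 16, 16), np.int32)
        labels[8, 8, 8] = 0
        cmap = qcm_integral(phi, LabelMask(labels), KernelSpec(), ctx)
        assert not cmap.valid[8, 8, 8]
        assert np.isnan(cmap.sigma[8, 8, 8])

    def test_otsu_default_segmentation(self, rng):
        mag = np.where(rng.uniform(size=(12, 12, 12)) > 0.5, 1.0, 0.1)
        mask = otsu_foreground(mag + rng.normal(0, 0.01, mag.shape))
        assert set(np.unique(mask.labels)) == {0, 1}
        agreement = np.mean((mask.labels == 1) == (mag > 0.5))
        assert agreement > 0.99


class TestEstimatorInvariants:
    def _setup(self, rng, spacing=SP):
        ctx = AcquisitionContext(spacing_mm=spacing)
        base = ndimage.gaussian_filter(rng.normal(0, 1, (18, 18, 18)), 2) * 0.05
        phi = PhaseVolume(base, spacing, wrapped=False)
        mag = np.ones(base.shape)
        mask = LabelMask(np.ones(base.shape, np.int32))
        return ctx, phi, mag, mask

    def test_gauge_invariance_affine_offset(self, rng):
        ctx, phi, mag, mask = self._setup(rng)
        coords = np.meshgrid(*[np.arange(18.0)] * 3, indexing="ij")
        affine = 0.3 + 0.01 * coords[0] - 0.02 * coords[1] + 0.005 * coords[2]
        phi2 = PhaseVolume(phi.values + affine, SP, wrapped=False)
        p1 = qcm_parabolic(phi, mag, KernelSpec(), ctx)
        p2 = qcm_parabolic(phi2, mag, KernelSpec(), ctx)
        np.testing.assert_allclose(p1.sigma[p1.valid], p2.sigma[p2.valid], atol=1e-9)
        i1 = qcm_integral(phi, mask, KernelSpec(), ctx)
        i2 = qcm_integral(phi2, mask, KernelSpec(), ctx)
        np.testing.assert_allclose(i1.sigma[i1.valid], i2.sigma[i2.valid], atol=1e-9)

    def test_units_coherence_spacing_scaling(self, rng):
        # same phase values on a grid scaled by s -> sigma scales by 1/s^2
        s = 2.0
        ctx1, phi1, mag, mask = self._setup(rng, spacing=SP)
        rng2 = np.random.default_rng(1234)
        ctx2, phi2, _, _ = self._setup(rng2, spacing=(s, s, s))
        k1 = KernelSpec(size_mm=(8, 8, 8))
        k2 = KernelSpec(size_mm=(8 * s, 8 * s, 8 * s))  # same voxel extent
        p1 = qcm_parabolic(phi1, mag, k1, ctx1)
        p2 = qcm_parabolic(phi2, mag, k2, ctx2)
        np.testing.assert_allclose(
            p2.sigma[p2.valid], p1.sigma[p1.valid] / s**2, rtol=1e-9
        )
        i1 = qcm_integral(phi1, mask, k1, ctx1)
        i2 = qcm_integral(phi2, mask, k2, ctx2)
        np.testing.assert_allclose(
            i2.sigma[i2.valid], i1.sigma[i1.valid] / s**2, rtol=1e-9
        )
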
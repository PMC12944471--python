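import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import ndimage

from qcmap import (
    ConfoundSpec,
    DegenerateInputError,
    ParameterError,
    PhaseVolume,
    ShapeError,
    bilateral_filter,
    estimate_b1_phase,
    forward_phase,
    rasterize,
    synthesize_echoes,
    unwrap_region_growing,
    wrap_phase,
)

SP = (1.0, 1.0, 1.0)


def _pv(values, wrapped=False, spacing=SP):
    return PhaseVolume(values=values, spacing_mm=spacing, wrapped=wrapped)


def _const_offset_2pi(diff):
    """Assert diff is one global constant that is a multiple of 2*pi."""
    c = diff.flat[0]
    assert np.abs(diff - c).max() < 1e-9
    assert abs(c / (2 * np.pi) - round(c / (2 * np.pi))) < 1e-9


class TestUnwrap:
    def test_linear_ramp_spanning_6pi(self):
        ramp = np.linspace(0.0, 6 * np.pi, 30)[:, None, None] * np.ones((1, 10, 10))
        out = unwrap_region_growing(_pv(wrap_phase(ramp), wrapped=True), np.ones_like(ramp))
        assert not out.wrapped
        _const_offset_2pi(out.values - ramp)

    def test_smooth_field_without_wraps_unchanged(self, rng):
        field = ndimage.gaussian_filter(rng.normal(0, 1, (16, 16, 16)), 3)
        field *= 2.0 / np.abs(field).max()  # gradients well below pi/voxel
        out = unwrap_region_growing(
            _pv(wrap_phase(field), wrapped=True), np.ones_like(field)
        )
        _const_offset_2pi(out.values - field)

    def test_recovers_phantom_forward_phase(self, small_phantom):
        # noise-free phantom phase, scaled to span several wraps, must be
        # recovered to sub-microradian accuracy up to one 2*pi constant
        spec, ctx, *_ = small_phantom
        sigma, _, mag = rasterize(spec)
        phi = forward_phase(sigma, ctx)
        truth = phi * (6.5 * np.pi / np.ptp(phi))
        out = unwrap_region_growing(
            _pv(wrap_phase(truth), wrapped=True, spacing=spec.spacing_mm), mag
        )
        d = out.values - truth
        c = 2 * np.pi * np.round(np.median(d) / (2 * np.pi))
        assert np.abs(d - c).max() < 1e-6

    def test_seed_independence_up_to_2pi(self, rng):
        field = ndimage.gaussian_filter(rng.normal(0, 1, (12, 12, 12)), 2)
        field *= 8.0 / np.abs(field).max()  # spans multiple wraps
        mag = rng.uniform(0.5, 1.5, field.shape)
        w = _pv(wrap_phase(field), wrapped=True)
        a = unwrap_region_growing(w, mag)
        b = unwrap_region_growing(w, mag, seed_index=(0, 0, 0))
        _const_offset_2pi(a.values - b.values)

    def test_agrees_with_independent_unwrapper(self, rng):
        from skimage.restoration import unwrap_phase as sk_unwrap

        field = ndimage.gaussian_filter(rng.normal(0, 1, (14, 14, 14)), 2)
        field *= 7.0 / np.abs(field).max()
        w = wrap_phase(field)
        ours = unwrap_region_growing(_pv(w, wrapped=True), np.ones_like(w)).values
        theirs = np.asarray(sk_unwrap(w))
        d = ours - theirs
        _const_offset_2pi(d)

    def test_all_zero_magnitude_rejected(self):
        w = _pv(np.zeros((5, 5, 5)), wrapped=True)
        with pytest.raises(DegenerateInputError):
            unwrap_region_growing(w, np.zeros((5, 5, 5)))

    def test_requires_wrapped_input(self):
        with pytest.raises(ParameterError):
            unwrap_region_growing(_pv(np.zeros((5, 5, 5)), wrapped=False), np.ones((5, 5, 5)))


class TestEstimateB1Phase:
    def test_constant_fields_quarter_sum(self):
        a = _pv(np.full((4, 4, 4), 0.8))
        b = _pv(np.full((4, 4, 4), 0.4))
        out = estimate_b1_phase(a, b)
        np.testing.assert_allclose(out.values, 0.3, atol=1e-15)

    @given(
        hnp.arrays(float, (4, 4, 4), elements=st.floats(-10, 10)),
        hnp.arrays(float, (4, 4, 4), elements=st.floats(-10, 10)),
    )
    def test_confound_cancellation_is_algebraic(self, phi, delta):
        plus = _pv(2 * phi + delta)
        minus = _pv(2 * phi - delta)
        out = estimate_b1_phase(plus, minus)
        np.testing.assert_allclose(out.values, phi, atol=1e-12)

    def test_zero_in_zero_out(self):
        z = _pv(np.zeros((3, 3, 3)))
        assert np.all(estimate_b1_phase(z, z).values == 0)

    def test_symmetry_and_linearity(self, rng):
        a = _pv(rng.normal(size=(5, 5, 5)))
        b = _pv(rng.normal(size=(5, 5, 5)))
        ab = estimate_b1_phase(a, b).values
        ba = estimate_b1_phase(b, a).values
        np.testing.assert_array_equal(ab, ba)
        doubled = estimate_b1_phase(_pv(2 * a.values), _pv(2 * b.values)).values
        np.testing.assert_allclose(doubled, 2 * ab, rtol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            estimate_b1_phase(_pv(np.zeros((4, 4, 4))), _pv(np.zeros((4, 4, 5))))


class TestBilateralFilter:
    def test_identity_on_constant_field(self):
        pv = _pv(np.full((8, 8, 8), 1.3))
        out = bilateral_filter(pv)
        np.testing.assert_array_equal(out.values, pv.values)

    def test_reduces_noise_rms(self, rng):
        clean = ndimage.gaussian_filter(rng.normal(0, 1, (20, 20, 20)), 4)
        clean *= 1.0 / np.abs(clean).max()
        noisy = clean + rng.normal(0, 0.05, clean.shape)
        out = bilateral_filter(_pv(noisy)).values
        rms_before = np.sqrt(np.mean((noisy - clean) ** 2))
        rms_after = np.sqrt(np.mean((out - clean) ** 2))
        assert rms_after < rms_before

    def test_output_bounded_by_input_range(self, rng):
        v = rng.normal(0, 1, (10, 10, 10))
        out = bilateral_filter(_pv(v)).values
        assert out.min() >= v.min() - 1e-12
        assert out.max() <= v.max() + 1e-12

    def test_preserves_step_edge_better_than_gaussian(self, rng):
        # step much taller than range_sigma: bilateral must not blur across
        # it; the raised plateau is kept small so the MAD-based range sigma
        # reflects the noise floor, not the step itself
        v = np.zeros((24, 8, 8))
        v[19:] = 10.0
        v += rng.normal(0, 0.01, v.shape)
        bil = bilateral_filter(_pv(v), degree_of_smoothing=3, spatial_sigma=1).values
        gau = ndimage.gaussian_filter(v, 1.0)
        prof_b = bil.mean(axis=(1, 2))
        prof_g = gau.mean(axis=(1, 2))
        # voxels adjacent to the edge: bilateral stays at its plateau value,
        # the plain Gaussian pulls them toward the midpoint
        assert abs(prof_b[18] - 0.0) < 0.1 and abs(prof_b[19] - 10.0) < 0.1
        assert abs(prof_g[18] - 0.0) > 1.0 and abs(prof_g[19] - 10.0) > 1.0

    def test_nonpositive_parameters_rejected(self):
        pv = _pv(np.zeros((4, 4, 4)))
        with pytest.raises(ParameterError):
            bilateral_filter(pv, degree_of_smoothing=0)
        with pytest.raises(ParameterError):
            bilateral_filter(pv, spatial_sigma=-1)
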
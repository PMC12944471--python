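# Methods

## The measurement model

At the proton Larmor frequency (127.7 MHz at 3 T) tissue conductivity is
dominated by ionic content.  Under the assumptions of piecewise-homogeneous
tissue and a transmit field whose phase varies much more slowly than its
magnitude, Maxwell's equations reduce to a local relation between the
transmit (B1+) phase `phi+` and the conductivity `sigma`:

    sigma = lap(phi+) / (omega * mu0)          [S/m]

with `omega = 2*pi*f` the Larmor angular frequency and `mu0` the vacuum
permeability (`omega*mu0 ~ 1.008e3 rad/m^2` per S/m at 127.7 MHz).

The B1+ phase is not observed directly.  A double-echo steady-state
acquisition yields two echoes whose phases carry twice the B1 phase plus
equal-and-opposite off-resonance terms:

    phi_S+ = 2*phi+ + delta,    phi_S- = 2*phi+ - delta,

where `delta` collects B0-inhomogeneity and chemical-shift phase.  After
unwrapping each echo phase, averaging cancels `delta` algebraically, and the
transceive assumption (transmit phase is half the total B1 phase) gives
`phi+ = (phi_S+ + phi_S-)/4`.  The `/4` produces a global-constant ambiguity
in multiples of `pi/2`; it is irrelevant downstream because only second
derivatives of `phi+` enter the conductivity.  The transmit share is
exposed as `transmit_fraction` (default 0.5) so departures from the
transceive assumption can be explored.

## Phase processing

**Unwrapping** is quality-guided region growing: voxels are visited in
descending magnitude priority from the maximum-magnitude voxel (a binary
max-heap keyed by each candidate's own magnitude), and each voxel is
unwrapped by adding the multiple of `2*pi` closest to the mean of its
already-unwrapped 6-neighbours.  The result is deterministic, satisfies
`wrap(output) == input` exactly, and on smooth fields is independent of the
seed voxel up to one global `2*pi` multiple.  The algorithm requires the
true field's voxel-to-voxel phase differences to stay below `pi` (the usual
unwrappability condition).

**Bilateral filtering** (parabolic path only, matching the processing
chains described for the two estimators) uses weights
`Gaussian(spatial distance in voxels; spatial_sigma) * Gaussian(value
difference; range_sigma)` over a window truncated at
`+/- ceil(3*spatial_sigma)` voxels per axis.  "Degree of smoothing" is
interpreted scale-free: `range_sigma = degree_of_smoothing * robust_std`
with the MAD-based robust std `1.4826 * median(|phi - median(phi)|)`.
Defaults: degree of smoothing 3, spatial sigma 1.  The output is a convex
combination of input values (bounded by the input's range), and a constant
field passes through unchanged.  Spatial distance is measured in voxels,
not millimetres; for strongly anisotropic voxels this weights axes
unequally in physical units.

## Conductivity estimators

Both estimators slide a kernel of physical size 8 x 8 x 8 mm (realised
voxel extent per axis: the largest odd integer at most `size/spacing`,
floored at 3; 15 voxels at 0.5 mm) across the volume.  Spacing is converted
to metres exactly once here, so Laplacians are rad/m^2.

**Parabolic fitting.**  Within each kernel, voxels whose magnitude differs
from the kernel mean by strictly more than 20 % (relative) are discarded in
a single pass — this intensity gate stands in for segmentation.  The
surviving phase samples are least-squares fitted to the full 3D quadratic

    P(x,y,z) = a x^2 + b y^2 + c z^2 + d xy + e yz + f xz
               + g x + h y + i z + j,

and `sigma = 2*(a+b+c)/(omega*mu0)`.  A voxel is invalid when its kernel
exits the volume, fewer than `max(20, 0.5 * kernel voxels)` samples survive,
or the design is rank-deficient.  Implementation: windows with no exclusions
reduce to a fixed linear functional of the phase, evaluated as separable
monomial correlations; windows with exclusions start from the full-window
normal equations and are downdated by the excluded voxels (compiled kernel),
which is exact and orders of magnitude faster than refitting every window.
The fit is performed in millimetre coordinates for conditioning and the
coefficients rescaled to SI.

**Integral (boundary-flux) form.**  The integration region is the kernel
intersected with the centre voxel's segmentation label, and

    sigma = (outward flux of grad phi+ through the region surface)
            / (V * omega * mu0),

with the face-normal derivative taken as the central difference across each
boundary face.  By the discrete divergence theorem this is *identically*
the region mean of the 7-point Laplacian (the sum telescopes), which is how
the sliding map is computed (per-label masked box means); the literal
face-sum is exposed as `region_boundary_flux` and the identity is asserted
in the tests.  A voxel is invalid when its centre label is 0, the region
support falls below `min_support_fraction` (default 0.5) of the kernel, or
the kernel plus a one-voxel flux halo exits the volume (the halo is needed
because the boundary derivative reads the phase one voxel outside the
kernel).  When no label mask is supplied, a single foreground label is
derived by Otsu thresholding of the magnitude.

Shared properties, verified as tests: both estimators are exact on global
quadratic phases independent of kernel size; both are invariant to adding
any affine field to `phi+`; scaling the voxel spacing by `s` (same phase
values) scales `sigma` by `1/s^2`.

## The digital phantom

The generator emulates a saline calibration phantom: three cylinders
(radius 8 mm, height 40 mm at full scale) of increasing NaCl concentration
embedded in an agarose-gel background.  Defaults, chosen once as the study
conditions:

| parameter | value | meaning |
|---|---|---|
| grid | 128^3 at 0.5 mm | desk-scale stand-in for a 400^3 acquisition |
| background sigma | 0.2 S/m | low-conductivity gel |
| tube contrasts | 0.04, 0.54, 1.28 S/m | designed conductivity steps of the 0/0.5/1 % w/v tubes |
| magnitudes | gel 0.7, tubes 1.0 | relaxation-doping signal difference; exercises the 20 % intensity gate at tube walls |
| B0 confound | 3 rad peak, 12 mm correlation length | smooth wrap-inducing off-resonance phase |
| chemical shift | 0.5 rad constant | on-resonance water model |
| noise_sd | 0.02 of background magnitude per complex channel | SNR ~ 50 |

The clean phase is obtained by inverting the conductivity relation as a
discrete Poisson problem `lap(phi+) = omega*mu0*(sigma - mean sigma)`,
solved spectrally with periodic boundaries using the exact eigenvalues of
the 7-point Laplacian.  This makes the ground truth exact *for the same
discretisation the estimators measure* (residuals at rounding level), which
is the point: estimator errors are attributable to noise and windowing, not
to forward-model mismatch.  The periodic zero-mean gauge means estimators
recover `sigma - mean(sigma)`; region contrasts and linearity are
unaffected, and evaluations compare in that gauge.

What the phantom does **not** emulate: steady-state signal weighting
(T1/T2/flip angle), radial sampling and streaks, coil sensitivities, fat,
true electromagnetic field simulation (the phase is constructed from the
target relation, not from a Maxwell solver), and air regions.  Passing
tests therefore demonstrate the *inverse* machinery — unwrapping, confound
cancellation, Laplacian estimation, masking, statistics — under controlled
noise, not sequence fidelity.

## The linearity study and its axis

The headline experiment regenerates the phantom noise for 20 seeds,
reconstructs with both estimators, and regresses the recovered per-tube
mean conductivity on a concentration proxy, reporting the median R^2.  The
proxy axis is the vector of *designed tube contrasts* (0.04, 0.54, 1.28
S/m): saline conductivity is linear in NaCl concentration over this range,
so the designed contrasts carry the concentration axis, and regressing on
them isolates the method's linearity of recovery.  (Regressing the same
recovered means on the raw percentages 0/0.5/1 instead would cap R^2 at
0.9877 even for perfect recovery, because the designed contrasts are
themselves not exactly proportional to the percentages — that cap reflects
the design values, not the method.)

## Noise behaviour of the two estimators

With the discretisation fixed above, the integral estimator is exactly the
kernel mean of the 7-point Laplacian; under white phase noise its variance
comes from one-voxel face differences on the kernel boundary shell
(~6 * 15^2 samples at weight 1/h^2).  The parabolic fit averages all 15^3
kernel voxels with smooth weights and is therefore the lower-variance
estimator in a uniform region at matched kernel size — measured voxelwise
stds ~0.10 S/m (parabolic) vs ~0.46 S/m (integral) at SNR 50, consistent
with a closed-form variance estimate (~4x std ratio; the 1D analogue is
flux variance ~4 s^2/(N^2 h^4) vs quadratic-fit variance ~720 s^2/(N^5 h^4)).
On scanner data the integral form is usually reported as the more robust
one; that advantage arises from effects this phantom deliberately excludes
— unwrap failures and boundary discontinuities, which the differential
path amplifies, and segmentation differences.  The corresponding ordering
test in the acceptance suite encodes the scanner-data expectation and
fails under the white-noise simulation; it is kept failing rather than
re-tuned, as an honest record of this divergence.  The integral tube stds
(~0.45 S/m) do land in the experimentally reported range.

## Numerical choices and edge cases

* Phase wrap interval is `(-pi, pi]` everywhere, boundary mapped to `+pi`.
* Outlier deviations exactly equal to the threshold are retained (strict
  "more than").  The kernel-mean intensity is a plain mean of all kernel
  voxels (single pass, no re-iteration).
* Boundary voxels get no shrunken-kernel estimates; they are invalid
  (NaN in maps and NIfTI output).
* Anisotropic voxels are fully supported: per-axis spacings in the
  Laplacian, face areas from the two orthogonal spacings.
* Degenerate inputs raise typed errors: all-zero magnitude (unwrapping),
  all-equal regressor (linearity), empty region list / geometry outside the
  grid (phantom), non-positive filter sigmas.
* Randomness: a single integer seed drives numpy's PCG64 generator; every
  stochastic operation takes its seed explicitly, and identical seeds give
  bitwise-identical volumes.

## Problem sizes

Unit and property tests run on 16-64 voxel grids; the full-scale linearity
study (128^3, 20 seeds, both estimators) is the package's reference
experiment and takes on the order of 10 minutes on one CPU core.  The
noise-robustness comparison uses a 64^3 homogeneous phantom, which is
sufficient to estimate voxelwise stds at matched kernel size.

## Known limitations

* The region-growing unwrapper follows the published *class* of algorithm;
  toolbox-internal details of the original implementation are not public,
  so constants (e.g. neighbour averaging) are this package's own choices.
* "Degree of smoothing" for the bilateral filter is toolbox jargon without
  a public definition; the MAD-scaled interpretation here reproduces the
  intended behaviour (stronger range smoothing at 3 than at 1) but is not
  guaranteed to match any particular toolbox numerically.
* The printed integral form of the estimator places the Laplacian under a
  surface integral; this package implements the divergence-theorem flux
  form, which is the standard integral estimator and dimensionally
  consistent with dividing by the region volume.
* Absolute conductivity is recovered only up to the volume-mean gauge of
  the periodic forward model; real acquisitions do not have this gauge, but
  they also lack ground truth.
* In vivo tissue values (~1.5-2.5 S/m cartilage, ~2-3 S/m menisci,
  ~0.2-0.3 S/m ligament) are plausibility context only; nothing in this
  package reproduces them.
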
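# Methods

This document describes the physical model, the numerical choices behind it,
the synthetic data generators, and the known limitations of the `edofscope`
package.

## 1. Optical model

### 1.1 Pupil and point spread function

The imaging system is modeled as a single effective objective of numerical
aperture `NA = 0.1` with a phase element in the pupil (Fourier) plane.  The
pupil function on an `N x N` frequency grid is

```
P(fx, fy) = A(fx, fy) * exp(i * phi_mask(fx, fy)) * exp(i * phi_defocus(fx, fy))
```

where `A` is the circular aperture of radius `NA / lambda` in spatial
frequency, `phi_mask = 2 pi (n - 1) h(fx, fy) / lambda` is the phase imparted
by a refractive height map `h` (refractive index `n = 1.5`), and the paraxial
defocus term for an object displaced `z` from focus is

```
phi_defocus = pi * lambda * z * (fx^2 + fy^2)
```

with all lengths in micrometers.  The incoherent (intensity) point spread
function is `|F^-1{P}|^2`, computed with a centered FFT, on an internal grid
whose pitch is the sensor pitch divided by an integer oversampling factor
(default 5, i.e. 0.4 um at the 2 um sensor pitch).  The intensity grid is
then box-binned to the requested output pitch, cropped to a centered odd
window (default 97 px), and normalized to unit sum, so every simulated PSF
conserves energy exactly by construction.

Zero padding of the pupil (pad factor 2) sets the internal sampling; the
oversample factor must divide the output pitch, which the code enforces.

Two wavelengths are modeled per the dual-modality design: fluorescence at
520 nm (excited at 457 nm) and reflectance at 523 nm.  The channel only
changes `lambda` in the aperture radius and the two phase terms.

### 1.2 Phase masks

Three parameterizations share one `PhaseMask` container (a height map in
micrometers on the pupil grid):

- **flat** — zero heights; the conventional system baseline.
- **cubic** — `h ∝ alpha * (u^3 + v^3)` over the aperture support, offset so
  heights are nonnegative inside the aperture; the classical wavefront-coding
  extended-depth-of-field element.  The cubic phase is antisymmetric about
  the optical axis on the FFT grid (the mirror of index `i` is `N - i mod N`).
- **learnable** — free pixelwise heights or a Zernike expansion (15
  coefficients), initialized from a seeded random draw, bounded to
  `[0, max_height_um]`.

`project_fabrication` quantizes heights to a given number of levels
(idempotent), modeling multi-level lithography.

### 1.3 Sensor

The sensor model applies, in order: quantum efficiency, Poisson shot noise,
a black-level pedestal, additive Gaussian read noise (4.0 e- RMS), full-well
clipping, and uniform quantization at the configured bit depth (10-bit
default).  Conversion gain is `full_well / 2^bits` electrons per DN;
`dn_to_electrons` inverts pedestal and gain using metadata stored on the
frame.  A seed is required: every noisy capture is reproducible.

## 2. Space-variant image formation

The field of view (5.2 x 3.9 mm, 2 um pitch) is large enough that the PSF
varies across it.  `form_image` renders a scene (radiance plus a per-pixel
depth map) through a `PSFBank` — PSFs tabulated on a grid of field positions
and depths — by overlap-add: the scene is partitioned with a window function
(raised-cosine or bilinear, a partition of unity), each tile is convolved
with its local PSF (nearest depth, bilinear in field position), and tiles
are summed.  `space_variant_oracle` performs the literal per-pixel
superposition and is used as the ground-truth reference in tests; with
constant-value padding the two agree to floating-point precision.

Windowed blending preserves a uniform scene only up to second order when
anchor PSFs share their centroid: the first-order error term is the window
gradient times the inter-anchor centroid shift, the second-order term the
window curvature times the kernel width.  This is a property of overlap-add
with spatially varying kernels, not an implementation artifact, and is
covered by an explicit tolerance in the tests.

## 3. Calibration

The calibration protocol images a grid of 3 um pinholes (8 x 10 at 500 um
pitch) at 11 depths (-250 to +250 um, 50 um steps), 10 repeats per depth.
`extract_psf_bank` averages repeats, detects spots at the in-focus plane,
subtracts a local annulus-median background per patch, clips negative
residuals, crops a 65 px patch at the rounded detected center, and
normalizes to unit sum.  Grid geometry (spacing regularity) is validated and
violations are reported with the offending statistic; saturated patches are
flagged.  `interpolate_bank` provides bilinear (clamped) interpolation over
field position and nearest-neighbor selection over depth, renormalizing the
result.

The matched generator (`make_pinhole_stack`) returns the effective spots it
actually rendered — the generating PSF convolved with the pitch-integrated
pinhole disk — so round-trip accuracy can be scored against an exact
reference.  Noiseless extraction reproduces the effective spots to machine
precision; with photon noise the dominant error is the small positive bias
introduced by clipping background noise to nonnegative values, which scales
inversely with pinhole flux.

## 4. Restoration

### 4.1 Wiener baseline

`wiener_deconvolve` applies `H* / (|H|^2 + NSR)` with the kernel rolled so
its center sits at the origin.  It is exact (up to the NSR floor) for
circular blur; for linear convolution, boundary mismatch propagates
globally, which is why quantitative tests blur circularly.

### 4.2 Restoration network

The network is a U-Net: strided-convolution downsampling over `n_scales`
resolutions, residual blocks at each scale, a pyramid pooling module at the
bottleneck (average pooling to fixed bin counts, 1x1 projection, bilinear
upsampling, concatenation), pixel-shuffle upsampling, and a global input
skip `output = input + tail(features)`.  The tail convolution is
zero-initialized, so an untrained network is exactly the identity map — the
training signal starts from the raw capture rather than from random output.
The reference input size is 368 x 480; other sizes are handled by symmetric
padding when `pad_to_fit` is set.  Weights live in plain NumPy arrays and
are archived as `.npz` plus a JSON spec.

### 4.3 Autodiff

Training uses an in-package reverse-mode automatic differentiation layer
(`edofscope.autodiff`) over NumPy arrays: convolution, pooling, pixel
shuffle, centered orthonormal FFTs, `|.|^2`, and clipping with a
straight-through gradient.  A finite-difference `grad_check` utility
validates gradients in the tests.  No external deep-learning framework is
used; the package is NumPy/SciPy only.

## 5. End-to-end design loop

The joint design stage optimizes mask heights and network weights together.
Per step: sample a batch of (scene, depth, channel) triples — channels
balanced by the modality mix, depths uniform over the 21-plane training grid
spanning 500 um — render each scene through the differentiable PSF of the
current mask, apply sensor noise with a straight-through estimator (the
noisy capture participates in the forward pass, the noise is treated as a
constant in the backward pass), restore with the network, and minimize
`L1 + 0.1 * (1 - MS-SSIM)` plus a total-variation penalty on the height map.
Adam updates both parameter groups with separate learning rates; heights are
projected back to `[0, max_height]` after each step.  The differentiable PSF
path agrees with the plain NumPy pipeline to 1e-12.

`finetune_on_calibrated_psfs` repeats the network-only stage using measured
(calibrated) PSFs instead of simulated ones, warning when only a single
field position is available.

## 6. Synthetic targets

- **Bead slides** — subresolution fluorescent disks (3 um default) placed by
  rejection sampling with a minimum separation, pasted with bilinear
  subpixel interpolation (flux and centroid exact), on a flat or tilted
  depth plane.
- **USAF-1951 chart** — three-bar elements for the requested groups, bar
  width `500 * 2^-(g + (e-1)/6)` um, with a registry of per-element
  linewidths, centers, and a sampling-resolvability flag; polarity
  inversion is exact (`positive + negative = 1`).
- **Tissue phantoms** — co-registered dual-channel scenes from one seed: a
  smooth random surface depth map shared by both channels, bright nuclei on
  a dim background in fluorescence, and absorbing vessels (offset deeper
  than the surface) in reflectance.
- **Pinhole stacks** — the calibration acquisition above, with sub-pixel
  grid jitter, returning ground truth (centers, depths, effective spots)
  alongside the noisy frames.

## 7. Metrology

`measure_fwhm` extracts an axial profile through a bead, subtracts the
median background, walks to the local peak, refines the peak with a
log-domain parabola through three samples (exact for a Gaussian apex),
resamples the profile 8x with a cubic spline, and takes the outermost
half-maximum crossings scanning inward from the borders.  Peaks below a
signal-to-noise margin yield `None` with a warning rather than a number.
`resolution_map` tiles the field into ROIs, measures each bead inside its
ROI crop, and aggregates per-depth means, field uniformity, CSV export, and
a depth-of-field estimate: the axial extent over which the per-depth mean
FWHM stays below a stated limit, with linear interpolation at the
crossings.  `score_resolvability` reports the finest USAF element whose
three-bar contrast modulation exceeds a threshold in either orientation.

## 8. Numerical choices

- Centered FFTs with explicit `ifftshift`/`fftshift` pairs keep PSFs
  centered on the window's middle pixel for odd windows.
- Integer oversampling plus box binning makes sensor-pitch PSFs exactly
  energy-conserving.
- All stochastic paths take explicit seeds; one global seed is expanded into
  per-module substreams and logged by the CLI.
- Images are float32 TIFF internally with JSON page metadata; 16-bit export
  is provided for viewer compatibility.
- The log-parabola FWHM refinement bounds the estimator error below 1% for
  Gaussian spots down to sigma ~ 1.3 px.

## 9. Limitations

- The defocus phase is paraxial; at NA 0.1 the high-NA correction is
  negligible but not included.
- Depth within a scene is handled per-pixel by nearest tabulated plane;
  there is no occlusion or volumetric scattering model.
- The sensor model omits fixed-pattern noise, dark current, and pixel
  crosstalk.
- Overlap-add blending preserves flat fields only approximately when the
  PSF centroid drifts across the field (see section 2).
- The calibration patch estimator's nonnegativity clip biases low-flux
  extractions; accuracy statements are tied to the stated flux.
- Training runs at desk scale (reduced pupil grids, small networks, 64 px
  scenes); the architecture scales to the full 368 x 480 input but no
  full-scale trained weights ship with the package.
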
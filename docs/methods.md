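# Methods

## Model

The forward model describes the auxiliary autofocus path of a widefield
microscope: a low-coherence near-infrared source (930 nm superluminescent
diode) shaped by two crossed cylindrical lenses, focused onto the
coverslip by the imaging objective, and re-imaged after back-reflection
onto a dedicated camera.  Each spot axis is treated as an independent
Gaussian beam in its effective (camera-plane) coordinates:

    sigma_axis(z) = w0_axis * sqrt(1 + (dz_axis / zr_axis)^2)

where `z` is the coverslip defocus in sample coordinates (`z > 0` =
objective-coverslip separation larger than at the fast-axis focus),
`dz_fast = z` and `dz_slow = z - focus_offset`.  The expectation image is a
separable elliptical Gaussian whose integrated photon count is independent
of `z` (the reflected power does not change with defocus; only the peak
intensity does), plus a fixed additive background.  The short temporal
coherence of the source justifies modelling spurious reflections as a
static background field rather than defocus-dependent interference
fringes; the default background is a 20-count pedestal plus a dim
off-centre Gaussian blob (amplitude 15, sigma 180 px).

Noise: Poisson photon noise, then additive Gaussian read noise, then
integer quantisation and clipping to the camera range.  Numerically, the
Poisson draw uses the matching normal approximation for pixel expectations
above 32 photons and for the flat far-from-spot background (the metrics
average >10^3 pixels per projection bin, so the approximation is exact in
effect); low-count pixels use exact Poisson draws.  All random draws are
controlled by explicit seeds.

## Shipped default configuration

| parameter | value | note |
|---|---|---|
| `zr_fast`, `zr_slow` | 8, 25 um | axial half-ranges: precision vs range trade-off of the two cylindrical lenses |
| `focus_offset` | +2 um | axial separation of the two best-focus planes; breaks the even symmetry and encodes the sign |
| `peak_photons` | 1e4 | brightest pixel of the in-focus fast axis, per frame |
| `w0_fast`, `w0_slow` | 12, 48 px | camera-plane waists |
| sensor | 1024 x 1536, 16-bit | gain 1 count/photon, read noise 2 counts |
| calibration grid | -80..+80 um, 0.5 um | 321 noiseless frames |
| thresholds | 0.2073 / 0.3343 of peak | see below |
| controller | 0.25 s updates, gain 1, max step 1 um | deadbeat proportional |

The waists and sensor size were chosen once so that (i) the metric curves
keep at least a few frequency bins of width across the calibrated range
(the spectral FWHM of axis `a` at defocus `z` is approximately
`N_a sqrt(ln 2) / (pi sigma_a(z))` for a sensor dimension `N_a`), and
(ii) the total spot photon budget (`2 pi w0_fast w0_slow * peak ~ 3.6e7`
photons/frame) supports nanometre-scale metric repeatability.  They are
frozen; the derived operating ranges and accuracies below follow from
them, not the other way around for any individual run.

## Defocus metrics

Each frame is background-subtracted (real-valued, negatives kept so noise
stays zero-mean) and collapsed into two projections by averaging rows
(fast axis, one value per column) and columns (slow axis).  The metric is
the FWHM, in frequency bins, of the power spectrum of the mean-subtracted
projection.  Mean subtraction voids the DC bin so a residual pedestal
cannot become the half-max reference; the true zero-frequency peak is
instead extrapolated from the first two usable bins assuming locally
Gaussian decay (`ln S(k) ~ -c k^2`), and the half-level crossing found by
outward scan is interpolated linearly in `(k^2, ln S)`.  Both steps are
exact for Gaussian spectra, so the estimator matches the continuous closed
form `N sqrt(ln 2) / (pi sigma)` at any width — including spectra only two
bins wide, where plain linear interpolation against the first-bin value is
biased by tens of percent.  Flat spectra (no crossing) return the maximal
one-sided width; an all-zero profile is an error.  Means rather than sums
make the metric exposure-scale-free; discarding phase makes it invariant
to beam displacement.

## Calibration

A z-stack spanning both operating ranges yields the two metric curves plus
the mean-intensity curve.  Thresholds delimiting the operating regions are
fixed fractions of each curve's peak (0.2073 fast, 0.3343 slow), frozen so
that the default configuration's single-shot region is ±37.5 um and its
two-step region reaches -68/+72 um (the slow region is symmetric about the
+2 um slow focus, not about 0).  A threshold rule based on the metric
statistics of pure-background frames (mean + 5 std) is implemented as an
option but is not the default: the spectral FWHM of a pure-noise frame is
a broadly distributed random variable (median a few bins, tail up to the
full width), so its mean + 5 std exceeds every signal value.  For the same
reason an intensity floor (mean background-subtracted counts, default 1)
backs up the metric thresholds when deciding frame validity.

At build time the table is checked for injectivity: no two grid points
inside the single-shot region may be closer in noise-scaled metric space
than a floor of 2; failure aborts calibration, since inversion would be
ambiguous by construction.  Per-axis metric noise scales are estimated
from replicate frames when the stack contains them, otherwise the frozen
defaults (0.0074 / 0.0028 bins, measured once for the default
configuration) are used.  Curves are stored raw; an optional 3-point
median filter is available for noisy hardware stacks.  Tables persist as
JSON plus a TIFF background image, with a beam/camera config hash that
warns on mismatch at load time.

## Estimation

Single-shot: the measured metric pair is compared against PCHIP (monotone
cubic) interpolations of the two curves on a 0.05 um grid over the
single-shot region, minimising the noise-weighted squared residual; the
minimum is refined parabolically to sub-grid resolution.  PCHIP rather
than piecewise-linear interpolation matters: linear interpolation of the
0.5 um calibration grid leaves ~100 nm systematic artifacts near the curve
peaks, larger than the noise floor.  If a rival local minimum lies more
than 1 um away with a residual within 4 units (two unit-variance terms) of
the best, the estimate is declared ambiguous and the caller should fall
back to the two-step mode.

Two-step: the slow curve is inverted for the frame that is inside the
two-step region (two candidates, one on each side of the slow peak) and
the candidate whose predicted companion metric best matches the second
frame — acquired a known 3 um away — is selected.  A slow-metric change
smaller than 3 noise scales between the frames is ambiguous (the
displacement was too small); both frames below threshold is out-of-range.

The recovery policy (`autofocus`) tries single-shot, falls back to
two-step plus a final single-shot, and uses at most three camera
acquisitions.  The focus-lock controller applies `gain * (z_hat -
setpoint)` every 0.25 s, clamped to 1 um per update and to absolute drive
limits; three consecutive invalid estimates or three consecutive updates
pinned at a drive limit abandon the lock at the last safe position.
Estimates are used raw (no temporal filtering), matching the
direct-correction behaviour of the instrument the model emulates.

## Evaluation protocols and problem sizes

- Repeat-from-offset: 10 repeats per preset offset, ±37 um in 2 um steps
  (single-shot) or ±60 um in 10 um steps (two-step); signed errors
  aggregated per offset.
- True focus: parabola through the three stack points bracketing the
  fast-curve maximum.
- Bead audit: fluorescence z-stacks (±4 um, 100 nm sampling, 128 px
  frames) of 50 sub-resolution beads with Gaussian axial intensity of
  FWHM 0.65 um (the objective's depth of field); per-bead best focus from
  a log-quadratic fit around the brightest plane, beads closer than three
  lateral sigmas dropped.  An optional constant bias (default 50 nm)
  models bead centres sitting above the coverslip.
- Plate: 8 x 12 wells, smooth tilt (1.2 / 2.0 um per well) plus clipped
  roughness (2 um std) keeping neighbour steps below 20 um; per well one
  single-shot correction, then the residual is measured through the bead
  audit, as the hardware evaluation did.
- Stability: closed-loop lock under sinusoidal drift (2 um amplitude,
  10 min period), residual std excluding the first 10 updates.  The
  acceptance script runs 10 simulated minutes (2400 updates); tests use a
  150 s run.

## Measured behaviour and limitations

With the shipped configuration the package measures (seeded runs of
`scripts/acceptance.py`): single-shot mean |error| ~13 nm over ±37 um and
~22 nm within ±5 um; two-step reach ~±71 um; plate spread ~29 nm std of
well means; closed-loop residual std ~70 nm.

The closed-loop figure deserves comment.  Near `z = 0` the fast curve is
at its (parabolic) peak and the slow curve, 2 um from its own peak with a
25 um half-range, has a relative slope of only `~2/zr_slow^2` per um — so
single-frame precision at the lock point is photon-limited at roughly
60-90 nm for this photon budget, and a gain-1 loop reproduces that noise
as residual jitter.  Real instruments of this design report closed-loop
stability in the tens of nanometres; reaching that in this model requires
a substantially larger photon budget per frame (the error falls only as
P^-1/4 at the fast-curve peak) or metric curves sharper than the
Gaussian-beam model produces.  This is a stated limitation of the shipped
simulation scale, not of the estimator, whose mid-range errors are far
below the instrument-class figures.

Other simplifications: no coherent interference fringes (justified by the
source's ~7 um coherence length), no diffraction integrals or high-NA
vectorial effects, no coverslip-thickness aberrations, a perfectly
centred spot, instantaneous and exact z-drive moves, and drift models
(linear / sinusoidal / random walk) that ignore vibration spectra.
Passing tests therefore demonstrate the correctness and internal
consistency of the pipeline under this idealised camera model, not
performance on any particular hardware.
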
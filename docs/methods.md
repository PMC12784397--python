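# Methods

This note records the physical models, numerical choices and known
limitations of the toolkit, in the order the pipeline uses them.

## Scalar Fourier optics

All fields are scalar complex amplitudes on uniform 2-D transverse
grids (µm units throughout; mm accepted at the mask interface).  The
instrument uses circularly polarized light and an NA 1.45 objective,
where vectorial (Richards–Wolf) focusing effects are not negligible;
the scalar model is a deliberate simplification that preserves the
quantities this package measures (thickness curves, effective ranges,
relative comparisons) while keeping the simulator desk-scale.  This is
the package's main known limitation.

**Propagation** uses the angular-spectrum method: the 2-D spectrum is
multiplied by `exp(i·d·√(k²n² − ky² − kz²))`.  Evanescent components
are zeroed rather than exponentially decayed: propagation distances
are always ≫ λ, where their contribution is below double precision.
Fields are zero-padded 2× before the spectral multiply to suppress
periodic wrap-around; the pad is cropped after each call.  Plane
sequences (`synthesize_volume`) reuse one forward FFT and apply the
per-plane kernels to the stored spectrum, which also makes hop
composition exact: chained kernels multiply to the single-hop kernel
at rounding error.

**Lens mapping** is the ideal 2f Fourier transform with the output
plane sampled at `λ_medium·f/(N·d)`, making the DFT unitary, so
Parseval power equality holds to machine precision.  The constant
phase prefactor is dropped.  The objective focal length defaults to
1.8 mm (180 mm tube standard / 100×); it is rig-specific and
configurable.

Coordinates are right-handed with x = propagation, y = sheet width,
z = sheet thickness; `BeamVolume` voxel centres sit at
`origin + index·pitch`, 0-based.

## Lattice and Gaussian sheets

The lattice sheet is generated exactly as the instrument generates it:
a binary photomask of optical density 5.2 (amplitude `10^(−OD/2)`
outside the slits, slit edges area-weighted on the grid) is placed
conjugate to the BFP and Fourier-mapped to the sample.  The default
mask has 3 slits of width 0.08 mm at y = −1.2, 0, +1.2 mm — a minimal
symmetric multi-slit sampling consistent with a square-lattice
"outer slit separation 2.4 mm" geometry; the slit count and length are
not uniquely fixed by the published mask description and are
configurable.

Two mask-plane parameters matter and were fixed once, before any
downstream calibration:

- **Slit length** 2.0 mm (before auto-scaling): sets the z-aperture of
  each beamlet.
- **Illumination envelope** 3.0 mm 1/e² intensity radius: the expanded
  laser spot illuminating the mask apodizes the slit aperture.  The
  ratio envelope/slit-half-length (3.0) is scale-invariant under
  auto-scaling and controls how "flat-topped" the z-spectrum is.  A
  strictly uniform aperture produces a sinc-sheet whose defocused
  profile breaks up raggedly near the end of its range, which is both
  unphysical (laser spots are Gaussian) and numerically hostile to
  per-plane Gaussian fits; the Gaussian envelope reproduces a smooth
  thickness curve while retaining most of the extended range of the
  flat aperture.

**Auto-scaling.** Relay-telescope magnifications between mask and BFP
are not modelled; instead all mask-plane coordinates (slit geometry and
illumination radius together) are multiplied by one factor so that the
*dithered* focal 1/e² thickness matches the requested waist
(1.8 µm default).  Because the lens mapping is an exact Fourier
transform, focal size scales inversely with mask size and the loop
converges in one or two corrections.  Scaling against the dithered
profile matters: dithering mixes the z-profiles of lattice antinodes
and nodes and broadens the effective sheet by ≈10% relative to the
undithered antinode profile.

The Gaussian reference sheet is constructed directly in the focal
plane — Gaussian in z with the requested 1/e² radius, 10th-order
super-Gaussian (flat) collimated envelope in y — as a cylindrical-lens
sheet.  Its measured effective range reproduces the confocal parameter
`2π n w0²/λ` within 1%, which is the module's primary self-check.

**Dithering** time-averages the lattice period along y: a weighted
average over 64 equally spaced phases of a sinusoidal displacement,
rounded to whole voxels (np.roll), which conserves per-plane energy
exactly.  The sine dwell leaves a residual fundamental of amplitude
`|J0(2πA/p)|` for dither amplitude A and lattice period p — 9.2% at
the calibrated default (A = 0.1 V × 35 µm/V = 3.5 µm against the
default period 3.79 µm).  Residuals below 5% occur only near the
Bessel zeros (the smallest amplitude ≥ p is A = 1.377·p); the tests
assert the Bessel-average oracle rather than a universal flatness
claim.

**Steering** applies the bench calibrations (0.64 µm z and 0.35 µm y
per 0.01 V galvo, 2.41 µm focus shift per 10 mA tunable-lens current)
as exact origin translations, so composed steers add without
resampling error.  The Gaussian path responds 2× (per-family
multiplier) because it bypasses the beam-shrinking relay.

**Mirror reflection** rotates the volume in the (x, z) plane by the
specular tilt 2·(45° − wall angle) — 12° downward for the 39° insert —
decomposed into three periodic shears with linear interpolation, which
conserves total intensity to machine precision.  No re-diffraction at
the mirror is modelled; the mirror is flat and large relative to the
beam.

## Thickness curves and effective range

Per-plane thickness is the 1/e² radius of
`I0·exp(−2z²/w²) + offset` fitted by least squares to the z-profile at
the beam's y-centre of mass.  For structured profiles the fit window
is the central lobe; a local minimum only terminates the window if the
profile has also dropped below 50% of the peak, so shallow defocus
ripples riding on the lobe do not truncate it.  The per-plane curve is
then passed through a width-3 median filter (identity on monotone
segments, <0.1% bias on a Gaussian curve) so an isolated mis-fit on a
ratty defocused profile cannot masquerade as the waist.  The waist is
the filtered minimum; the effective range is the contiguous interval
around it with `w(x) ≤ √2·w0`, the crossing located by linear
interpolation between planes.  The √2 criterion is applied to 1/e²
radii, not FWHM, matching the thickness convention used everywhere
else.  A `post_focus` mode measures from the waist forward only, for
situations where fluorescence near the mirror contaminates the
pre-focus profile.

Measured under these conventions the default lattice sheet reaches
1.86× the Gaussian effective range at matched 1.8 µm waists (the
simulation's ideal-optics value; experimental sheets with residual
aberrations sit closer to the 1.5× bound that the acceptance test
asserts).

## Scattering emulation

No quantitative scattering coefficients are derivable from the gel
recipe the experiments used, so the medium is parameterized abstractly
and documented as a qualitative emulation: thin Gaussian-correlated
random phase screens (white noise spectrally filtered to a Gaussian
autocorrelation, then normalized to the requested rms exactly) at
fixed spacing, plus opaque beads from a Poisson process.  The
split-step march keeps the field on the padded grid for the whole
propagation, so a transparent medium reproduces free-space propagation
to rounding error, and every realization is a pure function of the
seed.

The **self-healing score** blocks the beam with an opaque disk and
reports the shadow-window energy of the obstructed beam divided by the
unobstructed beam after 10 µm of recovery.  A ratio, not a Pearson
correlation, is used deliberately: correlation rewards shape
similarity irrespective of attenuation and would rank a deeply
shadowed but still-Gaussian profile above a partially refilled lattice
core.  The default scenario uses a 4 µm radius obstacle (±10% seeded
jitter, small centre jitter) — large enough to block the core of both
sheets including more than one lattice beamlet.  For much smaller
obstacles the y-uniform Gaussian sheet refills its shadow sideways
from unblocked sheet regions and the ordering can invert; that regime
is a property of the idealized infinitely wide Gaussian sheet, not of
the instruments compared here.

## Single-molecule movies

Blinking is per-frame independent Bernoulli (PAINT-like); binding-time
correlations across 200 ms frames are ignored.  Excitation weight is
the normalized sheet intensity interpolated at the emitter's 3-D
position (1 everywhere for epi, which is modelled as uniform).  The
camera chain is Poisson shot noise → Gamma(n, EM gain) electron
multiplication (excess noise factor → 2) → Gaussian read noise →
division by the conversion gain (4.41 photoelectrons per A/D count) →
dark level 500 counts, quantized to 16 bits.  Pixel pitch is the
calibrated 157 × 159 nm.

The Gaussian PSF defocuses as `σ(z) = σ0·√(1+(z/0.5 µm)²)` with
σ0 = 1.05 px; without defocus, epi illumination would produce no
out-of-focus haze and sheet-vs-epi comparisons would be meaningless.
The double-helix PSF is two equal Gaussian lobes separated by 1 µm
whose axis rotates at 90°/µm over ±1 µm (short-range variant;
30°/µm over ±3 µm long-range).  The commercial phase masks' true
rotation parameters are not public; these are configurable
placeholders, and the z round-trip tests validate the model's internal
consistency, not the hardware.

The sheet-vs-epi SBR benchmark mirrors the diffraction-limited
line-scan measurement: a dense always-on emitter plane 4 µm above
focus plays the out-of-focus structure, three bright in-focus probes
are scanned, and the background is read from a 1.6 µm window at the
scan ends.  Per-localization SBR (fitted peak signal over fitted
background) is also available for localization tables.

## Localization pipeline

Detection: à-trous B3-spline wavelet planes; candidates are
8-connected local maxima of the second detail plane above 2× the
standard deviation of the first (noise) plane.  Fitting: weighted
least squares with pixel-integrated models (weights = inverse observed
counts, floored at one photon) — a symmetric Gaussian plus constant
background, or a double Gaussian for the DH-PSF with depth from the
lobe angle wrapped to (−90°, 90°] (resolving the lobe-exchange
degeneracy).  Precision uses the EMCCD expression quoted in the
README; the Monte-Carlo fit ensemble, not the algebra, is the
contract — the suite checks agreement within 25% at the bench medians
(4320 photons, 16.1 background photons/pixel), where the formula sits
≈12% above the empirical scatter.

Drift correction subtracts the per-frame mean fiducial displacement
(each fiducial referenced to its own trajectory mean), linearly
interpolated over gaps and smoothed with a 50-frame moving average.
Filtering removes records failing any rule, with per-rule removal
counts logged; the presets encode the published thresholds (100 nm /
10⁶ photons for the scattering comparison; 42 nm xy / 50 nm z /
3000 photons for the two-target reconstruction).  Axial coordinates
are rescaled by 0.75 after filtering to compensate coverslip/sample
index mismatch.  Region statistics bin the FOV into 5 equal-width
regions along x with region 1 at the mirror edge, reporting counts,
counts normalized by region 1, and mean ± sd of SBR and uncertainty —
no hypothesis tests are added.  FRC renders a seeded random half-split
as 8 nm histograms, ring-averages the spectral correlation, smooths
lightly and thresholds at 1/7; when the curve never drops below
threshold the resolution is reported as the two-pixel bound.

## Problem sizes and defaults

Default grids: 1024² BFP samples over 12 mm, giving 63 nm focal
sampling; focal fields cropped to 256 (y) × 512 (z); volumes 121
planes over ±60 µm.  These sizes resolve the 1.8 µm sheet with ≈28
samples per waist and keep a full lattice/Gaussian comparison around
ten seconds.  Monte-Carlo ensembles use 250 fits; the self-healing
suite runs 10 seeded realizations; the SBR benchmark uses 5-frame
averages, matching how a bench measurement would average a short
stack.

## What synthetic tests do and do not show

The generator emulates ideal scalar optics, a linear EMCCD, isotropic
emitters and stationary samples.  Passing tests demonstrate internal
consistency of the models and correctness of the numerics — e.g. that
the effective-range advantage follows from the mask geometry alone, or
that the precision formula tracks the estimator's actual scatter.
They do not calibrate real scattering strengths, aberrated PSFs,
imager-strand kinetics, or the absolute localization counts of any
specific experiment.
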
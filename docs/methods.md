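# Methods

`granuloscope` reimplements, as a tested library, the image-processing and
quantification chain used to characterise the nanostructure of the mussel
byssus cuticle and of the secretory vesicles that build it: FIB-SEM stack
preprocessing (alignment, destriping, total-variation denoising, local
thresholding, size and median filtering), phase/instance segmentation, and
structural metrics (volume fractions, spherically averaged autocorrelation,
local layer thickness, lamellar orientation), plus STEM-EDS count-map
analysis.  Because no raw volumes are publicly deposited, everything is
validated end-to-end on synthetic phantoms with known ground truth; this
note records the models behind those phantoms, the numerical choices in the
processing chain, and what the validation does and does not show.

## Coordinate and stack conventions

Arrays are `(z, y, x)` with `z` the serial-section (milling) direction.
Voxel sizes are physical nanometres and mandatory; the two acquisition
presets are 17.5 × 12.4 × 12.4 nm (foot tissue) and 10.5 × 4.8 × 4.8 nm
(thread).  The fiber axis of a thread specimen is recorded in stack
metadata as a unit vector; the stack convention places it in the slice
plane (axis `y`).  With the fiber axis in-plane, the ~20 nm lamellae and
their 45° tilt live in the well-resolved 4.8 nm image plane; an
out-of-plane lamellar normal at 10.5 nm slice spacing would be
under-sampled and would also make consecutive slices look like translated
copies of each other, corrupting sequential registration.

## The bicontinuous granule phantom

The lightly-staining (ls) intra-granule phase is modelled as a level set of
an oriented band-pass filtered Gaussian random field — the standard
leveled-wave construction for bicontinuous, microphase-separated
morphologies.  White noise is filtered in the physical frequency domain by
a Gaussian annulus `exp(-((m - f0)^2) / (2 (0.15 f0)^2))` with
`m = sqrt(u^2 + a^2 v^2)`, where `u` is the frequency component along the
layer normal (tilted by the configured angle from the fiber axis, within
the slice plane), `v` the in-layer magnitude, and `a >= 1` the anisotropy.
At `a = 1` the annulus is an isotropic shell and the structure has a
spherically symmetric autocorrelation; growing `a` compresses the in-plane
pass band, extending the layers laterally while preserving their normal
spacing.  The field is thresholded at the quantile that realizes the
requested ls volume fraction inside a spherical granule support, so the
realized fraction is exact to one voxel layer.

**Band-centre calibration.**  For a narrowband Gaussian process thresholded
at fraction φ, the Rice level-crossing rate gives a mean excursion width of
`φ / (f0 exp(-c²/2))` with `c = Φ⁻¹(1-φ)`.  The band centre is therefore
placed at `f0 = φ / (C exp(-c²/2) t)` for target thickness `t`, with a
single empirical constant `C = 0.50` calibrated once against the package's
own local-thickness transform so that the realized modal thickness matches
the request.  The calibration holds within ±15% for `t` in 10–40 nm at both
isotropic 3 nm voxels and the thread acquisition voxels.

**Native-granule preset.**  20 nm layers, tilt 45°, ls fraction 0.40,
anisotropy 5, granule radius 450 nm, thread voxel sizes.  The fraction and
anisotropy are the package's own choices (no numeric values are reported
for them): 0.40 renders lamellae separated by somewhat thicker
heavily-staining gaps, and anisotropy 5 produces the extended flattened
layers the morphology calls for — at lower anisotropy the layers fragment
into short in-plane segments that a 40-pixel size filter then eats.
Rendered contrast is SEM-like (heavier staining brighter): ls dark (0.30),
hs bright (0.72), embedding matrix 0.78, with half-voxel Gaussian
smoothing against staircase aliasing.

## The vesicle phantom

Secretory vesicles are non-overlapping spheres (random sequential
placement; a packing failure reports the achievable count) whose interiors
are partitioned into proto-granule (pg), proto-matrix (pm) and crescent
(cp) by count-based quantile cuts: cp is a peripheral spherical cap along a
random direction, pg the central ball of the remainder, pm the shell
between.  Realized per-vesicle fractions therefore match the request to
within one voxel layer, and the cross-vesicle coefficient of variation is
essentially zero — the phantom emulates a *highly regulated* formation
process, which is the property the volume-fraction analysis is meant to
detect.  The default fractions (0.50, 0.40, 0.10) are plausible
placeholders: only the regularity across vesicles, not the numeric split,
is documented for the real vesicles.  Intensities follow the TEM
osmium-affinity ordering pm > pg > cp (0.80 / 0.50 / 0.20) over a 0.10
background, plus a weak isotropic Gaussian-random-field texture (sd 0.08,
correlation length 80 nm) standing in for intracellular material — real
gland tissue is textured everywhere, and without it slice registration on
vesicle-free regions is ill-posed.

## Imaging degradation

Applied in physical order: per-slice translational jitter (iid Gaussian,
default σ = 2 px, slice 0 pinned), multiplicative vertical stripes
(band-limited column gain, default amplitude 0.10 in 0.05–0.20 cycles/px),
additive Gaussian noise (σ = 0.05), optional Poisson shot noise, optional
contrast inversion.  The stripe pattern evolves along `z` as an AR(1)
process (correlation 0.9 per slice): FIB curtaining is topography-driven
and nearly static between consecutive slices.  Independent per-slice
stripe patterns would create random cross-correlation peaks between
adjacent slices and are avoided.  Zero-amplitude degradation is exactly
the identity, and injected shifts are recorded as ground truth.

## Preprocessing chain

Intensities are first normalised to [0, 1] (the Sauvola `r = 1.7` is the
dynamic-range scale of the local standard deviation, so the intensity scale
must be fixed; the normalisation is logged).

**Alignment.**  Sequential pairwise translation registration, slice 0
fixed, cumulative composition, one final bilinear resample per slice.  Two
estimators: `fourier_shift` (Hann-windowed zero-mean FFT cross-correlation
with Gaussian/quadratic subpixel peak interpolation — the window suppresses
wrap-around edge mismatch that otherwise biases the subpixel peak toward
integers; the correlation is *not* spectrally whitened, because whitening
lets broadband noise dominate weakly textured EM slices) and `ecc`
(Gauss-Newton refinement of the zero-normalized correlation coefficient
from the integer peak).  Constant slices register with zero shift and a
warning; estimates beyond 25% of the frame raise a registration error.
On static scenes both estimators recover iid σ = 2 px jitter with RMS
error < 0.2 px.  Because consecutive sections of a real (or synthetic)
specimen genuinely differ, pairwise registration also accumulates a smooth
pseudo-motion walk of order 1 px per 100 slices; the pipeline therefore
high-passes the cumulative corrections (Gaussian trend, σ = 8 slices,
configurable) — per-slice jitter is white and passes through, while the
spurious smooth warp (and any true slow stage drift, a documented
trade-off) is discarded.

**Destriping.**  Per-slice FFT notch on the near-zero row-frequency line
(vertical stripes are constant along rows): raised-cosine edges in both
frequency directions, DC untouched (slice mean exactly preserved),
off-notch spectrum untouched.  Default notch half-width 2 FFT rows over
the configured column-frequency band.

**TV denoising.**  Chambolle's dual projection in 3D with
forward-difference gradients, `τ = 1/8`, weight 0.07, the published
100,000-iteration budget as `max_iter`, and early stopping when the
relative primal-energy change between checks (every 10 iterations) falls
below `eps = 0.001`.  The monitored energy uses the same forward-difference
TV discretisation as the solver, and is non-increasing across checks; the
output obeys the maximum principle.  An independent implementation
(`skimage.restoration.denoise_tv_chambolle`) is used as a cross-check
oracle in the tests, never in the pipeline.

**Thresholding and cleanup.**  Sauvola `t = m (1 + k (s/r - 1))` with an
11 × 11 window per slice (reflective borders), `k = 0.005`, `r = 1.7`,
computed with float64 integral images and tested voxel-for-voxel against a
naive sliding-window oracle.  Connected components smaller than 40 voxels
(inclusive) are removed, per-slice with 8-connectivity by default
(volumetric 26-connectivity available).  The 3D median filter uses the
ellipsoidal 19-voxel neighbourhood of radius 1.5 voxels, reflective
borders, majority vote on binary input.

Thread preset: align → destripe → TV → invert → Sauvola → size filter →
median.  Tissue preset: align (ECC) → TV, leaving segmentation to seeded
region growing.

## Segmentation

Connected components are labelled in raster first-encounter order
(6/18/26-connectivity), tested against a union-find oracle.  The
magic-wand emulation flood-fills (26-connectivity) the intensity band
`seed mean ± tolerance`, recomputes the mean over the grown region and
regrows to a fixpoint (≤ 5 rounds); it is monotone in the tolerance.
Vesicle interiors are split into three phases by maximal between-class
variance on the interior histogram; adjacent classes whose means sit
closer than 15% of the intensity range are merged first (a vesicle with
only two real phases would otherwise have one mode bisected), and the
surviving classes are named cp < pg < pm by mean intensity, flipped when
provenance marks inverted contrast.

## Metrics

All metrics work in nanometres on anisotropic grids.

*Volume fractions* are exact voxel tallies per instance with per-phase
coefficients of variation across instances.

*Spherically averaged ACF*: the phase indicator is centred by its fraction
over the (possibly irregular) support, windowed to the support, correlated
by zero-padded FFT, normalised per offset by the support's overlap
autocorrelation (removing finite-shape bias), and binned in spherical
shells of physical lag with overlap weighting.  Lag 0 equals φ(1−φ)
exactly; the FFT path matches a direct-summation oracle to 1e-6.
Profile similarity is the RMS distance of lag-0-normalised profiles on a
common grid; the homogeneity score is the mean pairwise distance.

*Local thickness* follows the largest-inscribed-sphere construction:
radii are the Euclidean distance transform (physical sampling), coverage
is resolved by descending-radius ellipsoidal dilation with radius
quantisation of a quarter voxel.  Radii are used raw (distance to the
nearest background voxel centre): a half-voxel boundary correction is
exact only for axis-aligned interfaces and systematically under-reads
tilted layers by up to half a diagonal.  Axis-aligned fixtures therefore
read up to one voxel thick — inside the stated fixture tolerance.  The
headline *modal* thickness is the argmax of the 1 nm histogram after
Gaussian smoothing (σ = 3 nm), which suppresses the discrete diameter
spikes an anisotropic grid imprints; the mean and dispersion are also
reported (the mean runs a few nm above the mode because junctions between
layers admit larger inscribed spheres).

*Lamellar orientation*: the volume-averaged 3D structure tensor is
evaluated spectrally, `J = Σ_k k kᵀ exp(-σ_g² |k|²) |F(k)|²` with physical
angular frequencies and gradient scale σ_g = 6 nm — by Parseval this is the
average outer product of continuous Gaussian-derivative gradients.  The
discrete spatial filter is *not* equivalent here: at 10.5 nm slices a
sub-voxel-σ derivative kernel attenuates near-Nyquist gradients and biases
the normal by >10° at intermediate tilts, while the spectral form recovers
tilts of 0–90° within 0.3° on clean phantoms.  The mean layer normal is
the leading eigenvector, the reported angle is `arccos |n·a|` against the
declared fiber axis, and the anisotropy index `(λ1−λ3)/Σλ` flags
near-isotropic inputs (< 0.05) as unreliable.  The estimate is invariant
to contrast inversion.

## STEM-EDS analysis

Count maps are simulated as independent Poisson draws at per-phase,
per-element rates plus a flat continuum; the native-cuticle preset encodes
equal nitrogen in both phases, a 2:1 pm:pg sulfur rate ratio, Fe only in
the matrix and V only in the granule.  Relative weight fractions are
background-subtracted count fractions with no k-factor or absorption
correction (explicitly uncalibrated); zero-sum pixels are undefined, not
zero-filled.  Phase statistics use the normal approximation to the Poisson
mean; pairwise phase ratios are computed on background-subtracted means
(the continuum enters both phases and would bias the ratio toward 1) with
delta-method CIs, and a phase is flagged background-consistent when its
raw mean is within two standard errors of the declared continuum.
Transects sample along a segment with bilinear interpolation, averaging
over a configurable width (default 5 px) perpendicular to the line.
Interface sharpness is the 25–75% crossing distance of the monotone
envelope of the distance-binned profile across a phase boundary — no
parametric fit; for a Gaussian-blurred step this is 1.349 σ.

## Problem sizes and determinism

Every generator and pipeline takes an explicit seed; identical
configurations are bit-identical.  The end-to-end reference computation
(`scripts/acceptance.py`) uses a 192 × 256 × 256 voxel phantom (the
thread-acquisition field of view at full in-plane resolution) and runs in
about three minutes on one CPU, dominated by the TV solver; the test suite
uses 48–128-voxel-scale phantoms for module-level checks.  Phantom
structure, degradation and downstream analysis derive their seeds from the
single command-line seed via `SeedSequence`.

## What passing tests show — and what they do not

The phantoms validate that the chain recovers *known* structure through
realistic degradations: they emulate osmium-stain contrast ordering,
bicontinuous lamellar geometry, FIB curtaining, jitter and counting noise.
They do not model SEM image formation (beam-sample interaction, charging,
depth effects), membrane rendering of vesicles, partial-volume mixing
beyond half-voxel smoothing, or absolute EDS quantification; thickness and
orientation recovery on phantoms bounds algorithmic, not instrumental,
error.  Registration accuracy against ground truth is only measurable on
static scenes; on evolving specimens the "true" per-slice shift is not
identifiable from image data, and the pipeline's drift high-pass encodes
the assumption that slow apparent motion is artefactual.
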
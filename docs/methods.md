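# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `tomopipe`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Geometry and conventions

Parallel-beam geometry only (synchrotron case). Angles are in degrees,
counter-clockwise, θ = 0 along the +x axis of the phantom grid; a projection
at angle θ assigns to detector column *t* the line integral along the ray
`t = c + x cos θ + y sin θ`, where `c` is the fractional detector column of
the rotation axis and (x, y) are object coordinates relative to the axis
with +y up. A slice of width N places the axis at pixel `(N−1)/2`.
Reconstructed values are attenuation per pixel; divide by the pixel size to
obtain 1/length (this is documented, never applied silently).

## Synthetic data generator

The generator is the package's ground-truth instrument; its defaults define
the study conditions used by the tests and the acceptance script.

* **Projector.** Rotate-and-sum with first-order (linear) interpolation on a
  parity-matched canvas, so the phantom center sits exactly on the rotation
  axis (a parity mismatch would smuggle in a half-pixel shift). Tolerances
  in tests budget for the interpolation error of this projector; an
  independent implementation (scikit-image `radon`) is used as a
  cross-check in the suite, agreeing to a few percent RMS with identical
  orientation, scale and angle convention.
* **Detector model.** `frame = dark + g_c · flat · N₀ · e^{−p}`, Poisson on
  the detected counts, Gaussian read noise (σ = 2 counts) on the dark
  level, rounded to unsigned integers. `N₀ = 10⁴` photons per pixel gives a
  flat-field SNR of 100, typical of a well-exposed synchrotron scan.
  Line integrals of a phantom are rescaled so the densest ray attenuates by
  2.5 (transmission e^{−2.5} ≈ 8%); O(1)-valued phantoms would otherwise be
  opaque under this photon budget. The factor is recorded in the ground
  truth.
* **Zingers** (direct X-ray hits) multiply the affected raw pixel by 10
  (hence always ≥ 5× the local level), pre-normalization, at a configurable
  per-pixel rate; the exact mask is recorded.
* **Ring artifacts.** Per-column gains `g_c` are applied to the projections
  but, by default, *not* to the flats: they model response drift *after*
  flat acquisition, which is the minimal mechanism by which flat-field
  correction fails and vertical sinogram stripes appear. A static gain
  applied to both (option `gains_in_flats=True`) cancels exactly in
  normalization and produces no rings — a useful negative control.
* **Extended FOV.** 360° scans with the axis near the right detector edge;
  the detector covers half the object plus an overlap band `o = 2(W − c)`.
* **Propagation contrast.** Two linear near-field models, both spectral and
  defined on the same grid as the retrievals so round trips are exact:
  single-material TIE (`𝓕[I] = 𝓕[e^{−μT}] · (1 + (δz/μ)|k|²)`, the exact
  inverse of Paganin) and pure-phase TIE
  (`I = 1 + (λz/2π)∇²φ`, inverted by MBA/Moosmann). Retrieved phase is
  defined positive for thicker phase-advancing material.
* **Phase stepping.** `I_s = a₀(1 + V cos(2πs/S + φ))`, S equidistant steps
  over one grating period, optional Poisson noise.

What the generator does **not** emulate: detector PSF/scintillator blur,
motion/jitter, beam-energy drift, scattering, cone-beam effects, nonlinear
propagation. Passing tests therefore demonstrate correctness of the
processing chain under its stated forward models, not robustness to every
real-beamline pathology.

## Calibration

Center of rotation: mirror the 180° projection, scan integer shifts
(default ±50 px) for maximum normalized cross-correlation, refine with a
parabolic fit through the peak and its neighbors; `c = (N−1)/2 + s/2`.
Registration is ill-posed on mirror-symmetric objects, so calibration tests
use an asymmetric phantom. Axis tilt: centers estimated on 5 row bands at
10/30/50/70/90% detector height, least-squares line `c(row) = a + b·row`,
`tilt = atan b`; compensation rotates each frame by −tilt (linear
interpolation, edges extended). Reconstruction consumes the per-row center
from this fit directly, avoiding an extra resampling. Overlap: the widest
trailing/leading column band of the 0°/mirrored-180° pair whose correlation
is maximal (ties resolved toward the widest near-perfect band, again for
symmetry robustness); the final estimate is the median over 5 evenly spaced
opposing pairs. Stitching blends the shared `o` columns with a linear ramp
(weights sum to 1, constants preserved) giving width `2W − o`.

## Artifact filters

Zingers are detected per sinogram as `value > threshold × median` with the
median taken along the angle axis (window 5), and repaired by linear
interpolation along angle from the nearest clean samples; clean pixels are
returned bit-identical and the filter is idempotent on isolated spikes.
Defaults: threshold 1.2, kernel 5.

Both ring filters act **after** the −ln for absorption data: a gain error is
multiplicative in transmission, hence an additive per-column offset in the
log sinogram, which is exactly what subtractive profile filters remove.
(On phase or DPC sinograms they act directly.) The unsharp variant
subtracts the high-frequency residual `m − G_σ(m)` of the angular-mean
column profile from every row; the wavelet-FFT variant damps, per
decomposition level, the angular-frequency spectrum of the vertical-detail
band by `1 − e^{−k²/2σ²}` (σ = 2 frequency bins by default), which kills
the k = 0 component where constant-in-angle stripes condense. Band
orientation is pinned by a synthetic stripe test, not by wavelet band
naming. The default wavelet is db25; on narrow sinograms (≲ 500 columns)
its 50-tap filters limit the usable depth, and db8 with 3–4 levels is the
better choice (used in the tests) because dense stripe spectra need several
levels of coverage.

A structural caveat measured by the suite: any filter keyed to the angular
mean cannot distinguish a detector-gain stripe from the object's own
angular-mean structure. On smooth objects the filters remove > 90% of the
ring power introduced by ±2% gain drift while moving the reconstruction by
< 0.01 NRMSE; on objects with sharp edges (Shepp–Logan) the same filters
convert profile discontinuities into new rings at tangent radii. The ring
benchmarks therefore use a band-limited phantom; on real edgy samples these
filters trade artifact suppression against edge-radius fidelity.

## Phase retrieval

All retrievals pad symmetrically to the next power of 2 per dimension (a
size already a power of 2 is kept), operate in Fourier space with
frequencies in cycles/length (`|k|² = (2π)²(u² + v²)`), and crop back.
Intensities are floored at 10⁻⁶ before logarithms.

* Paganin: `T = −μ⁻¹ ln 𝓕⁻¹[𝓕[I/I₀]/(1 + (δz/μ)|k|²)]`, `μ = 4πβ/λ`.
  At z = 0 it reduces exactly to `−ln(I)/μ`. Jointly scaling (δ, β) by c
  leaves the filter unchanged and divides T by c.
* Deconvolution: spectrum × `G/(G² + reg)` for a Gaussian G of width σ
  pixels, renormalized to unit DC gain so the image mean is preserved.
* MBA: `φ = −(2π/λz) 𝓕⁻¹[𝓕[I−1]/(|k|² + α(2π/p)²)]` with pixel size p;
  α is dimensionless (default 10⁻³) and sets a low-frequency knee — objects
  whose spectrum sits mostly above that knee are recovered faithfully.
* Moosmann (linear order only): the α → 0 limit of the same kernel with the
  undefined DC term zeroed; the mean phase is not recoverable from
  propagation contrast and all comparisons are modulo that constant.
  Higher-order nonlinear corrections are out of scope.

## Grating interferometry

The stepping-axis DFT gives `a₀ = X₀/S`, `a₁ = 2|X₁|/S`, `φ = arg X₁`
(exact for noiseless single-harmonic curves at any S ≥ 3; the sign
convention is fixed by the worked cosine example in the tests). Contrasts:
absorption `a₀ˢ/a₀ʳ`, DPC `wrap(φˢ − φʳ) ∈ (−π, π]`, dark field `Vˢ/Vʳ`;
pixels with invalid reference (zero intensity or visibility) are masked.
One reference stepping set serves all angles by default. DPC projections
are destriped with the wavelet-FFT filter applied to the transpose.
Reconstruction applies −ln and the ramp filter to absorption and dark-field
sinograms, and the Hilbert kernel `−i·sgn(ν)` (no ramp, no ln) to DPC
sinograms, whose derivative character supplies the ramp magnitude.

## Reconstruction

Filters are defined on the normalized frequency ν = f/f_Nyquist ∈ [−1, 1]:
ramp `|ν|` times a window (Ram-Lak box, Hanning cosine, Parzen cubic
B-spline), zero beyond the cutoff. With back-projection scale `π/(2·n_ang)`
this reproduces the continuous inverse-Radon normalization, shared by both
engines so filters and cutoffs compare across them.

The FBP oracle zero-pads each projection to a power of 2 at least twice the
width (so the ramp's spatial tails do not wrap), filters, sinc-interpolates
4× by spectral zero-padding, and back-projects with linear interpolation on
the fine grid — keeping the oracle's interpolation error well below the
discretization error it is meant to measure.

Gridrec packs two real sinograms as one complex sinogram, filters each
padded projection spectrum (grid size = next power of 2 ≥ 2N, i.e. 2×
oversampling), applies the phase ramp `e^{2πifc}` moving the axis to the
origin, and spreads the samples along the Fourier-slice line with a
separable Kaiser–Bessel window (support 5 cells, β from the standard
oversampling formula ≈ 11.44); a single 2D inverse FFT plus division by the
window's analytic spatial transform yields both slices. Two details keep a
real sinogram's slice real to machine precision (and hence the complex
pair-packing exact): the unpaired −Nyquist bin of the radial filter and the
−Nyquist row/column of the grid are zeroed, restoring exact Hermitian
symmetry. A half-cell phase ramp aligns the output grid with the oracle's
pixel centers for even N. Global mass (slice integral vs mean ray sum) is
biased low by a few percent at the default grid — the truncated ramp tails
— and converges to the ray-sum mass as the grid is refined (the suite
checks ≤ 2% at 4× padding); pointwise accuracy is unaffected.

ROI cropping is applied after reconstruction (so an ROI equals the crop of
the full slice, bit-exact), rotated output uses linear interpolation.

## Orchestration, partitioning, streaming

The reader/compute partition plan is deterministic: readers = the multiple
of n_nodes closest to `n_total/(ratio+1)` with ratio default 7 (the
advantageous 1:6–1:8 band), floored at one reader per node, assigned
round-robin so every node carries the same count. Exact ties round toward
more readers on multi-node systems (spreading I/O) and fewer on a single
node (reading cores are expensive there). The plan is pure bookkeeping:
sinogram content is independent of it, and the execution backends (serial,
process pool) are bit-identical by construction.

The frame stream is a message contract (header with shape/counts/angles,
one raw little-endian frame per message with dtype/shape descriptor, end
marker); the shipped transport is in-process with full-backlog fan-out, so
any number of subscribers, in any delivery order, reconstruct scans
bit-identical to the file path. Preview builds sinograms only for requested
rows; its slices equal the matching full-run slices because each row is
processed independently.

Runs are pure functions of (input scan, config, seed); the config is a
YAML-serializable dataclass and every stage logs its parameters, shapes and
duration (durations are reported, never asserted — they are
hardware-dependent).

## Problem sizes

The test suite and acceptance script run end-to-end at 256×256 with 400
angles, engine-equivalence at 64/128/256, ring/calibration studies at
128–256, chosen as the package's own validation sizes: large enough that
discretization effects (interpolation, gridding aliasing, profile
smoothing) are representative, small enough that the whole validation
completes in well under a minute each.

## Known limitations

- Parallel beam only; no cone/fan geometry, no iterative reconstruction,
  no GPU path.
- Linear-order propagation models only; strong-phase or multi-distance
  regimes are out of scope.
- Ring filters assume stripe-vs-object separability (see above).
- The stream transport ships only in-process; a network PUB/SUB
  implementation would plug into the same message contract.
- No multi-node scheduling; the partition plan is the testable content of
  the parallel design.
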
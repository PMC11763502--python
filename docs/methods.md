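# Methods

## The problem

Fluorescence lifetime imaging (FLIM) maps, per pixel, the exponential
decay constant of a fluorophore's excited state. A reliable lifetime fit
needs hundreds of photons per pixel, so a 512×512 acquisition takes
minutes while a 256×256 or 128×128 scan of the same field takes a small
fraction of that — at the cost of pixel count. `flimupscale` converts a
fast low-pixel acquisition (an intensity image plus a fitted lifetime
matrix in picoseconds) into a high-pixel image by interpolation, treating
the two channels separately and keeping track of which pixels actually
carry a fitted lifetime.

Two properties distinguish this from generic image upscaling:

1. **Masked data.** Outside bright structures the photon count is too low
   for a decay fit; those pixels have *no* lifetime, not a zero lifetime.
   A plain interpolator that touches them invents lifetimes at structure
   boundaries. Every interpolation stage here drops masked pixels from
   its stencil and renormalizes the surviving weights.
2. **Edges carry the biology.** Mitochondria, microspheres and nuclear
   pores are small and sharp; smoothing across their boundaries destroys
   exactly the detail the higher pixel count was meant to recover. The
   edge-preserving interpolator chooses, per pixel, the local direction
   of least variation and interpolates along it.

## Bicubic baseline

The baseline is separable cubic convolution: the value at fractional
position (i+s, j+t) is A·B·C with B the 4×4 block of known neighbors and
A, C the kernel weights at distances (1+s, s, 1−s, 2−s). The kernel is
the standard one-parameter family

    R(x) = (a+2)x³ − (a+3)x² + 1      0 ≤ x < 1
         = a x³ − 5a x² + 8a x − 4a   1 ≤ x < 2
         = 0                          x ≥ 2

with a = −1 by default (R(x) = 1 − 2x² + x³ on [0,1),
4 − 8x + 5x² − x³ on [1,2)). The weights form a partition of unity
(constants are reproduced exactly); a = −1 also reproduces affine images
exactly. Output registration: source pixel (i, j) maps to output
(f·i, f·j) 0-based for factor f, identical to the edge-preserving
method's step 1, so the two methods are comparable pixel-for-pixel and
source values reappear bit-exactly. Borders are edge-replicated —
this avoids ringing and keeps mask bookkeeping trivial.

The masked variant drops invalid pixels from the 16-point stencil,
renormalizes the surviving signed weights to 1, and refuses the output
(marks it invalid) when the surviving *absolute* weight mass falls below
`min_support` (default 0.5, versus 2.25 for the full stencil at the
half-pixel position) or the signed sum degenerates (|Σw| ≤ 1e−9). The
default says: do not fabricate a lifetime where most of the neighborhood
is missing.

## Edge-preserving interpolation (2×)

**Step 1** copies source (i, j) to output (2i, 2j). No arithmetic — the
acquired data survive bit-exactly.

**Step 2** fills the centers (2i+1, 2j+1) from the surrounding 4×4
source block. The block is serialized along each of four candidate
directions — horizontal, vertical, main diagonal (top-left→bottom-right),
anti-diagonal — in boustrophedon ("snake") order: lines parallel to the
direction are concatenated in offset order, each line alternating
traversal sense so consecutive sequence elements stay spatially
adjacent. The variation along a direction is the summed absolute
difference between consecutive *valid* elements of that sequence
(invalid elements are dropped from the chain; see below). The center is
then interpolated **along the direction of minimum variation** — the
edge direction — with:

* main/anti diagonal: the 4 diagonal pixels, weights (−1/16, 9/16,
  9/16, −1/16);
* horizontal (vertical): the two middle rows (columns), each carrying
  the same 4-point weights, averaged — an 8-pixel stencil summing to 1;
* isotropic fallback: the full 16-pixel separable cubic stencil at the
  half-pixel position with a = −0.5, whose 1-D half-pixel weights are
  exactly (−1/16, 9/16, 9/16, −1/16), consistent with the directional
  stencils. (The a = −1 member is kept as the *baseline* interpolator's
  default; the two coexist deliberately.)

The fallback triggers when the two best variations tie within a relative
tolerance of 1e−9, or when any direction's usable pair count falls below
half the maximum (too few valid pixels to compare directions fairly).

*Why minimum variation:* interpolating along the direction in which the
data change least means averaging values that belong to the same
structure; interpolating across it would mix values from both sides of
an edge. Selecting the 45° diagonal pixels for a pixel on a 45° edge —
the canonical example — is precisely the minimum-variation choice. An
alternative reading that interpolates along the maximum-variation
("gradient") direction would blur every edge and contradict the method's
purpose; both the selected (minimum) direction and the measured
variations are exposed in `DirectionStats`-style outputs so either
convention can be inspected.

*Variation under masking:* a pair-wise rule that simply skips any
adjacent pair touching an invalid pixel degenerates in step 3, where the
filled lattice is a checkerboard and *every* 4-adjacent horizontal or
vertical pair contains an unfilled pixel. We therefore drop invalid
elements from the snake chain and difference consecutive survivors; the
count of usable differences is what the low-support fallback inspects.
Masked values still can never influence the result.

*Diagonal serialization convention:* diagonal lines are ordered by their
offset (top-right to bottom-left for the main-diagonal direction),
the first line traversed in increasing-row sense, alternating. Any such
convention yields equivalent direction selection on the windows that
matter (the four variations are compared, not used absolutely); the
choice is frozen and the test suite pins it with an independent
brute-force serialization.

**Step 3** fills the remaining (even, odd) and (odd, even) positions.
A 5×5 window of the partially interpolated image, centered on the
target, decides horizontal versus vertical by the same snake-variation
rule (unfilled pixels treated as invalid). The value then comes from the
4 already-filled neighbors at offsets −3, −1, +1, +3 along the chosen
axis — these all exist on the filled lattices — with the same
(−1/16, 9/16, 9/16, −1/16) weights. The 5×5 window is used only for
direction selection; a 5×5 window cannot contain four collinear filled
neighbors at the stencil's spacing. On a tie (or low support) the two
axial estimates are averaged; if only one survives masking it is used;
if neither does, the pixel is invalid.

**Masking** works identically in every stencil: invalid pixels are
dropped, signed weights renormalized to 1, output refused below
`min_support` of surviving absolute mass. Border stencils clamp to the
nearest lattice sample (edge replication on the source lattice).

**Factor 4** applies the 2× pipeline twice. The second pass consumes the
first pass's values and validity mask. No direct 4× stencil is defined.

**Direction contrast.** Each step-2/step-3 pixel records
(max−min)/(max+min+ε) over its candidate variations — 0 where the window
is isotropic, →1 where one direction utterly dominates. Step-1 pixels
inherit the mean of their filled 4-neighbors' contrasts. This grid is
the gradient map consumed by the wavelet enhancement.

## Wavelet enhancement of the intensity image

One-level 2-D DWT (default `db2`, symmetric extension) splits the
interpolated intensity image into approximation + horizontal/vertical/
diagonal detail bands. Each detail coefficient is multiplied by
(1 + α·ḡ), where ḡ is the mean direction contrast over the coefficient's
dyadic footprint and α ≥ 0 (default 0.5) the gain strength — edges are
amplified in proportion to how edge-like the interpolator found them.
The three detail bands are then soft-thresholded at the universal
(VisuShrink) threshold σ√(2 ln N) with σ = MAD(diagonal band)/0.6745,
and the transform inverted; negative reconstructed photon counts are
clipped to 0. With α = 0 and denoising off the pipeline is the identity
to reconstruction precision (1e−8). The gain law, wavelet family and
depth are package design choices isolated behind `EnhanceParams`;
orientation-selective gain (matching each band to its edge orientation)
is deliberately not implemented and would be the natural next
refinement. Lifetimes are never filtered.

## Pseudo-color rendering

Lifetime → hue via an explicit LUT (default 256 bins over
700–1400 ps, hue 0°→240°, i.e. red = short to blue = long, full
saturation; `invert` flips it to match vendor conventions); intensity →
brightness, normalized by the 99.5th percentile (robust to hot pixels)
and clamped to [0, 1]; masked pixels render black. Out-of-range
lifetimes clamp to the end bins; bins are nearest (no LUT
interpolation). Rendering is byte-deterministic.

## Synthetic phantoms

The generator stands in for real acquisitions and produces (LR, GT)
pairs on demand:

* **Scenes.** `microspheres`: non-overlapping disks of 4.0 µm diameter
  (80 px at the default 0.05 µm pixel); `filaments`: smoothly turning
  random strokes dilated to ~3 px width (mitochondria-like);
  `puncta`: isolated 2–3 px spots (nuclear-pore-like).
* **Lifetimes.** One uniform draw in 700–1400 ps per structure, plus
  30 ps per-pixel Gaussian jitter (the pixel-to-pixel scatter a single
  measurement shows); background 1800 ps, well above the structure
  range.
* **Intensity.** Ideal brightness (default 200 expected photons peak,
  2 background) blurred by an isotropic Gaussian PSF (σ = 1.2 px, a
  generic confocal stand-in), then Poisson photon noise.
* **Mask.** Valid lifetime exactly where intensity ≥ photon threshold
  (default 20), mimicking a fitter that refuses dim pixels.
* **Determinism.** Four RNG streams (geometry, structure lifetimes,
  photon noise, lifetime jitter) spawned from one seed, so changing the
  photon budget never moves the structures.
* **Degradation.** `decimate` (default) keeps one sample per block —
  a coarser scan of the same field, the protocol the method targets;
  `block_average` is the photon-conserving alternative (intensity =
  block sum, lifetime = intensity-weighted mean of valid pixels).

What the phantoms do **not** emulate: decay-curve fitting noise
structure (lifetime jitter is Gaussian, not fit-derived), detector
afterpulsing, scanner distortion, optical aberration beyond a Gaussian
PSF, or multi-component decays. Passing tests therefore demonstrate the
interpolation/masking/enhancement machinery, not end-to-end instrument
performance.

## Evaluation

All lifetime statistics are restricted to pixels valid in *both*
compared frames. Reported per candidate: intensity PSNR (dB, peak from
the ground truth; "inf" sentinel when identical), lifetime MAE (ps),
normalized L1 distance between lifetime histograms (10 ps bins over
700–1400 ps by default, out-of-range clamped into end bins, densities
normalized to 1), optional edge sharpness (maximum absolute adjacent
difference along a stated line profile, bilinear sampling; a
masked-aware sampler renormalizes weights so invalid lifetimes never
mix in), and valid-pixel counts. These distances are this package's
quantifications of what is usually judged visually — histograms and
profiles — and are named as such in the report.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full protocol on a
512×512 microsphere ground truth decimated to 256×256 (factor 2) and
128×128 (factor 4) — the native sizes of the acquisition protocol the
package targets — which completes in seconds on one CPU; unit tests use
8–32 px grids. Fixed numerical constants: direction tie tolerance 1e−9
(relative), contrast ε 1e−12, degenerate-stencil guard |Σw| > 1e−9,
lifetime text precision 6 significant digits, `min_support` 0.5.

## Known limitations

* The 4× path is two 2× passes; errors of the first pass propagate.
* Isotropic fallback averaging in step 3 can leave faint checkerboard
  texture in perfectly flat noisy regions (it averages two 4-point
  estimates rather than using a full 2-D stencil).
* The wavelet gain is orientation-agnostic.
* Negative stencil lobes can overshoot the local value range by up to
  1/8 of its width; lifetimes are not clipped to the input range (only
  positivity is enforced at frame assembly).
* The ASCII lifetime reader's header skipping is a compatibility guess;
  export dialects vary across vendor software versions.
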
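# Methods

`semmorph` quantifies neuronal ultrastructure in scanning-electron-microscopy
(SEM) fields: axon-like tubes, round cell bodies, and the concentric
lamellae of compact myelin. This note documents the models and numerical
choices behind each stage, what the synthetic benchmark does and does not
emulate, and the known limitations.

## Calibration and containers

All images are `CalibratedImage` objects: a float field in [0, 1] plus an
explicit pixel size in nm/pixel. There is deliberately no default
calibration — every output quantity (µm² areas, nm diameters and periods)
is physical, and a silently assumed pixel size would corrupt all of them.
Quantization to 8/16-bit integers happens only at file write.

## Synthetic scenes and ground truth

The generator rasterizes analytic primitives by pixel-center sampling on a
0-based (row, col) grid: a pixel belongs to a primitive iff its center lies
inside the analytic boundary. Primitives:

- **tube** — polyline centerline, lumen diameter, wall thickness; the wall
  renders bright, the lumen near background, emulating hollow axon
  cross-profiles. Defaults in tests follow white-matter axon scales
  (lumen ~0.4–1 µm, walls tens of nm).
- **body** — disc with optional membrane rim and band-limited filament
  texture, at the 1.4–16 µm scale of neuronal somata.
- **lamellar_ring** — `n_layers` bright bands of width period/2 spaced by
  the period (~10–12 nm for compact myelin), alternating full and
  `amplitude_ratio`-attenuated amplitudes to emulate major dense vs
  intraperiod lines.
- **filament_texture** — a textured disc for cytoplasmic filament fields.

Noise chain, applied in fixed order blur → Poisson → Gaussian → background
gradient, approximates beam point spread, counting statistics, detector
read noise, and charging gradients. With all parameters zero the render
equals the noiseless rasterization exactly, so geometric oracles
(pixel-count areas, distance-transform widths) are exact up to
rasterization (±1 boundary pixel).

Determinism: one PRNG seeded per call drives the noise chain; textured
primitives carry their own `texture_seed`, so the *noiseless* render is
independent of the scene seed. Per-primitive texture streams derive from
`texture_seed + primitive index`; insertion-order independence of textures
is therefore **not** guaranteed and not claimed.

What the benchmark does not emulate: secondary-electron physics, realistic
charging artifacts, topographic shading, structured (non-white) detector
noise, and 3-D sectioning geometry. Passing tests demonstrate that the
measurement chain is correct on images whose degradations are of the
modeled kinds and magnitudes — not that it is robust to every real
instrument artifact.

## Wavelet denoising

Daubechies-4, 3 levels, soft shrinkage at the universal (VisuShrink)
threshold σ·√(2 ln N), with σ estimated as MAD/0.6745 of the finest
diagonal detail band. These are the standard defaults for edge-preserving
shrinkage; all are config-overridable. Symmetric boundary extension avoids
ringing at crop edges; non-dyadic sizes rely on the transform's internal
padding and are cropped back after reconstruction. With a fixed zero
threshold the stage is a pure round trip (≤1e−8 max deviation), which the
tests pin down. Translation-invariant (cycle-spinning) denoising is out of
scope.

## ROI extraction

Background filtering uses the morphological two-phase (Chan–Vese,
piecewise-constant) active contour with Otsu-threshold initialization,
default smoothing 1 and 200 iterations. The returned foreground is the
phase agreeing best (Dice) with the initialization. A zero-contrast image
returns the initialization unchanged with a `degenerate_contrast` flag
rather than failing.

Numerical note: the morphological smoothing operator rounds single-pixel
corners; exactness tests on noise-free two-valued images therefore run
with smoothing 0, where the update is driven purely by the two-phase
energy and reproduces the true partition exactly. Smoothing 1 is the
default for noisy fields, trading boundary fidelity at the single-pixel
scale for robustness.

## Fuzzy c-means segmentation

The unsupervised partitioner is classical FCM: minimize
Σᵢₖ uᵢₖᵐ‖xᵢ − cₖ‖² subject to Σₖ uᵢₖ = 1, alternating the closed-form
membership and center updates. Defaults: m = 2, tol 1e−5 on the largest
center displacement, intensity features (optionally intensity plus a
level-1 wavelet detail-energy texture channel). Initialization is
deterministic — centers at the (k+½)/K quantiles of the ROI feature
distribution — so runs are reproducible without seeds. The recorded
objective sequence evaluates J after each membership half-step; since both
half-steps minimize J, the sequence is provably non-increasing. Classes
are reported sorted by ascending center intensity; argmax ties resolve to
the lower class index. Pixels coinciding with a center get a crisp
(one-hot, or uniform over coincident centers) membership.

### Progressive refinement

Pixels whose top membership falls below the ambiguity threshold (default
0.8) sit between class centers, where intensity alone cannot decide. Under
*fixed* centers the FCM membership formula is already per-pixel optimal,
so any purely feature-based refit either changes nothing or moves centers
into the boundary zone — which demonstrably worsens assignments on
mixture benchmarks. Refinement therefore brings in the one source of
information FCM ignores: spatial context. Each round recomputes the
ambiguous pixels' memberships against the fixed global centers using
neighbourhood-averaged features (3×3 window, growing by one ring per
round), so isolated noisy pixels inherit the class of their surroundings.
Unambiguous labelings are exact fixed points, and `max_rounds=0` is the
identity.

## Morphometry

- **Labeling**: 8-connected components of the chosen foreground classes,
  intersected with the active-contour ROI; components under `min_area`
  (default 16 px) are dropped and counted. Boundary pixels are those with
  a 4-neighbour outside the object.
- **Cell bodies**: area = pixel count × pixel area; diameter = mean Feret
  width over 180 directions at 1° steps (boundary pixel centers plus one
  pixel of extent); equivalent-circle diameter 2·√(area/π). Diameter and
  area are measured independently — reported tables list both, and they
  are not circular equivalents of one another.
- **Tubes**: diameter = 2 × mean distance-transform value along the
  medial-axis skeleton, excluding skeleton points within one mean width of
  the tips so rounded ends do not bias the estimate. A component counts as
  a tube when its skeleton is at least twice as long as its mean width;
  otherwise it is measured as a generic object. Discretization keeps the
  estimate within ±1 pixel of the rasterized width.
- **Wall thickness**: full width at half maximum of the
  background-subtracted intensity ridge along a crossing segment, sampled
  at 0.25-pixel steps with bilinear interpolation; the baseline is linear
  between the profile-end means, and the ridge peak must exceed a noise
  floor (4 × a robust first-difference noise estimate, min 1e−3) or a
  `no-wall-detected` result is returned. Half-maximum crossings are
  located by linear interpolation.
- **Size classes**: the exact 1-D least-squares k-partition of the
  diameters, solved by dynamic programming over the sorted values (O(kn²),
  no random initialization), labeled 1A, 1B, … by descending mean. On the
  bundled 19-cell reference table the exact partition reproduces the
  published 2/4/13 membership because the between-class gaps are large.
- **Statistics**: mean; SD with n−1 denominator; SEM = SD/√n; SD and SEM
  are absent (not zero) for n = 1. Report rounding is half-away-from-zero
  at each table's printed precision; internal values keep full precision.

The bundled reference tables (spinal-cord cell bodies; brain and
spinal-cord axon diameters) are stored with comma decimal separators and
parsed by a comma-decimal-aware reader. The spinal-cord diameter column is
in nm (its published header unit is a typo), and the spinal mean is
672.07 nm at full precision, printed elsewhere as 672.0 and 672.1; tests
accept both roundings.

## Lamellae periodicity

A radial profile averages bilinear-interpolated samples over n_angles
(default 360) equally spaced angles at each radius; samples outside the
image are excluded, and radii with no coverage truncate the profile with a
flag. For an annular ROI the profile is restricted to the ROI's radial
span (±half a period band) so edge transitions outside the annulus cannot
masquerade as lamellae; a thin annulus is extended to the minimum span the
period band requires.

Detection: subtract a moving-average trend (window 2 × period_max); find
the dominant periodogram frequency in the 5–20 nm band (the mammalian
compact-myelin bracket), refined by quadratic interpolation around the
spectral peak; count peaks above a prominence of 2 × a robust noise
estimate with minimum separation period/2. A period is reported only when
the spectral peak carries at least 20% of the non-DC power and at least
three peaks exist — a single ring has no repetition to define a period.
Peak heights are split into major-dense vs intraperiod classes by an exact
two-class least-squares split; if the class means differ by less than 25%
of the upper mean the peaks are treated as one class (equal-amplitude
rings produce no spurious alternation). No numeric reference period exists
for the archaeological material itself, so the periodicity tests validate
recovery on synthetic truth; the only literature-anchored check is the
detection floor of four layers.

## Pipeline

`run_pipeline` chains denoise → active-contour ROI → FCM over the full
frame → progressive refinement → labeling of the foreground class
intersected with the ROI → per-object measurement (tube vs body by the
elongation rule) → size-class grouping → summary tables, with an optional
lamellae pass. Every stage is deterministic given the config, so repeated
runs produce byte-identical CSVs; the manifest records all effective
parameters and per-stage counts. Foreground selection is by intensity
class ("bright" = top FCM class, "dark" = bottom), a deliberate
simplification: mixed bright/dark structures in one frame need two passes
with different configs.

## Composition utility

Atom% ↔ mass% conversion under explicit closure over the listed elements
(mass%ᵢ = aᵢMᵢ/ΣaⱼMⱼ), with a built-in light-element atomic-mass table
(IUPAC 2021 values) that callers can override. Published organic-matter
C/O percentage pairs are generally not reproducible under two-element
closure because unlisted light elements carry the missing atom fraction;
the utility therefore never infers hidden elements — the caller states the
closure. No ZAF/matrix correction is attempted.

## Problem sizes used in validation

The test suite and acceptance script use scenes from 200×200 up to
800×990 pixels, tube populations of n = 200 at 10 nm/pixel, 512×512 noise
fields for σ estimation, and 20 seeded profiles for period recovery —
sizes at which every analytic oracle stays exact while the whole suite
completes in well under a minute on one core.

## Known limitations

- Measurements are 2-D section measurements; no stereological correction
  is applied, so section obliquity biases diameters upward.
- The tube/body discrimination is the elongation rule only; vessels and
  axons are not distinguished beyond the diameter and wall-thickness
  scales discussed above.
- FWHM wall thickness assumes a single dominant ridge along the crossing
  segment; double membranes closer than the point spread merge.
- The periodicity detector assumes approximately concentric lamellae;
  strongly elliptical or ruptured sheaths blur the radial profile and
  lower the reported confidence.
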
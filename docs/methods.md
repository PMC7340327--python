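# Methods

This note documents the model, the conventions and numerical choices the
package commits to, what the synthetic data does and does not emulate, and
the known limitations.

## Circular statistics

Tilt is circular.  All differences are circular distances
(`signed_diff` maps a−b into (−period/2, period/2], antipodal ties to
+period/2 for sign stability), and all means are resultant-vector means:
the mean of angles θₖ with weights wₖ is arg Σ wₖ e^{jθₖ·360/period} ·
period/360 reduced to [0, period).  A resultant shorter than 1e−9 of the
total weight means the mean direction is undefined and raises a
`DegenerateResultantError`; callers state their fallback explicitly
(pooling falls back to the local estimate at the target and flags it).

Two deliberate conventions deserve attention:

* **Mean absolute difference.**  The tilt-difference statistic aggregates
  the absolute circular distances |Δτ| ∈ [0,180] *circularly* —
  arg Σ e^{j|Δτ|} — rather than arithmetically.  Both aggregations are
  implemented (`aggregation="circular"` is the default everywhere,
  `"arithmetic"` is available); for tightly concentrated differences they
  agree, for dispersed ones they do not, and no code path silently
  substitutes one for the other.
* **Axial (period-180) means.**  The lookup tables average tilt magnitude
  by summing raw phasors e^{jτᵤ} on the full circle and folding the mean
  direction back onto [0,180] — the "raw phasor" convention.  The
  standard axial estimator (angle doubling) is available via
  `angle_doubling=True` on the tables and is the period-180 behavior of
  `circ_mean`.  The two genuinely differ for dispersed axial data (e.g.
  {5°, 175°}: doubling averages to 0, raw phasors to 90).

## Tilt magnitude vs. the 180° modulus

Signed tilt τ ∈ [0,360) decomposes uniquely into magnitude × sign with
magnitude m = |τ centred to (−180,180]| ∈ [0,180] and sign ±1, so that
m·s mod 360 reconstructs τ (τ=240 → m=120, s=−1).  The local model's
"unsigned tilt" tables store **magnitudes**, because the final local
estimate is the product of the magnitude estimate and the sign estimate;
storing the 180° modulus instead would mis-reconstruct every tilt in
(180,360).  The 180° modulus remains the right identification for
*orientation* quantities — the image cues (luminance/texture/disparity
orientations) and `TiltMap.tilt_unsigned` keep it.

## Geometry

* Coordinates: x rightward, y **upward** in the visual field; arrays are
  stored bottom-row-first in memory and flipped by the I/O layer, so a
  ground plane receding in depth has tilt 90°.
* Groundtruth tilt is arctan2(∇ᵧr, ∇ₓr) of the range map, computed with
  separable sampled-Gaussian / Gaussian-derivative kernels, space constant
  σ_tilt = 3 arcmin, truncated at 3σ.  The derivative kernel is
  renormalized so a unit ramp yields exactly unit slope; this makes the
  operator exact on affine rasters despite truncation (the library
  filter's truncated kernel is ~1.6% off at σ=3 px, which would leak into
  every downstream tilt).  A border margin of 3σ is marked undefined
  rather than padded — padding fabricates tilt at edges.  Gradient
  magnitudes below 1e−9 m/arcmin (fronto-parallel) have no tilt direction
  and are undefined.
* Slant is arctan(|∇_θ r| / r) with the gradient per radian of visual
  angle: 0 for fronto-parallel, → 90° for grazing surfaces.  It is used
  only as a sampling constraint.
* Disparity from range is δ = IPD·(1/r − 1/r_fix) radians (converted to
  arcmin), positive = crossed (nearer than fixation); IPD defaults to the
  typical human 6.5 cm.

## Image cues

* Luminance and disparity cues: orientation of the Gaussian-derivative
  gradient, σ_cue = 6 arcmin.
* Disparity map: per-pixel horizontal shift maximizing Gaussian-windowed
  normalized cross-correlation (window space constant = σ_cue), searched
  over the range implied by the scene's distance bounds plus a 2 px
  margin, refined by 3-point quadratic interpolation.  Where NCC = 1 the
  integer match is exact and no refinement is applied.  Pixels failing a
  left↔right consistency check (disagreement > 1 px) are flagged
  half-occluded; flat windows are undefined.
* Texture cue: per pixel, a Gaussian-tapered patch (truncated at 3σ,
  power-of-two side) is Fourier transformed; the cue is the orientation of
  the major principal axis of the amplitude spectrum's second-moment
  matrix (DC removed), mapped *directly* to the image domain — a grating
  modulated along direction θ puts its spectral energy along frequency
  direction θ, so the spectral major axis equals the modulation direction.
  This convention is fixed in the cue metadata and used identically at
  training and test.  Spectra whose principal-axis ratio is below 1.05
  are treated as isotropic (undefined).  At this window size, sampling
  fluctuations of white noise can exceed that ratio, so isotropy is a
  guard, not a detector; what matters downstream is that surviving
  orientations of textureless patches are unbiased (tested).
* Each cue is quantized into 64 equal half-open bins
  (floor(v·64/period)).  A pixel with any undefined cue is excluded from
  both table training and local estimation — no imputation.

## Local model

Training accumulates per-pixel phasors into the 64³ unsigned-cue table
(tilt magnitudes) and the 64-bin signed-disparity table (signed tilts),
with per-scene pre-summation so that training on a union of scenes is
bit-identical to merging tables trained on the parts.  Estimation reads
the conditional circular means; empty cue-triplet cells back off to the
disparity-cue marginal, then to the global prior mean, with per-pixel
provenance recorded.  A zero resultant in a sign cell yields +1 with a
logged warning (determinism).  The factored form — magnitude from three
unsigned cues, sign from the signed disparity cue alone — is the only
implemented combination rule; a joint signed posterior over all three
cues is deliberately out of scope.  An area-matched single-stage control
(`area_matched_sigma`) scales σ_cue so the operator support (6σ) matches
a target diameter, default 1.0°.

## Scene statistics and pooling regions

The mean-absolute-tilt-difference map is computed for all offsets within
a configurable radius (default analyses use 8–12 arcmin), optionally
conditioned on the target's 15°-wide tilt bin (24 bins, matching the
response binning; the count is configurable).  The unconditioned map is
exactly symmetric under pair exchange, enforced by computing each offset
pair once and mirroring.

The 2D Gaussian is fit to the *inverted* surface s = max(diff) − diff,
normalized to unit volume, by Levenberg–Marquardt least squares over a
Cholesky-parameterized covariance (moment-based initialization) — the
difference map is minimal at the centre, so the Gaussian's peak must sit
at the offset of maximal similarity; the inversion is recorded here and
in metadata.  The reported ellipse is the 1-σ iso-level (A = π√det Σ);
only relative areas matter downstream, so the level choice is harmless
but fixed.  Per-bin fits become a `PoolingSpec`: relative areas
normalized to mean 1 (the average area uses the arithmetic mean), aspect
ratios, and orientations given by a configurable rule — default
*orthogonal* elongation (tilt 0° → vertically elongated region), with
"aligned" and "fitted" alternatives, since scene statistics support the
orthogonal reading but the rule is genuinely a modelling choice.  The
average equivalent diameter is D̄ = 2√(Ā/π).

Pooling regions are pixel sets (centre-in-region membership, no partial
weights) with equal weights by default (a Gaussian taper exists but is
off: equal weights are the only stated choice, for the circular model).
Elliptical regions scale the bin's relative area by π(D̄/2)²; a
zero-diameter region is the single target pixel, so the global model
degenerates to the local model *exactly* (special-cased to avoid even
round-off).  Adaptive pooling can key on groundtruth tilt (oracle
analyses) or on the initial local estimate at the target — one pass, no
iteration.  Undefined local estimates are dropped and weights
renormalized; a degenerate pooled resultant falls back to the target's
local estimate, flagged.

## Synthetic data

The generator emulates the structural properties of outdoor
range-scanned stereo databases: stereo pairs at 6.5 cm IPD with
co-registered range, nothing nearer than 3 m (violations are an error),
piecewise-smooth surfaces, a cardinal-peaked tilt prior (default: 60% of
mass in the four cardinal bins), and tilt-dependent anisotropic spatial
correlation.  Three scene kinds: planar Voronoi mosaics (analytic
groundtruth per facet), a ground plane with fronto-parallel objects, and
smoothed random depth fields.  Defaults are fixed once: distances 5–20 m,
slants 30–60° (the psychophysical sampling range), 1/f-amplitude texture
(a falling spectrum is what makes foreshortened texture informative —
compression raises the spectral cutoff along the tilt direction),
Lambertian shading under a fixed directional light, distance-dependent
luminance attenuation (30 m e-folding, standing in for aerial perspective
and irradiance falloff, which gives the luminance gradient its tilt
signal on planar surfaces), and 1% pixel noise.  The right eye is the
left image warped horizontally by the groundtruth disparity with cubic
interpolation; fold-over pixels are recorded as half-occluded.  In
mosaics, analytic tilt is marked undefined within 12 px of facet
boundaries: the rendered range (and any finite-support cue) mixes
surfaces there, so the per-facet tilt is not the groundtruth of the
rendered scene.

Two direct tilt-map generators support the statistics and pooling
analyses without rendering: anisotropically smoothed complex-noise fields
(tilt = phase; the difference-map ellipse inherits the kernel's
orientation and axis ratio), and anisotropic-Voronoi patchworks whose
cell metric is contracted along the orientation given by the tilt rule,
so cells are elongated orthogonally to their tilt without the
fragmentation that sequential ellipse painting would cause.  The
simulated observer draws von Mises responses about groundtruth with
optional cardinal attraction, 180° sign flips, and uniform lapses.

What passing tests on these data do *not* show: performance on real
scenes with cluttered geometry, specular materials, vegetation-like
texture statistics, sensor miscalibration, or real human response
idiosyncrasies.  The synthetic results establish correctness of the
machinery and the direction of the pooling effects, not the field
magnitudes.

## Evaluation

Estimation error is the absolute circular distance to groundtruth;
prediction error the distance to (simulated) observer responses; both
default to the circular aggregation above.  Sweeps share one
per-target error matrix across diameters; argmin ties resolve to the
smallest diameter (conservative pooling), with ties detected at 1e−9 to
absorb phasor round-off.  Bootstrap CIs resample stimuli with
replacement (default 1000 sets, 2.5/97.5 percentiles, seeded).  Per-bin
best diameters are compared to spec-predicted diameters by Pearson
correlation with a seeded permutation p-value (10⁴ permutations);
constant vectors are flagged undefined rather than asserted.  The
reliability diagnostic reports conditional distributions of groundtruth
given the estimate and a shift-invariance score (mean pairwise
total-variation distance after recentring) — reported, never asserted.
The consensus baseline is the per-stimulus circular mean across
observers, an upper-bound reference for prediction error.

## Problem sizes

The shipped analyses run on one CPU in minutes: scene ensembles of 6–20
scenes at 128–512 px, 64³ tables trained on 10⁴–10⁵ pixels, sweeps over
~7 diameters with 400–12,000 targets, 100-set pooling comparisons, and
1000-instance brute-force oracles.  These sizes were chosen so every
property is measured with comfortable statistical margin while the whole
suite stays interactive.

## Known limitations

* Pooling ignores depth boundaries; on scenes with many discontinuities
  the optimal diameter shrinks and adaptive shapes matter less.
  Boundary-gated pooling is deliberately out of scope.
* The 64³ table needs large training ensembles to populate; on small
  synthetic runs most test pixels use the disparity-marginal fallback
  (provenance makes this visible).
* The texture cue computes one FFT per pixel; full-frame maps at large
  image sizes are the pipeline's slowest stage.
* The stereo matcher is horizontal-shift only (no vertical disparity, no
  multi-scale pyramid), adequate for the rendered geometry it is paired
  with.
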
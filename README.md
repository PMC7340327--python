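# tiltpool

Hierarchical estimation of 3D surface tilt from stereo images, with spatial
pooling rules grounded in scene statistics.

## The problem

A surface's 3D orientation is described by its **slant** (how far it is
rotated out of the frontoparallel plane, 0–90°) and its **tilt** (the
direction of that rotation: the angle of the surface normal projected into
the frontoparallel plane, 0–360°).  Estimating tilt from images is hard
because every local cue is noisy and ambiguous, but tilts in real scenes
are spatially correlated — nearby points usually belong to the same
surface — so estimates can be improved by pooling over a neighborhood.
This package implements, end to end, a two-stage model of that process for
researchers in computational vision and natural-scene statistics:

1. **Local stage.**  At each pixel, three image cues are measured — the
   orientations of the local luminance gradient, of the dominant axis of
   the windowed amplitude spectrum (texture), and of the gradient of the
   binocular-disparity map recovered by windowed normalized
   cross-correlation.  Each cue is quantized to 64 levels, and lookup
   tables trained on scenes with co-registered range data store the
   conditional circular mean of groundtruth tilt for every cue
   combination:

   τ̂ᵤ = E[τᵤ | Cᵤ] = arg Σ e^{jτᵤ}   over the tilts co-occurring with the
   unsigned cue triplet Cᵤ = [Lᵤ, Tᵤ, Dᵤ], and

   sgn(τ̂ₛ) = sgn(E[τₛ | Dₛ])   from the signed disparity cue alone.

   The local signed estimate is the product τ̂ˡᵒᶜᵃˡ = τ̂ᵤ · sgn(τ̂ₛ).

2. **Global stage.**  The local estimates in a spatial neighborhood N
   centred on a target are combined by a weighted circular mean,
   τ̂ᵍˡᵒᵇᵃˡ = Σᵢ∈N wᵢ τ̂ᵢˡᵒᶜᵃˡ (phasor notation).  The neighborhood is
   either a **fixed circle** (one diameter for all tilts) or an **adaptive
   ellipse** whose area, aspect ratio, and orientation depend on the
   target tilt, fit to the spatial tilt statistics: the mean absolute
   circular tilt difference E[|τᵢ − τ₀| | τ₀] as a function of spatial
   offset, summarized by a 2D-Gaussian fit whose iso-level ellipses give
   the pooling regions.  Ellipse sizes are compared to circles through
   the equivalent diameter D = 2√(A/π).

Groundtruth tilt is the orientation of the range gradient,
τ = arctan2(∇ᵧr, ∇ₓr), computed with Gaussian-derivative operators
(σ_tilt = 3 arcmin; cues use σ_cue = 6 arcmin).

Because the original laser-scanned stereo database is not publicly
accessioned, the package ships a first-class synthetic-scene generator
(`tiltpool.synthetic`) that renders stereo pairs with known range,
tilt-dependent anisotropic spatial statistics, and a parametric simulated
observer, so every stage is testable against analytic groundtruth.

## Worked example

Fit the full hierarchy to six rendered scenes with smoothly varying,
anisotropically correlated depth (horizontal 25:10 arcmin correlation
kernel), then inspect the fit:

```python
import numpy as np
from tiltpool import HierarchicalTiltModel, ViewingGeometry
from tiltpool.synthetic import SceneRecipe, generate_scene

geom = ViewingGeometry(pixel_scale=1.0, fixation_distance_m=10.0,
                       image_size=(160, 160))
recipes = [SceneRecipe(seed=s, kind="smooth_field", depth_amplitude_m=0.8,
                       correlation_length_major_arcmin=25.0,
                       correlation_length_minor_arcmin=10.0)
           for s in range(6)]
scenes = [generate_scene(r, geom) for r in recipes]
model = HierarchicalTiltModel(scenes, use_groundtruth_disparity=True,
                              max_offset_arcmin=10.0, n_tilt_bins=12)
res = model.fit()
print(res.summary())
```

```
Hierarchical surface-tilt model
==============================================
training pixels                  53,956
cue bins per dimension               64
occupied cue-triplet cells        13.1%
unsigned-mean convention     raw phasor
tilt bins (statistics)               12
fitted average eq. diam         18.4 arcmin
aspect ratio (min..max)      2.21 .. 2.86
relative area (min..max)     0.52 .. 1.51
cardinal-bin prior mass           34.2%
```

The fitted pooling ellipses recover the generating anisotropy (aspect
ratios 2.2–2.9 against a 2.5 kernel ratio).  `res.estimate(scene, ...)`
then produces local or pooled tilt maps for new scenes.

The value of pooling is clearest when local-estimate noise is independent
across pixels.  On a scene of 100 constant-tilt patches with 40° circular
noise on the local estimates, the error-vs-diameter sweep
(`tiltpool.evaluation.sweep_diameters`) prints:

```
    0.0 arcmin    31.97 deg     <- local model (no pooling)
    4.0 arcmin    10.21 deg
    8.0 arcmin     8.42 deg     <- best: noise averaged within patches
   16.0 arcmin    10.71 deg
   32.0 arcmin    18.79 deg
   64.0 arcmin    37.06 deg     <- pooling across unrelated surfaces
   96.0 arcmin    54.36 deg
```

Pooling first averages out estimate noise, then — once the region
outgrows the surfaces themselves — mixes unrelated tilts and hurts: the
U-shape that motivates a finite, statistics-matched pooling region.

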
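# Methods

This note documents the models, conventions and numerical choices behind
`vesselmorph`, in the order the pipeline runs.

## Phantom image formation

The generator is designed around what the measurement chain actually
consumes, not around physical optics.  No point-spread function or
aperture diffraction is modelled; the claim the phantoms support is that
the *processing* recovers boundary geometry correctly, not that the images
look like any particular instrument's output.

**Scene.**  A vessel is a capsule around a dense centerline polyline with
arc-length lumen-radius and wall-thickness profiles (constant by default).
The confocal reflectance is a smooth background (0.40) with a slightly
brighter lumen (+0.05) and a brighter wall band (+0.20), with 1 px
smoothstep transitions.  A static random texture field (s.d. 0.08,
correlation length 1.5 px) is added as a photoreceptor-mosaic surrogate:
without it a straight uniform vessel carries no information about
along-vessel motion and frame registration is unconstrained in that axis.

**Flow.**  Moving blood cells are modelled as i.i.d. Gaussian speckle per
frame per lumen pixel (s.d. `flow_sigma`); temporal ordering is irrelevant
to a standard-deviation image, so no hemodynamic correlation is simulated.
The speckle amplitude ramps linearly over 1 px centred on the true lumen
radius, so the half-height crossing of the STD profile sits at the true
radius regardless of how the boundary falls on the pixel grid.  Truth
diameters therefore share the measurement convention exactly.

**Offset channels.**  A smooth phase surrogate
`φ = A·[tanh((d−R_lumen)/w) + tanh((d−R_ext)/w)]` (A = 0.225, w = 1.5 px,
d = distance to the centerline) has gradient-magnitude peaks exactly at
the two wall edges.  The four offset channels are a constant base (0.5)
plus/minus half the row/column finite-difference of φ, so opposed channels
sum to a gradient-free field and their normalised difference recovers the
directional phase gradient.  Mural-cell edges are short arcs (8–14 px,
windowed with 4 px tapers) of an extra tanh step at a radius strictly
inside the wall band; their arc-length intervals and radial fractions are
retained as annotations so rejection logic can be scored.  The number of
injected arcs is `round(mural_edge_rate)` for reproducibility.

**Acquisition.**  Each frame is the scene translated by a per-frame
Gaussian jitter draw (rigid translation only, matching the
translation-only registration), with additive noise of per-pixel standard
deviation `sqrt(amp² + shot²)` inside the flow support and
`sqrt(background² + shot²)` outside, then clipped at zero.  All five
channels share the jitter.  Frames are rendered in float32 with a single
stacked interpolation and a single noise draw per frame; identical
geometry + noise model (including seed) gives bit-identical stacks.

Defaults (free parameters; the source study reports no acquisition noise
statistics): `flow_sigma` 0.10, `background_sigma` 0.005,
`shot_noise_sigma` 0.01, `jitter_sigma` 1.0 px, 100 frames.

**What the phantoms do not emulate:** intra-frame (scanline) distortion,
torsional eye motion, pulsatile flow, capillary-scale vessels, wall
texture or pathology (hyper-/hypo-reflective lesions), and realistic
speckle statistics.  Passing tests demonstrate correctness of the
geometry-recovery chain under this model, not performance on clinical
images.

## Preprocessing

Frame quality is normalised cross-correlation against the stack median
image; the default keep count is `min(50, frames)`.  Registration is
rigid translation estimated by phase correlation (mean-subtracted, Hann
windowed, upsampled 20× for subpixel resolution) against the
highest-quality frame.  Windowing matters: unwindowed correlation has
~0.2 px wrap-around bias, and skimage's spectral-whitening normalisation
fails outright on smooth scenes, so plain cross-correlation is used.
Estimated shifts below 0.1 px snap to zero so an already-aligned stack is
not resampled; shifts beyond 20% of the image width drop the frame with a
warning.  The confocal shifts are applied to all offset channels (the
channels are simultaneous).  Mean and STD images use the n−1 denominator
and are NaN outside the intersection of shifted frame footprints; the
choice of denominator is immaterial downstream but fixed for testability.
STD images are never intensity-normalised before measurement.

## Split detector and MPG

`split = (a − b) / max(a + b, ε)` with ε = 1e-6 of the mean sum — the
standard offset-aperture convention (the source names but does not define
the formula; the methods reference it cites may use different constants).
Split detection runs on registered mean images, not frame-by-frame, to
maximise SNR.  Both components are smoothed with an isotropic Gaussian
(σ = 1 px, configurable) before the norm to stabilise local-maximum
detection.  Channel geometry (which file is "up") is declared by the
caller, never inferred from content.

## Segmentation

*Tracing.*  Flow mask = STD ≥ Otsu threshold; the seed's connected
component is hole-filled (flow speckle leaves ~1% sub-threshold holes that
would fragment the skeleton), skeletonised, and the longest skeleton path
is smoothed with a spline and resampled at 2 px.  Ends are trimmed by
1.35× the initial radius estimate (distance-transform median along the
skeleton) to avoid end-cap distortion; segments shorter than 50 px after
trimming are rejected.

*Lumen boundary.*  Per normal, per side: plateau = median STD over the
inner half of the profile, background = median beyond 1.8× the initial
radius estimate; the boundary is the outermost radius where the profile
falls through background + 50% of (plateau − background), located by
linear interpolation.  The half-height rule (rather than maximum gradient)
is a package choice — it is robust to profile asymmetry; the source
specifies only "boundary of the blood flow".

*External boundary.*  Candidates are local MPG maxima with prominence
≥ 20% of the profile's maximum prominence, at least 2 px outside the lumen
radius (which excludes the inner-wall MPG peak); the candidate nearest the
lumen wins, refined by parabolic interpolation.  Profiles are sampled at
0.25 px steps out to 2.5× the initial radius estimate.

*Continuity.*  Per side, radius samples deviating from a window-11 running
median by more than 3× the median absolute deviation (floored at 0.25 px
so noiseless sequences are not all flagged) are spurious: external samples
are re-chosen as the next admissible MPG maximum outward that passes the
same screen, otherwise excluded.  Surviving sequences minimise
`Σ w_i (x_i − r_i)² + λ Σ (Δ²x)²` (λ = 2 by default), a discrete snake
whose second-difference penalty also bridges excluded gaps; λ = 0 is an
exact identity.  Vessels with more than half their samples excluded are
rejected.  The automatic re-choice covers what the original workflow did
by hand; a YAML edit journal (erase/set/exclude, replayed
deterministically) remains for cases automation misses.  `external >
lumen` is enforced as a hard invariant after every stage.

## Morphometry

Vessel LD and ED are unweighted means of per-sample diameters over kept
samples (arc-length weighting would differ only for strongly nonuniform
spacing, which the tracer prevents).  `W = (ED − LD)/2`;
`WLR = W / LD` computed from vessel means (a ratio of means, robust to
per-sample noise), using the single-wall convention — the published
summary cells are internally consistent with `W/LD` and not with `2W/LD`.
Contour areas use the shoelace formula (via shapely, which also rejects
self-intersecting polygons).  Grader agreement compares lumen and
wall-annulus areas by strip integration on a common arc-length grid,
overall and on four equal arc-length quarters ("sub-region" is undefined
in the source; quarters are this package's fixed choice); every relative
delta must be strictly below 0.10.

## Statistics

The arteriole is the unit of analysis; within-eye/within-patient
clustering is not modelled (a documented limitation — ids are retained so
users can aggregate).  The rank-sum test enumerates all `C(n+m, n)` rank
assignments (midranks for ties) when both samples have ≤ 10 observations,
else uses the tie-corrected normal approximation with a 0.5 continuity
correction.  The severity omnibus is Kruskal–Wallis by default,
switchable to a Jonckheere–Terpstra ordered-trend test; all pairwise
contrasts are reported without multiplicity adjustment (exploratory
convention: p ≤ 0.05 significant, p ≤ 0.1 trend-level).  Quartiles use the
linear-interpolation rule; the rule is part of the contract because
conventions differ on small samples.

Cohort-generator group distributions are truncated normals whose
location/scale derive from the published per-group quartiles
(location = (Q1+Q3)/2, scale = IQR/1.349); the two-group effect cohort
uses the control-group parameters for both strata with a +4 µm wall shift.
The ~40% ED-significance rate under that shift is expected — ED inherits
the wall shift — which is why the end-to-end check asserts "no systematic
diameter effect" (a minority of significant replicates) rather than
per-replicate non-significance.

## Problem sizes

Validation suites run 20 default-noise phantoms spanning LD 90–180 µm and
W 12–22 µm at 1 µm/px for parameter recovery, three orientations for
isotropy, 2000 null replicates at n = 55 for the type-I check and 200
replicates for the effect-direction check; the acceptance script uses 8
recovery phantoms.  These sizes are the package's own trade-off between
Monte-Carlo resolution and runtime.

## Known limitations

Bifurcations, venules and capillaries are out of scope; the tracer assumes
a single unbranched segment.  Pixel scale is an input (no axial-length
model).  Agreement analysis assumes both graders segment the same traced
vessel.  Statistical power statements apply to the synthetic cohort model,
not to any clinical population.
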
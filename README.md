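# vesselmorph

Morphometry of retinal arterioles from adaptive-optics scanning laser
ophthalmoscope (AOSLO) acquisitions with multi-offset detection.

Arteriolar wall remodeling — wall thickening and luminal narrowing — is an
in-vivo marker of microvascular damage in diabetes and hypertension.  An
AOSLO with one confocal and four offset-aperture detection channels can
resolve both the blood column and the vessel wall: temporal intensity
fluctuations from moving blood cells outline the perfused lumen, and the
refractive-index discontinuities at the wall edges show up as maxima of the
magnitude of the phase gradient.  `vesselmorph` implements the full
analysis chain from raw multi-channel frame stacks to group-level
statistics, plus a phantom generator with known ground truth so the whole
chain is testable without patient data.

## Method

For each retinal location, 100–200 frames per channel are acquired. The
pipeline then computes, per arteriole:

1. **Preprocess** — the best frames are selected by correlation to the
   stack median, registered by rigid translation (windowed subpixel phase
   correlation on the confocal channel; shifts shared by all simultaneous
   channels), and collapsed into mean and temporal standard-deviation
   images.  The STD image is a dye-free motion-contrast map of the lumen.
2. **Phase gradient** — opposed offset channels form two orthogonal
   split-detector images, `(a − b) / (a + b)`, and the MPG image is their
   Euclidean norm `√(h² + v²)`; its maxima trace the wall edges
   independently of vessel orientation.
3. **Segmentation** — the vessel is traced on the STD image; along each
   centerline normal, the lumen boundary is the half-height crossing of
   the STD profile and the external wall boundary is the nearest admissible
   MPG maximum outside the lumen.  A discrete-snake continuity stage
   re-chooses or excludes samples that break from a running median (these
   are typically mural-cell edges masquerading as the outer wall) and a
   replayable edit journal covers residual manual corrections.
4. **Morphometry** — luminal diameter `LD`, external diameter `ED`, mean
   single-wall thickness `W = (ED − LD)/2` and wall-to-lumen ratio
   `WLR = W/LD`, so `ED = LD·(1 + 2·WLR)` holds exactly.  Inter-grader
   agreement requires < 10% lumen and wall-annulus area difference,
   overall and on four arc-length quarters.
5. **Statistics** — two-sided Wilcoxon rank-sum tests (exact enumeration
   for small samples, tie-corrected normal approximation otherwise) by
   diabetes status, a Kruskal–Wallis omnibus plus pairwise contrasts
   across retinopathy-severity groups, and `IQR (Q1, Q3)` summary tables.

## Worked example

```python
from vesselmorph import simulate_default_phantom, preprocess_acquisition
from vesselmorph.phase_gradient import mpg_from_offsets
from vesselmorph.segmentation import segment_vessel
from vesselmorph.morphometry import compute_morphometry

acq = simulate_default_phantom(120.0, 16.0, seed=1, n_frames=40,
                               usable_length_px=120)
derived, reg = preprocess_acquisition(acq.channels)
mpg = mpg_from_offsets(derived)
seg = segment_vessel(derived["confocal"].std_image, mpg.pixels,
                     acq.seed_point)
m = compute_morphometry(seg, pixel_scale=1.0)
print(f"LD={m.ld_um:.2f} ED={m.ed_um:.2f} W={m.wall_um:.2f} WLR={m.wlr:.3f}")
```

prints

```
LD=120.09 ED=152.00 W=15.95 WLR=0.133
```

i.e. a phantom arteriole with true LD 120 µm and wall 16 µm at 1 µm/px is
recovered to within 0.1 µm under the default noise model (flow speckle,
eye-motion jitter, shot noise).

The same chain is available from the shell:

```sh
vesselmorph run --config run.yaml          # full pipeline with caching
vesselmorph simulate --config phantom.yaml --out data --seed 1
vesselmorph stats --cohort cohort.csv --out stats/
```

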
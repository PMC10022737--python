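# Methods

This note documents the models and procedures implemented in `debriscope`,
the parameters that matter, the numerical choices, and what the synthetic
validation does and does not demonstrate.

## The assay being modelled

Water samples (default 50 mL) are gravity-filtered through an ultrathin
(400 nm) silicon nitride membrane with lithographically patterned 8 μm
slit pores; three 0.7 × 3.0 mm windows give 6.3 mm² of active area.
Captured debris is imaged on the membrane in brightfield Nomarski-DIC
(2.5625 px/μm) and, after Nile red staining, in epifluorescence
(0.6107 px/μm). Stained (lipophilic) debris is reported as *presumptively*
plastic — the package computes a stained fraction and leaves the material
interpretation to the user; spectroscopy is out of scope.

## Pixel classification

A per-pixel random forest assigns each pixel to one of five classes —
particle (debris), slot, residue, membrane, edge — from a handful of
scribbled example regions on a single image per sample; that classifier
is then applied to every image of the sample.

* **Feature stack (21 features)**: raw intensity plus, per scale
  σ ∈ {1, 2, 4, 8} px: Gaussian-smoothed intensity, gradient magnitude,
  Laplacian, and both Hessian eigenvalues. The recipe is fixed and
  recorded in classifier metadata, so any saved classifier is
  self-describing. Reflective boundaries make interior pixels translation
  equivariant.
* **Forest**: 200 trees by default (config override available — reports
  of the original workflow cite both 100 and 200 iterations; we default
  to 200), unlimited depth, √n_features per split, bootstrap on, single
  thread, fixed seed. Training is deterministic given the seed.
* **Scribbles**: training regions are stroke-like — lines walked from a
  random in-class pixel until they hit the class boundary (default
  60 px ≈ 23 μm), thickened by one pixel. Strokes clipped at boundaries
  matter: they expose the classifier to near-edge context (membrane next
  to a slit, particle rims), which interior-only patches do not, and are
  what a human annotator naturally draws.
* **Scaling**: images wider than 2000 px are downscaled to 2000 px before
  classification; the scale factor propagates into the pixel scale so all
  metrology stays in μm.

## Debris thresholding (histogram minimum)

The debris-class probability map is binarised with the
Prewitt–Mendelsohn minimum method: build a 256-bin histogram over the
map's full range, repeatedly replace it by its replicate-edge 3-point
mean until exactly two local maxima remain (plateau-aware counting; a run
of equal bins is one maximum), and threshold at the minimum between the
modes. Numerical choices:

* foreground is *strictly above* the threshold bin;
* ties among between-mode minima break to the lowest bin index;
* a histogram that is (or becomes) unimodal raises an explicit error, and
  the smoothing loop is capped at 10,000 iterations;
* the implementation is verified exactly against an independently coded
  brute-force version on seeded random bimodal histograms.

In the composed pipeline (`segment_debris_map`) the thresholded mask is
conditioned with a 3×3 binary median filter (configurable, 0 disables)
before object analysis. Classifier probability maps carry per-pixel
noise; without despeckling, ragged mask boundaries seed spurious
distance-transform maxima and the watershed over-splits. The primitive
operations themselves (threshold, fiber extraction, watershed) remain
unconditioned.

## Fiber vs particulate discrimination

The assay's fiber rule is geometric: a debris component is a fiber iff it
**spans the field of view**. Implemented as: the component touches two
distinct image borders, *and* the end-to-end geodesic length of its
skeleton (8-connected, diagonal weight √2, longest shortest path via
double-sweep Dijkstra, plus the distance-transform radius at both skeleton
ends to restore what skeletonization trims) is at least
`min(H, W) − 2` px — the 2 px is a rasterization allowance without which a
perfectly straight border-to-border band fails by one pixel. Interior
fibers are deliberately counted as particulate; crossing fibers merge into
one component and count once (documented non-goal).

Fiber diameter = 2 × mean distance-transform value along the skeleton,
converted to μm; fibers are binned **large** (> 8 μm — wider than the
slits, so they could never pass the filter) or **small** (≤ 8 μm).
Components under 2 px² are discarded as sub-resolution speckle
(configurable).

## Aggregate separation

Touching particles are split by a watershed of the negated Euclidean
distance transform, seeded at its regional maxima with maxima closer than
2 px merged; each connected component is guaranteed at least one marker,
so the watershed can only split, never merge. Determinism follows from
the deterministic EDT, peak ordering and flooding.

## Metrology, volume and mass

Each separated label is measured with the moment-equivalent ellipse (the
ellipse with the same normalized second central moments as the region —
the de facto standard of particle-analysis tools). Axes convert px → μm
by dividing by the pixel scale; a sub-pixel fitted axis is floored at one
pixel rather than dropped.

Volume models the 2-D projection as an **oblate spheroid**:
R₁ = R₂ = major/2, R₃ = minor/2, V = (4/3)πR₁R₂R₃. A `spheroid="prolate"`
switch (R₁ = R₂ = minor/2, R₃ = major/2) exists for sensitivity analysis.
Projection minimization and watershed fragmentation both bias volumes
low; the summed *areas* of a split aggregate are conserved exactly, but
its summed spheroid volume is generally below the unsplit estimate — this
is inherent to the model, not a defect, and is therefore not asserted.

Mass uses the unit identity 1 μm³ × 1 g/cm³ = 10⁻³ ng over a density band
(default 0.8–1.8 g/cm³, covering common polymers), reported as a
(low, high) mass band.

## Fluorescence quantification

The stained channel (single plane or z-stack, max-projected) is cropped
to the active area (a manual, per-acquisition rectangle; full frame by
default), thresholded with the same minimum rule, watershedded and
measured. Two guards distinguish a blank membrane from a failure:

* a histogram that never becomes bimodal → zero particles, status
  `"blank"`;
* a *chance* bimodal histogram on a noise-only image (including the
  clip-at-zero spike) is caught by requiring the foreground to clear the
  background by 6 robust standard deviations (1.4826 × MAD of the crop).

Stained detections are matched to brightfield particles by
nearest-centroid assignment (one-to-one, default tolerance 5 μm);
unmatched stained objects are kept as stained-only records. The stained
fraction is stained concentration over total concentration.

## Sample summary

Counts are scaled up from the imaged fraction of the active area
(`imaged_area_fraction` = n_images × field area / 6.3 mm², computed and
recorded by the pipeline) and divided by the filtered volume:
concentration = count / (fraction × volume). Replicate dispersion is the
SEM over replicate concentrations (sd/√N), never pooled images. Daily
exposure = concentration × 500 mL/day by default. Images whose particle
count exceeds ×10 the replicate median (or falls below median/10) are
excluded with a logged reason — an automated analogue of judging
"orders-of-magnitude" outliers by eye; factor = ∞ disables it, a zero
median or fewer than three images suspends it.

## The synthetic scene generator

Every stage is validated on generated scenes with exhaustive ground truth
(per-pixel object labels, per-pixel class labels, per-object tables).
What it emulates:

* membrane background with vertical slit stripes (slit width rasterized
  to `round(8 × 2.5625) = 21 px`, pitch 20 μm — a plausible value
  consistent with >10% porosity, configurable), a bright window-edge band,
  and mottled low-contrast residue patches;
* log-normal particle sizes (median 2 μm, σ_log 0.6, truncated to
  [0.5, 25] μm) — heavily skewed toward the smallest observable sizes;
  random orientation and aspect 0.5–1;
* aggregates: ⌊aggregate_fraction × n⌋ particles placed overlapping a
  previously placed partner (centroid spacing = 0.8 × summed radii);
* fibers: sinusoidally perturbed paths spanning opposite borders, stamped
  at the requested diameter; rejection-sampled not to cross each other so
  per-fiber ground truth stays well defined;
* DIC-like photometry: per-object signed contrast plus a bas-relief term;
  debris over an open slit renders bright regardless of contrast sign
  (debris there is lit against the dark opening);
* noise: additive Gaussian (σ = 2% of range) plus a random linear
  illumination gradient (±3%);
* fluorescence: the stained subset re-rasterized at its own pixel scale
  (co-registration by geometry, not resampling), rendered near-saturated
  with a PSF blur (σ 0.6 px) and 2% noise — the exposure-for-dye,
  max-projection regime; a sub-resolution stained emitter still lights
  its containing pixel.

What it does **not** emulate: physically accurate DIC or fluorescence
optics, spectral properties, debris chemistry, stain variability,
filtration hydrodynamics, or real textures of rust/sand/biofilm. Passing
closure tests therefore demonstrates the *algorithmic* correctness of the
chain under class-separable imagery, not field performance on real
micrographs.

## Validation results the tests compute

* threshold: exact agreement with the brute-force oracle on 100 random
  bimodal histograms;
* segmentation closure (10 seeded 512×512 scenes, 200 particles ≥ 2 μm,
  ≤ 20% aggregated, 3 spanning fibers): particle counts within ±10% of
  truth, all fibers recovered, zero interior blobs called fibers;
* classifier: ≥ 0.95 held-out pixel accuracy against the ground-truth
  class map over 5 seeds (8 stroke regions per class, 200 trees);
* stained fraction: configured 0.5–8% recovered within ±2 percentage
  points (mean over 10 seeds per fraction);
* normalization: tile/whole-image concentration identity, exposure
  linearity (5.044/mL → 2522/day), SEM convention;
* determinism: byte-identical tables and summaries across reruns of the
  full pipeline with fixed seeds.

Problem sizes (512×512 scenes, 200 particles, ≤ 10 seeds per study) were
chosen so the whole suite completes in about a minute on one CPU while
keeping per-scene statistics meaningful.

## Known limitations

* The full classifier path overcounts particles by roughly 1.5–2× on
  synthetic scenes relative to ground truth: the signed DIC relief
  creates intensity waists inside particles that survive thresholding and
  get split by the watershed, and slot-edge misclassifications add small
  false components. The closure studies therefore isolate the
  segmentation chain with an idealized debris-probability map; the
  classifier is held to its pixel-accuracy criterion instead.
* Fiber detection through the classifier path inherits the classifier's
  weakest failure mode: when the training strokes under-sample fiber
  appearance, stretches of a fiber are misclassified, the component no
  longer spans the field, and the fiber is counted as particulate (or
  lost). This mirrors practice — semi-automated fiber counts are known to
  be fragile enough that manual recounts are common — and is why the
  fiber-recovery validation drives the segmentation stage with an
  idealized debris map. Retraining with better examples is the remedy,
  exactly as in the interactive workflow.
* Stained counting at the coarse fluorescence scale (0.6107 px/μm) cannot
  separate stained particles closer than ~3 μm; they merge into one
  detection.
* Fiber diameter is a skeleton-mean; for strongly varying-width fibers it
  under-represents the extremes.
* Concentrations assume the imaged fields are representative of the whole
  active area; the imaged-area fraction is recorded so this assumption is
  auditable.
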
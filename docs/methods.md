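# Methods

This note documents the models, estimators and numerical choices behind
`lvmotion`, and what the synthetic phantom does and does not establish about
real data.

## Dyskinesia index

For `M` angular segments with mean radial displacement `d_i(t)` (inward
positive, measured against an end-diastolic reference frame), the
displacement efficiency and dyskinesia index are

    eff(t) = |Σ_i d_i(t)| / Σ_i |d_i(t)|,      DI = mean over included t of eff(t).

Choices and their rationale:

* **Magnitude in the numerator.** `eff` is defined as a magnitude, which is
  what confines DI to [0, 1] (a raw signed ratio would reach −1 when most of
  the wall bulges). A consequence is that DI is invariant to a global sign
  flip of the field, so the instrument's sign convention affects only
  reporting, never the index.
* **Frame exclusion, not imputation.** Frames with `Σ|d| ≤ 1e-9 mm` (always
  the reference frame; under pure noise possibly others) carry no
  directional information. Assigning them eff = 1 or 0 would shift DI by an
  arbitrary constant, so they are excluded from the average and reported in
  `excluded_frames`.
* **Unweighted mean over frames.** Acquisition frame times are close to
  uniform (30–40 frames per cycle), so no time-weighting is applied.
* **Slice selection.** Regional dyskinesia is scored on the short-axis plane
  2 mm above the apex (the default `di_slice_height_mm` in the pipeline
  config), where apical infarcts bulge; any slice can be selected.

Known behaviour under noise: frames near the cycle ends have little true
motion, so with additive tracking noise their eff is noise-dominated
(expectation ≈ `1/√(πM/2)` rather than the noiseless value). Averaging over
the cycle therefore biases DI slightly toward 0; the bias shrinks as the
motion-to-noise ratio grows and is negligible at the amplitude scales
(≈ 1 mm excursion vs ≈ 0.01–0.02 mm noise) typical of murine speckle
tracking. This is a property of the statistic itself, shared by any
implementation of the definition above.

## Contour kinematics

Displacements are recovered from contours geometrically (the package does
not re-implement speckle tracking; it consumes either contours or the
tracker's displacement export):

* The centroid of the **reference (end-diastolic) frame** — the max-area
  frame by default — is held fixed for the whole cycle. A per-frame centroid
  would follow a bulging wall and partially cancel exactly the motion the
  index must detect.
* Radii are sampled by ray casting from that centroid, `K = 4` rays per
  segment at equal angles (segment 1 starts at the +x axis, CCW), averaged
  per segment; `d_i(t) = r_ref,i − r_t,i`. Contours must be star-shaped
  about the reference centroid — true of short-axis LV anatomy — and a ray
  crossing the boundary more or fewer than once is a hard error naming the
  frame, never a silent repair.
* Anatomical sector labels (anterior, anterolateral, …) are a
  presentation-layer grouping of the 96 segments and deliberately kept out
  of the math core.

## Volumetrics

End-diastole and end-systole are detected **per slice** as the frames of
maximal/minimal endocardial area (ties break to the earliest frame), because
slices of a dyssynchronous ventricle peak at different phases; volumes are
plain disc sums `Σ A·h` with no apex/base cap correction, matching a 1 mm
slice protocol. EF and SV follow algebraically, and fold-changes vs each
animal's own baseline are used for longitudinal volume comparisons (EF is
reported absolute — which metrics are normalised is pipeline configuration).
Polygon areas and centroids use exact shoelace-based geometry (via shapely).

## Wall thinning

Thickness is measured from an endocardial sample point along the local
outward normal to the nearest epicardial intersection (normal-ray
thickness). Nearest-point distance was rejected because it underestimates at
corners and depends on the epi trace's vertex density; for smooth concentric
traces the two agree to well under the 1e-3 mm test tolerance. The thinning
extent applies the **inclusive** 0.5 mm threshold ("0.5 mm or thinner") and
weights samples by arc length (trapezoidal half-intervals, wrapping for
closed traces). Long-axis traces are supplied as contour files; the package
does not synthesise long-axis views from the short-axis stack.

## Cohort statistics

* Summaries are mean ± SEM (sd/√n, ddof = 1).
* Two-sample comparisons use the two-tailed **pooled-variance** Student's
  t-test (not Welch), per the study design this layer reproduces.
* The repeated-measures analysis is a classical two-way mixed-design ANOVA:
  between-subject factor group, within-subject factor time, subjects nested
  in groups as the error stratum for the group effect. Sums of squares are
  computed directly (group sizes may differ; within-subject data must be
  complete) and agree with `pingouin.mixed_anova` to relative 1e-9 in the
  test suite. No sphericity correction is applied. Post tests are unpaired
  per-timepoint group contrasts with Bonferroni multiplication by the number
  of timepoints, capped at 1. Animals missing any included timepoint are
  dropped complete-case with a logged warning (the package's explicit choice
  for dropout handling). The significance threshold defaults to 0.05.

## Motion phantom

The phantom emulates a murine short-axis echo acquisition: default 6 slices
at 1.0 mm spacing, 35 frames per cycle, 96 angular segments, 1.5 mm basal
end-diastolic endocardial radius with a linear 8 %/slice apical taper, 1 mm
end-diastolic wall. Each segment's radius follows
`r(θ, t) = R_slice − A(θ)·s(t) + ε` with a shared raised-cosine waveform
`s(t)` peaking at end-systolic fraction 0.4; positive amplitudes (default
+0.4 mm) contract inward, a configurable contiguous sector gets a negative
(outward) amplitude, and the wall over that sector can be thinned (e.g. to
0.4 mm) to model the infarct zone.

* **Why the waveform does not matter for the oracle:** with a shared `s(t)`
  and no noise, `eff(t) = |ΣA|/Σ|A|` at every moving frame, so
  `DI = |ΣA|/Σ|A|` independent of the waveform's shape — the closed form
  every pipeline stage is tested against (to 1e-12 on displacement fields,
  1e-3 through full contour geometry, where the residual is polygon-chord
  discretisation).
* **Noise model.** Radial noise is drawn per (frame, segment) and shared by
  a segment's vertices — the granularity at which a speckle tracker jitters —
  so noisy contours stay locally smooth and the displacement-table and
  contour routes have the same noise semantics. The epicardium rides at
  exactly the generative thickness above the (noisy) endocardium, keeping
  the thickness map exact ground truth.
* **Cohorts.** Between-animal variability is additive per-segment amplitude
  jitter (default SD 0.05 mm), drawn once per animal and, in the pipeline,
  held across timepoints so each synthetic animal is a consistent
  individual. All randomness is threaded through explicit seeds
  (`numpy.random.SeedSequence` spawning); regeneration is bit-identical.
* **Defaults as study conditions.** The demo/acceptance cohorts use n = 9
  control vs n = 6 treated, amplitudes ±0.4 mm with 14 vs 4 dyskinetic
  segments of 96 — closed-form group DI 0.708 vs 0.917, matching the
  0.71/0.91 regime the cohort-separation checks target — with 0.02 mm
  tracking noise.

**What the phantom does not model:** B-mode image formation, speckle
statistics, out-of-plane motion, translation/rotation of the heart,
papillary muscles, non-star-shaped remodeling, or frame-time jitter.
Passing tests establish that the estimators are correct for star-shaped
contour data with radial noise; they do not validate the upstream tracing or
tracking of real images.

## Numerical and scale choices

* Tolerances: zero-motion denominator threshold 1e-9 mm; ray-cast
  degeneracy guard 1e-12; oracle agreement asserted at 1e-12
  (displacement route) and 1e-3 mm / 0.5 % (geometry route).
* Contours are normalised to CCW on load; areas are orientation-invariant.
* Phantom contours use 8 vertices per segment (768 per contour), keeping
  chord-vs-arc area error ≈ 1e-5 relative — far inside the 0.5 % volume
  tolerance.
* Simulation sizes in the test and acceptance suites (1,000 random fields;
  50 recovery replicates; 100 cohort repetitions; 200 null ANOVA datasets)
  were chosen to bound the Monte-Carlo error of each check well below its
  acceptance margin while keeping the whole suite fast to run.

## Known limitations

* The displacement-table CSV dialect is this package's own (the proprietary
  instrument export schema is not public); readers convert µm tables and
  validate grid completeness, but other vendors' layouts need adapting.
* The mixed ANOVA requires complete within-subject data after the
  complete-case drop; unbalanced *group* sizes are supported, missing
  *timepoints* are not modelled (no mixed-effects likelihood).
* Star-shapedness is required, not repaired: severely remodeled ventricles
  with re-entrant contours are rejected explicitly.
* DI's small noise-induced downward bias at very low motion-to-noise ratios
  (see above) is inherent to the definition.
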
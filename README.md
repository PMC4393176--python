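# lvmotion

Quantification of regional left-ventricular (LV) wall motion, chamber
volumes, and wall thinning from short-axis contour cines — the measurement
chain used to assess early infarct-zone dyskinesia and post-infarct LV
remodeling in small-animal (mouse) echocardiography.

After a myocardial infarction the infarct zone is structurally weakened and
can bulge *outward* under systolic pressure while healthy myocardium
contracts inward (early dyskinesia). `lvmotion` quantifies this from the
data a high-frequency ultrasound study actually produces: traced endocardial
(and epicardial) contours per short-axis slice per frame, or the per-segment
radial-displacement tables a speckle tracker exports.

It is intended for researchers analysing rodent echo studies, and for anyone
who needs a tested, self-contained reference implementation of the
dyskinesia index with exact synthetic ground truth.

## What it computes

**Dyskinesia index (DI).** With `d_i(t)` the mean radial displacement of
angular segment `i` at time `t` (inward positive, `M` segments, default 96),
the displacement efficiency at each time point and its cycle average are

    eff(t) = |Σ_i d_i(t)| / Σ_i |d_i(t)| ,        DI = mean_t eff(t) ,

taken over the frames with nonzero total motion. `DI ∈ [0, 1]`: unity is
completely polar (coherent) motion, and smaller values indicate increasing
dyskinesis. Time points where the denominator vanishes (always including the
reference frame) are excluded rather than imputed.

**Volumetrics.** Per slice, end-diastole/end-systole are the max/min
endocardial-area frames (detected per slice, not globally); volumes follow by
disc summation `V = Σ A·h` over the apex-to-base stack, with
`EF = 100·(LVEDV − LVESV)/LVEDV` and `SV = LVEDV − LVESV`, in µL.
Longitudinal volumes can be expressed as fold changes vs each animal's
baseline.

**Wall thinning.** From paired endo/epi traces at end-diastole, thickness is
measured along the local outward normal; the thinning extent is the
arc-length percentage of wall at or below 0.5 mm (inclusive; normal mouse
end-diastolic wall ≈ 1 mm).

**Cohort statistics.** Mean ± SEM summaries, two-tailed unpaired (pooled
variance) Student's t-tests, and a two-way mixed-design repeated-measures
ANOVA (between: group; within: time) with Bonferroni per-timepoint post
tests.

**Motion phantom.** A synthetic mouse-LV generator (star-shaped contour
stacks with a configurable dyskinetic sector, shared raised-cosine systolic
waveform, seeded radial noise) with closed-form oracles: for the noiseless
phantom, `DI = |Σ A_i| / Σ |A_i|` exactly, and disc-sum volumes have an
analytic form — so the whole chain is testable without any data download.

## Worked example

```python
import numpy as np
from lvmotion import (MotionParams, dyskinetic_amplitudes, simulate_cine_stack,
                      segment_radial_displacements, dyskinesia_index, analytic_di,
                      lv_volumes, thickness_profile, thinning_extent)

# a mouse LV with a dyskinetic quarter: 24 of 96 segments bulge 0.3 mm
# outward while the rest contract 0.4 mm inward; infarct wall thinned to 0.4 mm
params = MotionParams(
    amplitudes=dyskinetic_amplitudes(96, n_dyskinetic=24, healthy=0.4, dyskinetic=-0.3),
    wall_thickness_dyskinetic=0.4,
)
stack = simulate_cine_stack(params)

sl = stack.slices[2]                      # the plane 2 mm above the apex
field = segment_radial_displacements(sl.endo, n_segments=96,
                                     frame_times=stack.frame_times)
res = dyskinesia_index(field)
print(f"DI = {res.di:.4f}   (closed form: {analytic_di(params):.4f})")

vol = lv_volumes(stack)
print(f"LVEDV = {vol.lvedv:.1f} uL   LVESV = {vol.lvesv:.1f} uL   "
      f"EF = {vol.ef:.1f} %   SV = {vol.sv:.1f} uL")

ed = 0                                    # phantom end-diastole is frame 0
prof = thickness_profile(sl.endo[ed], sl.epi[ed], n_samples=96)
print(f"wall thinning extent (<= 0.5 mm) = {thinning_extent(prof):.1f} % of wall")
```

prints

```
DI = 0.6000   (closed form: 0.6000)
LVEDV = 27.9 uL   LVESV = 20.4 uL   EF = 26.9 %   SV = 7.5 uL
wall thinning extent (<= 0.5 mm) = 25.0 % of wall
```

The measured DI matches the closed form `(72·0.4 − 24·0.3)/(72·0.4 + 24·0.3)
= 0.6` because all segments share the systolic waveform; the thinning extent
is the dyskinetic quarter of the wall (24/96 = 25 %).

The same stages are exposed as a CLI (`lvmotion simulate | displace | di |
volumes | thinning | stats | run`); `lvmotion run --out report/` executes the
packaged two-cohort demo study (9 control vs 6 treated animals across five
timepoints) and writes per-animal metrics, group summaries, t-tests, ANOVA
tables and a run manifest.

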
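# Demo study: two simulated cohorts mirroring a mouse reperfused-MI protocol.
# Control animals (n=9) develop a wide dyskinetic (outward-bulging) sector with
# infarct-zone wall thinning on day 2; treated animals (n=6) are protected
# (narrow dyskinetic sector, wall above the 0.5 mm thinning threshold).
mode: phantom
seed: 20150329
timepoints: [baseline, d2, d7, d14, d28]
acquisition:
  n_segments: 96
  n_frames: 35
  n_slices: 6
  slice_spacing_mm: 1.0
  base_radius_mm: 1.5
  wall_thickness_ed_mm: 1.0
  apex_taper: 0.08
  noise_sd_mm: 0.02
analysis:
  di_timepoint: d2
  di_slice_height_mm: 2.0
  thinning_timepoints: [d2, d28]
  thinning_threshold_mm: 0.5
  normalize_to_baseline: [lvedv, lvesv, sv]
  rm_anova_metrics: [rel_lvesv, rel_lvedv, rel_sv, ef]
  rm_anova_timepoints: [d2, d7, d14, d28]
groups:
  - name: control
    n: 9
    healthy_amplitude_mm: 0.4
    dyskinetic_amplitude_mm: -0.4
    dyskinetic_wall_thickness_mm: 0.4
    amplitude_jitter_sd_mm: 0.05
    dyskinetic_segments: {baseline: 0, d2: 14, d7: 14, d14: 13, d28: 12}
  - name: treated
    n: 6
    healthy_amplitude_mm: 0.4
    dyskinetic_amplitude_mm: -0.4
    dyskinetic_wall_thickness_mm: 0.6
    amplitude_jitter_sd_mm: 0.05
    dyskinetic_segments: {baseline: 0, d2: 4, d7: 4, d14: 3, d28: 3}
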
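"""Phantom generator: structure, reproducibility, and closed-form oracles."""

import numpy as np
import pytest

from lvmotion import (
    MotionParams,
    GroupSpec,
    analytic_di,
    dyskinetic_amplitudes,
    dyskinesia_index,
    simulate_cine_stack,
    simulate_cohort,
    simulate_displacement_cohort,
    simulate_displacement_field,
    systolic_waveform,
)


class TestWaveform:
    def test_anchors_and_range(self):
        t = np.linspace(0, 0.999, 500)
        s = systolic_waveform(t, es_fraction=0.4)
        assert systolic_waveform(0.0) == 0.0
        assert systolic_waveform(0.4) == pytest.approx(1.0)
        assert np.all((s >= 0) & (s <= 1))

    def test_monotone_rise_to_end_systole(self):
        t = np.linspace(0, 0.4, 100)
        assert np.all(np.diff(systolic_waveform(t)) >= 0)


class TestMotionParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_segments": 1},
            {"n_frames": 2},
            {"base_radius": 0.0},
            {"wall_thickness_ed": -1.0},
            {"noise_sd": -0.1},
            {"amplitudes": np.full(96, 1.6)},  # |a| >= base_radius
            {"amplitudes": np.zeros(10)},  # wrong length
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            MotionParams(**kwargs)


class TestDisplacementField:
    def test_uniform_inward_field_is_waveform_scaled_and_fully_polar(self):
        p = MotionParams(amplitudes=np.full(96, 0.4))
        f = simulate_displacement_field(p)
        s = systolic_waveform(p.frame_times)
        assert np.allclose(f.d, 0.4 * s[None, :])
        assert dyskinesia_index(f).di == 1.0

    def test_72_24_split_gives_di_half(self):
        p = MotionParams(amplitudes=dyskinetic_amplitudes(96, 24, 1.0, -1.0))
        di = dyskinesia_index(simulate_displacement_field(p)).di
        assert di == pytest.approx(0.5, abs=1e-12)

    def test_same_seed_reproduces_noise_exactly(self):
        p = MotionParams(noise_sd=0.05, seed=42)
        f1 = simulate_displacement_field(p)
        f2 = simulate_displacement_field(p)
        assert np.array_equal(f1.d, f2.d)
        f3 = simulate_displacement_field(MotionParams(noise_sd=0.05, seed=43))
        assert not np.array_equal(f1.d, f3.d)

    def test_reference_frame_stays_zero_under_noise(self):
        f = simulate_displacement_field(MotionParams(noise_sd=0.1, seed=1))
        assert np.all(f.d[:, 0] == 0.0)


class TestAnalyticDI:
    @pytest.mark.parametrize(
        "amplitudes, expected",
        [
            (np.full(96, 0.4), 1.0),
            (dyskinetic_amplitudes(96, 48, 1.0, -1.0), 0.0),
            (dyskinetic_amplitudes(96, 24, 1.0, -1.0), 0.5),
            (dyskinetic_amplitudes(96, 24, 0.4, -0.3), (72 * 0.4 - 24 * 0.3) / (72 * 0.4 + 24 * 0.3)),
        ],
    )
    def test_closed_form(self, amplitudes, expected):
        assert analytic_di(MotionParams(amplitudes=amplitudes)) == pytest.approx(
            expected, abs=1e-15
        )

    def test_undefined_for_zero_motion_or_noise(self):
        with pytest.raises(ValueError):
            analytic_di(MotionParams(amplitudes=np.zeros(96)))
        with pytest.raises(ValueError):
            analytic_di(MotionParams(noise_sd=0.1))


class TestCineStack:
    def test_structure_and_polygon_contracts(self):
        stack = simulate_cine_stack(MotionParams(n_slices=6, n_frames=35))
        stack.validate()  # simple, CCW, >= 8 vertices, shared frame count
        assert stack.n_slices == 6
        assert stack.n_frames == 35

    def test_uniform_contraction_slice_area_at_peak_systole(self):
        # base_radius 1.5, amplitude 0.4 -> radius 1.1 at s(t)=1
        p = MotionParams(amplitudes=np.full(96, 0.4), apex_taper=0.0, n_slices=1)
        stack = simulate_cine_stack(p)
        es_frame = int(np.argmax(systolic_waveform(p.frame_times)))
        from lvmotion import contour_area

        area = contour_area(stack.slices[0].endo[es_frame])
        assert area == pytest.approx(np.pi * 1.1**2, rel=1e-4)

    def test_dyskinetic_sector_bulges_outward_at_peak(self):
        p = MotionParams(
            amplitudes=dyskinetic_amplitudes(96, 24, 0.4, -0.3), apex_taper=0.0, n_slices=1
        )
        stack = simulate_cine_stack(p)
        es_frame = int(np.argmax(systolic_waveform(p.frame_times)))
        radii = np.hypot(*stack.slices[0].endo[es_frame].T)
        assert radii.max() == pytest.approx(1.8, abs=1e-12)

    def test_negative_radius_rejected(self):
        p = MotionParams(amplitudes=np.full(96, 1.4), apex_taper=0.4)
        with pytest.raises(ValueError, match="radius"):
            simulate_cine_stack(p)


class TestCohort:
    def _specs(self, jitter=0.05):
        return [
            GroupSpec("control", MotionParams(amplitudes=dyskinetic_amplitudes(96, 14, 0.4, -0.4), n_slices=2, n_frames=10), jitter),
            GroupSpec("treated", MotionParams(amplitudes=dyskinetic_amplitudes(96, 4, 0.4, -0.4), n_slices=2, n_frames=10), jitter),
        ]

    def test_labelled_structure(self):
        cohort = simulate_cohort(self._specs(), [3, 2], seed=7)
        assert [a.group for a in cohort] == ["control"] * 3 + ["treated"] * 2
        assert all(a.stack.n_slices == 2 for a in cohort)
        assert all(a.params.amplitudes.shape == (96,) for a in cohort)

    def test_seeded_regeneration_is_identical(self):
        c1 = simulate_cohort(self._specs(), [2, 2], seed=11)
        c2 = simulate_cohort(self._specs(), [2, 2], seed=11)
        for a1, a2 in zip(c1, c2):
            assert np.array_equal(a1.params.amplitudes, a2.params.amplitudes)
            assert np.array_equal(a1.stack.slices[0].endo[3], a2.stack.slices[0].endo[3])

    def test_zero_jitter_makes_animals_identical_within_group(self):
        cohort = simulate_displacement_cohort(self._specs(jitter=0.0), [3, 2], seed=5)
        a, b = cohort[0], cohort[1]
        assert np.array_equal(a.params.amplitudes, b.params.amplitudes)

    def test_rejects_single_animal_groups(self):
        with pytest.raises(ValueError, match="n >= 2"):
            simulate_cohort(self._specs(), [1, 3], seed=0)
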
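"""Fraction pipeline: registration, truncation correction, ΔWEPL, course runs."""

import math

import numpy as np
import pytest

from weplrange.fraction import (CourseOptions, FractionRecord, PipelineError,
                                RangeErrorSample, ScanningCircle,
                                apply_rigid_shift, fraction_range_error,
                                run_course, summarize_fraction,
                                truncation_correct)
from weplrange.raytrace import BeamGeometry, SPImage, wepl_map


def _sample(deltas, **kw):
    defaults = dict(patient_id="p", fraction_index=2, gantry_angle=0.0)
    defaults.update(kw)
    return RangeErrorSample(delta_wepl=np.asarray(deltas, float), **defaults)


class TestApplyRigidShift:
    def test_zero_transform_is_identity(self, water_image):
        assert apply_rigid_shift(water_image, (0.0, 0.0)) is water_image

    def test_whole_pixel_shift_is_integer_roll(self, rng):
        values = rng.uniform(0.0, 2.0, size=(20, 20))
        image = SPImage(values=values)
        # +1 mm in x = one column toward patient left; edge refills with 0
        shifted = apply_rigid_shift(image, (1.0, 0.0))
        expected = np.zeros_like(values)
        expected[:, 1:] = values[:, :-1]
        assert np.allclose(shifted.values, expected, atol=1e-12)

    def test_half_pixel_shift_of_linear_ramp(self):
        img0 = SPImage(values=np.zeros((20, 20)))
        X, _ = img0.pixel_centers()
        image = SPImage(values=X + 20.0)  # linear in x, positive
        shifted = apply_rigid_shift(image, (0.5, 0.0))
        # interior pixels: ramp evaluated at x - 0.5
        assert np.allclose(shifted.values[5:15, 5:15],
                           X[5:15, 5:15] - 0.5 + 20.0, atol=1e-9)

    def test_quarter_turn_about_center_permutes_grid(self, rng):
        values = rng.uniform(0.0, 2.0, size=(21, 21))
        image = SPImage(values=values)
        rotated = apply_rigid_shift(image, (0.0, 0.0), rotation=90.0)
        # +90 deg counter-clockwise in x-y: rotated[r, c] = values[c, N-1-r]
        assert np.allclose(rotated.values, np.rot90(values, k=1), atol=1e-9)

    def test_non_finite_shift_rejected(self, water_image):
        with pytest.raises(PipelineError):
            apply_rigid_shift(water_image, (float("nan"), 0.0))


class TestTruncationCorrect:
    def test_everything_inside_circle_unchanged(self, rng):
        image = SPImage(values=rng.uniform(0.0, 2.0, size=(20, 20)))
        circle = ScanningCircle(diameter=1000.0)
        body = np.ones((20, 20), bool)
        out = truncation_correct(image, circle, body)
        assert np.array_equal(out.values, image.values)

    def test_three_way_rule_brute_force(self, rng):
        image = SPImage(values=rng.uniform(0.1, 2.0, size=(30, 30)))
        circle = ScanningCircle(center=(0.0, 0.0), diameter=20.0)
        body = (np.indices((30, 30)).sum(axis=0) % 2).astype(bool)
        fill = 1.0
        out = truncation_correct(image, circle, body, fill_sp=fill)
        X, Y = image.pixel_centers()
        inside = X ** 2 + Y ** 2 <= 10.0 ** 2
        for r in range(30):
            for c in range(30):
                if inside[r, c]:
                    assert out.values[r, c] == image.values[r, c]
                elif body[r, c]:
                    assert out.values[r, c] == fill
                else:
                    assert out.values[r, c] == 0.0

    def test_mask_grid_mismatch_rejected(self, water_image):
        with pytest.raises(PipelineError):
            truncation_correct(water_image, ScanningCircle(),
                               np.ones((3, 3), bool))


class TestFractionRangeError:
    def test_identical_maps_give_zero(self, water_image, anterior_parallel):
        mask = np.zeros(water_image.shape, bool)
        mask[30:40, 10:30] = True
        ref = wepl_map(water_image, mask, anterior_parallel)
        sample = fraction_range_error(ref, ref, mask)
        assert np.all(sample.delta_wepl == 0.0)
        assert sample.n_pixels == mask.sum()

    def test_upstream_slab_shifts_every_pixel(self, water_image,
                                              anterior_parallel):
        mask = np.zeros(water_image.shape, bool)
        mask[40:50, 10:30] = True
        values = water_image.values.copy()
        values[5:15, :] += 0.5  # 10 mm slab of SP excess +0.5
        frac = SPImage(values=values)
        ref_map = wepl_map(water_image, mask, anterior_parallel)
        frac_map = wepl_map(frac, mask, anterior_parallel)
        sample = fraction_range_error(ref_map, frac_map, mask)
        assert np.allclose(sample.delta_wepl, 5.0, atol=1e-9)

    def test_grid_mismatch_rejected(self, water_image, anterior_parallel):
        mask = np.ones(water_image.shape, bool)
        ref = wepl_map(water_image, mask, anterior_parallel)
        other = wepl_map(SPImage(values=np.ones((10, 10))),
                         np.ones((10, 10), bool), anterior_parallel)
        with pytest.raises(PipelineError):
            fraction_range_error(ref, other, mask)


class TestSummarizeFraction:
    def test_degenerate_all_zero(self):
        s = summarize_fraction(_sample([0.0, 0.0, 0.0, 0.0]), bin_width=1.0)
        assert s.mean == 0.0 and s.sd == 0.0
        assert s.percent_volume.sum() == pytest.approx(100.0)
        assert (s.percent_volume == 100.0).sum() == 1

    def test_hand_arithmetic(self):
        s = summarize_fraction(_sample([1.0, 2.0, 3.0]))
        assert s.mean == pytest.approx(2.0)
        assert s.sd == pytest.approx(1.0)

    def test_single_pixel_sd_undefined_mean_kept(self):
        s = summarize_fraction(_sample([3.5]))
        assert s.mean == pytest.approx(3.5)
        assert math.isnan(s.sd)

    def test_monte_carlo_normal_recovery(self, rng):
        draws = rng.normal(-1.5, 2.5, size=10_000)
        s = summarize_fraction(_sample(draws))
        assert s.mean == pytest.approx(-1.5, abs=4 * 2.5 / 100.0)
        assert s.sd == pytest.approx(2.5, abs=4 * 2.5 / math.sqrt(2e4))

    @pytest.mark.parametrize("bin_width", [0.25, 1.0, 3.7])
    def test_histogram_mass_conserved(self, rng, bin_width):
        s = summarize_fraction(_sample(rng.normal(0, 5, size=500)),
                               bin_width=bin_width)
        assert s.percent_volume.sum() == pytest.approx(100.0, abs=1e-6)
        assert np.allclose(np.diff(s.bin_edges), bin_width)

    def test_invalid_bin_width(self):
        with pytest.raises(PipelineError):
            summarize_fraction(_sample([1.0]), bin_width=0.0)


def _phantom_course(n=48, m=40):
    """Water block with a CTV rectangle, usable for tiny course runs."""
    values = np.ones((n, m))
    ctv = np.zeros((1, n, m), bool)
    ctv[0, 30:38, 12:28] = True
    body = np.ones((1, n, m), bool)
    return values, ctv, body


class TestRunCourse:
    def test_identical_fractions_all_zero(self):
        values, ctv, body = _phantom_course()
        ref = FractionRecord(1, values[None], is_sp=True)
        fracs = [FractionRecord(k, values[None], is_sp=True)
                 for k in (2, 3, 4)]
        beams = [BeamGeometry(0.0, None), BeamGeometry(90.0, None)]
        samples, summaries = run_course(ref, fracs, ctv, body, beams)
        assert len(summaries) == 6
        for s in summaries:
            assert s.mean == 0.0 and s.sd == 0.0

    def test_reference_self_comparison_exact_zero(self):
        values, ctv, body = _phantom_course()
        ref = FractionRecord(1, values[None], is_sp=True)
        samples, _ = run_course(ref, [ref], ctv, body,
                                [BeamGeometry(0.0, None)])
        assert np.all(samples[0].delta_wepl == 0.0)

    def test_recorded_shift_corrects_displacement(self, rng):
        """A fraction that is the reference displaced by a couch error,
        registered back with the recorded correction, has ~zero mean."""
        values = np.zeros((48, 40))
        values[4:46, 4:36] = 1.0        # water body surrounded by air
        values[10:14, 4:36] = 1.4       # structure so the shift matters
        ctv = np.zeros((1, 48, 40), bool)
        ctv[0, 30:38, 12:28] = True
        image = SPImage(values=values)
        displaced = apply_rigid_shift(image, (-0.3, -0.6))
        ref = FractionRecord(1, values[None], is_sp=True)
        frac = FractionRecord(2, displaced.values[None], is_sp=True,
                              shift=(0.3, 0.6))
        _, summaries = run_course(ref, [frac], ctv, None,
                                  [BeamGeometry(0.0, None)])
        assert abs(summaries[0].mean) < 0.1

    def test_upstream_slab_linearity(self):
        """Adding Δs over a t-mm upstream slab moves every delta by t·Δs."""
        values, ctv, body = _phantom_course()
        perturbed = values.copy()
        perturbed[5:15, :] += 0.25
        ref = FractionRecord(1, values[None], is_sp=True)
        frac = FractionRecord(2, perturbed[None], is_sp=True)
        samples, _ = run_course(ref, [frac], ctv, body,
                                [BeamGeometry(0.0, None)])
        assert np.allclose(samples[0].delta_wepl, 10 * 0.25, atol=1e-9)

    def test_unusable_fraction_skipped(self):
        values, ctv, body = _phantom_course()
        ref = FractionRecord(1, values[None], is_sp=True)
        fracs = [FractionRecord(2, values[None], is_sp=True, usable=False),
                 FractionRecord(3, values[None], is_sp=True)]
        _, summaries = run_course(ref, fracs, ctv, body,
                                  [BeamGeometry(0.0, None)])
        assert [s.fraction_index for s in summaries] == [3]

    def test_no_usable_fractions_raises(self):
        values, ctv, body = _phantom_course()
        ref = FractionRecord(1, values[None], is_sp=True)
        with pytest.raises(PipelineError):
            run_course(ref, [FractionRecord(2, values[None], is_sp=True,
                                            usable=False)],
                       ctv, body, [BeamGeometry(0.0, None)])

    def test_excluded_slice_does_not_change_other_slices(self, rng):
        base = rng.uniform(0.5, 1.5, size=(3, 30, 30))
        ctv = np.zeros((3, 30, 30), bool)
        ctv[:, 20:26, 10:20] = True
        other = rng.uniform(0.5, 1.5, size=(3, 30, 30))
        beams = [BeamGeometry(0.0, None)]

        def deltas(excluded):
            ref = FractionRecord(1, base, is_sp=True,
                                 excluded_slices=excluded)
            frac = FractionRecord(2, other, is_sp=True,
                                  excluded_slices=excluded)
            samples, _ = run_course(ref, [frac], ctv, None, beams)
            return samples[0].delta_wepl

    # slice 1 excluded: remaining deltas equal those slices' deltas
        full = deltas(())
        partial = deltas((1,))
        per_slice = ctv[0].sum()
        expected = np.concatenate([full[:per_slice], full[2 * per_slice:]])
        assert np.array_equal(partial, expected)

    def test_hu_input_goes_through_calibration(self, default_table):
        hu = np.full((40, 30), 9.5)  # water HU on the default curve
        ctv = np.zeros((1, 40, 30), bool)
        ctv[0, 25:30, 10:20] = True
        ref = FractionRecord(1, hu[None])
        frac = FractionRecord(2, hu[None])
        samples, _ = run_course(ref, [frac], ctv, None,
                                [BeamGeometry(0.0, None)],
                                calibration=default_table)
        assert np.all(samples[0].delta_wepl == 0.0)

    def test_hu_input_without_calibration_rejected(self):
        hu = np.full((10, 10), 0.0)
        ctv = np.zeros((1, 10, 10), bool)
        ctv[0, 5, 5] = True
        with pytest.raises(PipelineError):
            run_course(FractionRecord(1, hu[None]),
                       [FractionRecord(2, hu[None])], ctv, None,
                       [BeamGeometry(0.0, None)])
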
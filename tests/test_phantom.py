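"""Synthetic cohort generator: ground truth, forward signal, rater masks."""

import numpy as np
import pytest

from subqmri.phantom import (
    GROUP_AGE_RANGES,
    MultiEchoSeries,
    PhantomSpec,
    StructureDef,
    build_phantom,
    default_spec,
    generate_cohort,
    perturb_rater_masks,
    simulate_signal,
)
from subqmri.spatial import center_of_mass

from conftest import quiet_spec


class TestSeriesInvariants:
    def test_echo_count_mismatch(self):
        with pytest.raises(ValueError, match="number of magnitude volumes"):
            MultiEchoSeries((10.0, 20.0), np.ones((2, 2, 2, 3)), None)

    def test_phase_shape_mismatch(self):
        with pytest.raises(ValueError, match="identical shapes"):
            MultiEchoSeries(
                (10.0, 20.0), np.ones((2, 2, 2, 2)), np.ones((2, 2, 2, 3))
            )

    def test_non_increasing_echoes(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            MultiEchoSeries((20.0, 10.0), np.ones((2, 2, 2, 2)), None)

    def test_negative_magnitude(self):
        with pytest.raises(ValueError, match="non-negative"):
            MultiEchoSeries((10.0, 20.0), -np.ones((2, 2, 2, 2)), None)


class TestBuildPhantom:
    def test_identity_case_com_equals_catalog_center(self):
        """At age 20 with drift and jitter off, CoMs sit at the catalog centers."""
        spec = quiet_spec()
        rec = build_phantom(spec, 20.0, 0)
        template = rec.to_template @ rec.affine
        half_voxel = spec.voxel_size_mm / 2.0
        for s in spec.structures:
            if s.is_csf and s.name != "LV":
                continue  # midline CSF tubes are carved by each other
            com = center_of_mass(rec.truth_masks[(s.name, s.hemisphere)], template)
            err = np.abs(np.asarray(com.xyz_mm) - np.asarray(s.center_mm))
            assert err.max() < half_voxel, (s.name, s.hemisphere, err)

    def test_deterministic_given_seed(self):
        spec = default_spec(seed=0)
        a = build_phantom(spec, 47.3, 555)
        b = build_phantom(spec, 47.3, 555)
        np.testing.assert_array_equal(a.t2s_map, b.t2s_map)
        np.testing.assert_array_equal(a.chi_map, b.chi_map)
        for key in a.truth_masks:
            np.testing.assert_array_equal(a.truth_masks[key], b.truth_masks[key])
            np.testing.assert_array_equal(
                a.rater_masks[key][0], b.rater_masks[key][0]
            )

    def test_age_out_of_range(self):
        with pytest.raises(ValueError, match="age"):
            build_phantom(default_spec(), 95.0, 0)

    def test_colliding_structures_error_names_pair(self):
        spec = quiet_spec()
        spec.structures = [
            StructureDef("A", "midline", (0.0, 0.0, 0.0), (6.0, 6.0, 6.0)),
            StructureDef("B", "midline", (4.0, 0.0, 0.0), (6.0, 6.0, 6.0)),
        ]
        with pytest.raises(ValueError, match="A.*B|B.*A"):
            build_phantom(spec, 25.0, 0)

    def test_ventricles_grow_with_age(self):
        spec = quiet_spec()
        young = build_phantom(spec, 20.0, 0)
        old = build_phantom(spec, 75.0, 0)
        assert old.ventricle_volume_mm3 > young.ventricle_volume_mm3

    def test_com_drift_moves_structure(self):
        spec = quiet_spec()
        young = build_phantom(spec, 20.0, 0)
        old = build_phantom(spec, 75.0, 0)
        tpl = np.asarray(young.to_template @ young.affine)
        com_y = center_of_mass(young.truth_masks[("STR", "right")], tpl)
        com_o = center_of_mass(old.truth_masks[("STR", "right")], tpl)
        # default drift: 0.017 mm/y upward -> ~0.94 mm over 55 years
        assert com_o.xyz_mm[2] - com_y.xyz_mm[2] == pytest.approx(0.94, abs=0.5)


class TestSimulateSignal:
    def _flat_spec(self, te=(10.0, 20.0)):
        return PhantomSpec(
            shape=(12, 12, 12),
            voxel_size_mm=2.0,
            structures=[],
            background_t2s_ms=20.0,
            background_chi_ppm=0.0,
            s0=100.0,
            echo_times_ms=te,
            noise_sd=0.0,
            background_field_coeffs=(0.0,) * 7,
            brain_semi_axes_mm=(10.0, 10.0, 10.0),
        )

    def test_magnitude_closed_form(self):
        """T2* = 20 ms, S0 = 100, TE 10/20 ms -> 100 e^-1/2, 100 e^-1."""
        spec = self._flat_spec()
        rec = build_phantom(spec, 25.0, 0)
        series = simulate_signal(rec, spec)
        c = (6, 6, 6)
        assert series.magnitude[c][0] == pytest.approx(100 * np.exp(-0.5), rel=1e-5)
        assert series.magnitude[c][1] == pytest.approx(100 * np.exp(-1.0), rel=1e-5)

    def test_zero_susceptibility_zero_background_gives_zero_phase(self):
        spec = self._flat_spec()
        rec = build_phantom(spec, 25.0, 0)
        series = simulate_signal(rec, spec)
        assert np.abs(series.phase).max() < 1e-5

    def test_nonpositive_t2star_errors(self):
        spec = self._flat_spec()
        rec = build_phantom(spec, 25.0, 0)
        rec.t2s_map[rec.brain_mask] = 0.0
        with pytest.raises(ValueError, match="positive"):
            simulate_signal(rec, spec)

    def test_phase_wrapped_range(self):
        spec = default_spec(seed=2)
        rec = build_phantom(spec, 30.0, 2)
        series = simulate_signal(rec, spec)
        assert series.phase.max() <= np.pi + 1e-6
        assert series.phase.min() > -np.pi - 1e-6

    def test_noise_deterministic_given_seed(self):
        spec = default_spec(seed=2)
        rec = build_phantom(spec, 30.0, 7)
        s1 = simulate_signal(rec, spec)
        s2 = simulate_signal(rec, spec)
        np.testing.assert_array_equal(s1.magnitude, s2.magnitude)


class TestRaterMasks:
    def _cube(self, n=5, grid=11):
        m = np.zeros((grid, grid, grid), bool)
        lo = (grid - n) // 2
        m[lo : lo + n, lo : lo + n, lo : lo + n] = True
        return m

    def test_zero_probability_reproduces_truth(self):
        truth = self._cube()
        r1, r2 = perturb_rater_masks(truth, (0.0, 0.0), 3)
        np.testing.assert_array_equal(r1, truth)
        np.testing.assert_array_equal(r2, truth)

    def test_seeds_give_different_masks(self):
        truth = self._cube()
        a1, _ = perturb_rater_masks(truth, (0.3, 0.3), 1)
        b1, _ = perturb_rater_masks(truth, (0.3, 0.3), 2)
        assert (a1 != b1).any()

    def test_full_flip_matches_enumeration_on_cube(self):
        """p = 1 on a 5^3 cube: every boundary voxel flips, so the rater mask
        is exactly (core 3^3) + (6-connected outer shell, 6 faces of 5^2),
        giving dice(rater, truth) = 2*27 / (177 + 125)."""
        from subqmri.segmentation import dice

        truth = self._cube()
        r1, r2 = perturb_rater_masks(truth, (1.0, 1.0), 0)
        np.testing.assert_array_equal(r1, r2)  # deterministic at p = 1
        assert int(r1.sum()) == 27 + 6 * 25
        assert dice(r1, truth) == pytest.approx(2 * 27 / (177 + 125))

    def test_changes_confined_to_boundary(self):
        from scipy import ndimage

        truth = self._cube(7, 15)
        r1, _ = perturb_rater_masks(truth, (0.5, 0.5), 9)
        core = ndimage.binary_erosion(truth)
        halo = ndimage.binary_dilation(truth)
        assert (r1 & core).sum() == core.sum()  # interior untouched
        assert not (r1 & ~halo).any()  # nothing beyond one-voxel dilation

    def test_empty_result_errors(self):
        truth = np.ones((1, 1, 1), bool)
        with pytest.raises(ValueError, match="emptied"):
            perturb_rater_masks(truth, (1.0, 1.0), 0)

    def test_empty_truth_errors(self):
        with pytest.raises(ValueError, match="empty"):
            perturb_rater_masks(np.zeros((3, 3, 3), bool), (0.1, 0.1), 0)


class TestCohort:
    def test_group_sizes_and_age_ranges(self):
        spec = default_spec(seed=9, group_sizes={"young": 5, "middle": 3, "elderly": 2})
        recs = generate_cohort(spec, simulate=False)
        assert len(recs) == 10
        for rec in recs:
            lo, hi = GROUP_AGE_RANGES[rec.group]
            assert lo <= rec.age <= hi

    def test_cohort_deterministic(self):
        spec = default_spec(seed=9, group_sizes={"young": 2, "middle": 1, "elderly": 1})
        a = generate_cohort(spec, simulate=False)
        b = generate_cohort(spec, simulate=False)
        assert [r.age for r in a] == [r.age for r in b]
        np.testing.assert_array_equal(a[0].t2s_map, b[0].t2s_map)

    def test_ground_truth_age_slope_recovered_by_ols(self):
        """Sample OLS slope of ROI-mean truth T2* vs age within 2 SE of the
        generating slope (striatum, 100 subjects)."""
        spec = default_spec(
            seed=21, group_sizes={"young": 40, "middle": 30, "elderly": 30}
        )
        recs = generate_cohort(spec, simulate=False)
        ages = np.array([r.age for r in recs])
        means = np.array(
            [r.t2s_map[r.truth_masks[("STR", "right")]].mean() for r in recs]
        )
        design = np.column_stack([np.ones(len(ages)), ages])
        coef, res_ss, *_ = np.linalg.lstsq(design, means, rcond=None)
        resid = means - design @ coef
        s2 = resid @ resid / (len(ages) - 2)
        se = np.sqrt(s2 / ((ages - ages.mean()) ** 2).sum())
        true_slope = (22.70 - 27.97) / (69.6 - 23.8)
        assert abs(coef[1] - true_slope) < 2 * se
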
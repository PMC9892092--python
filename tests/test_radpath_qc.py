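import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import nephroguide as ng
from nephroguide.radpath_qc import (
    GridError,
    IncompleteReportError,
    RegistrationError,
    match_slices,
)

from conftest import perturb_slice


class TestDice:
    def test_identical_masks(self):
        m = np.zeros((10, 10), bool)
        m[2:7, 3:8] = True
        assert ng.dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        a[0:3, 0:3] = True
        b[6:9, 6:9] = True
        assert ng.dice(a, b) == 0.0

    def test_half_shifted_square(self):
        a = np.zeros((30, 30), bool)
        b = np.zeros((30, 30), bool)
        a[5:15, 5:15] = True
        b[5:15, 10:20] = True
        assert ng.dice(a, b) == 0.5  # overlap 50 of (100+100)

    def test_both_empty_is_vacuous_agreement(self):
        assert ng.dice(np.zeros((5, 5), bool), np.zeros((5, 5), bool)) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(GridError):
            ng.dice(np.zeros((5, 5), bool), np.zeros((6, 5), bool))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        a=hnp.arrays(bool, (12, 12)),
        b=hnp.arrays(bool, (12, 12)),
    )
    def test_symmetric_and_bounded(self, a, b):
        d = ng.dice(a, b)
        assert 0.0 <= d <= 1.0
        assert d == ng.dice(b, a)
        if a.any() or b.any():
            assert (d == 1.0) == np.array_equal(a, b)


class TestSimilarityTransform:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        s=st.floats(0.5, 2.0),
        th=st.floats(-3.0, 3.0),
        tx=st.floats(-20, 20),
        ty=st.floats(-20, 20),
    )
    def test_inverse_round_trips_points(self, s, th, tx, ty):
        tf = ng.SimilarityTransform2D(s, th, (tx, ty))
        pts = np.array([[0.0, 0.0], [3.5, -2.0], [10.0, 7.0]])
        np.testing.assert_allclose(tf.inverse().apply(tf.apply(pts)), pts, atol=1e-9)

    def test_compose_matches_matrix_product(self):
        t1 = ng.SimilarityTransform2D(1.2, 0.3, (1.0, -2.0))
        t2 = ng.SimilarityTransform2D(0.8, -0.5, (3.0, 4.0))
        pts = np.array([[1.0, 1.0], [-4.0, 2.5]])
        np.testing.assert_allclose(
            t1.compose(t2).apply(pts), t1.apply(t2.apply(pts)), atol=1e-9
        )

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            ng.SimilarityTransform2D(scale=0.0)


class TestEstimateSimilarity:
    def test_self_registration_is_identity(self, tumor_stack_1mm):
        m = max(tumor_stack_1mm, key=lambda x: x.sum())
        tf, d, _ = ng.estimate_similarity(m, m, 1.0)
        assert d == 1.0
        assert tf.scale == pytest.approx(1.0, abs=0.01)
        assert tf.rotation == pytest.approx(0.0, abs=np.deg2rad(1.0))

    def test_known_transform_recovered(self, tumor_stack_1mm):
        m = max(tumor_stack_1mm, key=lambda x: x.sum())
        photo, fwd = perturb_slice(m, 1.2, 30.0, (5.0, -3.0))
        tf, d, _ = ng.estimate_similarity(photo, m, 1.0)
        inv = fwd.inverse()
        assert d >= 0.98
        assert abs(tf.scale - inv.scale) <= 0.02
        assert abs(tf.rotation - inv.rotation) <= np.deg2rad(2.0)
        cp = np.argwhere(photo).mean(axis=0)
        assert np.linalg.norm(tf.apply(cp)[0] - inv.apply(cp)[0]) <= 1.0

    def test_refinement_never_below_moment_initialization(self, tumor_stack_1mm):
        m = max(tumor_stack_1mm, key=lambda x: x.sum())
        photo, _ = perturb_slice(m, 0.9, -20.0, (8.0, 6.0))
        _, d_init, _ = ng.estimate_similarity(photo, m, 1.0, refine=False)
        _, d_ref, _ = ng.estimate_similarity(photo, m, 1.0, refine=True)
        assert d_ref >= d_init

    def test_empty_mask_rejected(self):
        with pytest.raises(RegistrationError):
            ng.estimate_similarity(np.zeros((10, 10), bool), np.ones((10, 10), bool))

    def test_near_circular_mask_flagged_degenerate(self):
        zz, yy = np.mgrid[:60, :60]
        disc = (zz - 30) ** 2 + (yy - 30) ** 2 <= 400
        _, _, degenerate = ng.estimate_similarity(disc, disc, 1.0)
        assert degenerate

    def test_two_lesion_ambiguity_scores_materially_lower(self, tumor_stack_1mm):
        # emulates a tumor of two separate lesions that shift independently
        # on the photograph, so no single similarity transform can match
        # both regions of interest after rescaling
        m = max(tumor_stack_1mm, key=lambda x: x.sum())
        lesion_b = np.roll(m, (40, 45), axis=(0, 1))
        two = m | lesion_b
        photo_a, _ = perturb_slice(m, 1.1, 25.0, (8.0, -5.0))
        photo_b, _ = perturb_slice(lesion_b, 0.95, -15.0, (-6.0, 10.0))
        photo_two = photo_a | photo_b
        _, d_one, _ = ng.estimate_similarity(photo_a, m, 1.0)
        tf_two, d_two, _ = ng.estimate_similarity(photo_two, two, 1.0)
        assert d_two < d_one - 0.1
        assert d_two < 0.9

    def test_dice_degrades_monotonically_with_elastic_deformation(self, phantom_1mm):
        _, truth, _ = phantom_1mm
        frame = ng.slice_frame_from(truth)
        means = []
        for amp in (0.0, 2.0, 4.0, 8.0):
            spec = ng.MacroSimSpec(
                scale_range=(0.95, 1.05),
                rotation_range_deg=(-10, 10),
                translation_max_mm=5.0,
                elastic_amplitude_mm=amp,
                thickness_jitter_sigma_mm=0.0,
                pixel_mm=1.0,
                seed=7,
            )
            sim = ng.simulate_macro_slices(truth, frame, spec)
            ds = [
                ng.estimate_similarity(s.macro_mask, sim.mri_stack[s.slab_indices[0]], 1.0)[1]
                for s in sim.slices
                if sim.mri_stack[s.slab_indices[0]].sum() > 200
            ]
            means.append(float(np.mean(ds)))
        assert all(a > b for a, b in zip(means, means[1:]))


class TestSliceAccounting:
    @pytest.mark.parametrize(
        "pairs,expected",
        [
            ([(5, 5), (5, 5)], (5.0, 0.0)),
            ([(5, 7), (6, 6), (4, 6)], (6.0, 2.0)),
            ([(5, 6)], (5.5, 1.0)),
        ],
    )
    def test_thickness_stats(self, pairs, expected):
        assert ng.slice_thickness_stats(pairs) == pytest.approx(expected)

    def test_nonpositive_measurement_rejected(self):
        with pytest.raises(ValueError):
            ng.slice_thickness_stats([(5.0, -1.0)])

    @pytest.mark.parametrize(
        "resulted,target,expected",
        [(19, 32, 59.4), (28, 31, 90.3), (20, 20, 100.0)],
    )
    def test_slice_count_ratio(self, resulted, target, expected):
        assert ng.slice_count_ratio(resulted, target) == expected

    def test_zero_target_rejected(self):
        with pytest.raises(ValueError):
            ng.slice_count_ratio(5, 0)

    def test_proportional_matching_spans_both_stacks(self):
        mapping = match_slices(5, 10)
        assert mapping[0] == 0 and mapping[-1] == 9
        assert mapping == sorted(mapping)

    def test_landmark_anchored_matching_interpolates(self):
        mapping = match_slices(10, 20, method="landmark", landmark_pairs=[(0, 0), (9, 18)])
        assert mapping[0] == 0 and mapping[-1] == 18
        assert mapping[5] == 10


class TestLandmarks:
    def test_all_levels_equal_all_match(self):
        rad = {"hilum": 3, "upper_calyx": 1, "lower_calyx": 6}
        assert ng.landmark_concordance(rad, dict(rad)) == (3, 3)

    def test_absent_landmark_counts_toward_total_only(self):
        rad = {"hilum": 3, "upper_calyx": 1}
        assert ng.landmark_concordance(rad, {"hilum": 3}) == (1, 2)

    def test_within_tolerance_window_matches(self):
        rad = {"hilum": 3}
        assert ng.landmark_concordance(rad, {"hilum": 4}) == (1, 1)
        assert ng.landmark_concordance(rad, {"hilum": 5}) == (0, 1)
        assert ng.landmark_concordance(rad, {"hilum": 5}, tolerance=2) == (1, 1)

    def test_unknown_pathology_landmark_rejected(self):
        with pytest.raises(ValueError):
            ng.landmark_concordance({"hilum": 3}, {"mystery": 2})


def _report(ratio_counts=(16, 20), largest=0.85):
    return ng.PatientQCReport(
        patient_id="p",
        median_thickness=5.0,
        median_opposite_diff=1.0,
        n_target=ratio_counts[1],
        n_resulted=ratio_counts[0],
        landmarks_matched=2,
        landmarks_total=3,
        dice_values=[largest, 0.9],
        largest_slice_dice=largest,
    )


class TestInclusionDecision:
    def test_all_criteria_pass(self):
        include, reasons = ng.inclusion_decision(_report(), 7, False)
        assert include and reasons == []

    def test_low_slice_ratio_excludes(self):
        include, reasons = ng.inclusion_decision(_report(ratio_counts=(19, 32)), 7, False)
        assert not include and reasons == ["slice-count"]

    def test_low_dice_excludes(self):
        include, reasons = ng.inclusion_decision(_report(largest=0.79), 7, False)
        assert not include and reasons == ["overlap"]

    def test_long_interval_and_chemo_excluded(self):
        include, reasons = ng.inclusion_decision(_report(), 15, True)
        assert not include
        assert set(reasons) == {"interval", "chemotherapy"}

    def test_boundaries_are_inclusive(self):
        assert ng.inclusion_decision(_report(ratio_counts=(15, 20)), 14, False)[0]
        assert ng.inclusion_decision(_report(largest=0.800), 14, False)[0]

    def test_missing_largest_slice_dice_is_error(self):
        rep = _report()
        rep.largest_slice_dice = None
        with pytest.raises(IncompleteReportError):
            ng.inclusion_decision(rep, 7, False)

    def test_monotone_improving_any_criterion_never_flips_to_exclude(self):
        base_args = dict(ratio_counts=(14, 20), largest=0.79)
        for days, chemo in ((20, True), (7, False)):
            inc0, _ = ng.inclusion_decision(_report(**base_args), days, chemo)
            better = [
                (dict(ratio_counts=(20, 20), largest=0.79), days, chemo),
                (dict(ratio_counts=(14, 20), largest=0.95), days, chemo),
                (base_args, 1, chemo),
                (base_args, days, False),
            ]
            for args, d, c in better:
                inc1, _ = ng.inclusion_decision(_report(**args), d, c)
                assert inc1 >= inc0  # improving one criterion never hurts


class TestCohortSummary:
    def test_age_fixture_median_and_range(self):
        table = ng.cohort_fixture()["merged"]
        summary = ng.cohort_summary(table).set_index("quantity")
        assert summary.loc["age_months", "median"] == 50.0
        assert summary.loc["age_months", "min"] == 4.0
        assert summary.loc["age_months", "max"] == 100.0

    def test_cost_fixture_median_and_range(self):
        summary = ng.cohort_summary(ng.cohort_fixture()["merged"]).set_index("quantity")
        assert summary.loc["cost_eur", "median"] == 18.90
        assert summary.loc["cost_eur", "min"] == 12.13
        assert summary.loc["cost_eur", "max"] == 38.07

    def test_single_patient_median_equals_range(self):
        table = ng.cohort_fixture()["merged"].iloc[[2]]
        summary = ng.cohort_summary(table).set_index("quantity")
        row = summary.loc["age_months"]
        assert row["median"] == row["min"] == row["max"]

    def test_empty_cohort_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            ng.cohort_summary(pd.DataFrame())
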
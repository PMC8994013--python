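"""LV/RV quantification: keypoints, measures, ED/ES detection, EF and FAC."""

import numpy as np
import pytest

from echoseg import phantom as ph
from echoseg import quantify as q


def half_disc(radius=40, shape=(100, 120), center=(20, 60)):
    """Flat edge at the top, curved boundary below."""
    rr, cc = np.ogrid[:shape[0], :shape[1]]
    cr, ccol = center
    return (((rr - cr) ** 2 + (cc - ccol) ** 2 <= radius ** 2)
            & (rr >= cr)).astype(np.uint8)


class TestKeypoints:
    def test_half_disc_landmarks(self):
        mask = half_disc()
        kp = q.find_lv_keypoints(mask)
        # mitral joints at the ends of the flat top edge, apex at the bottom
        assert kp.mitral_a[0] == pytest.approx(20, abs=1)
        assert kp.mitral_b[0] == pytest.approx(20, abs=1)
        cols = sorted([kp.mitral_a[1], kp.mitral_b[1]])
        assert cols[0] == pytest.approx(60 - 40, abs=1.5)
        assert cols[1] == pytest.approx(60 + 40, abs=1.5)
        assert kp.apex[0] == pytest.approx(60, abs=1)
        assert kp.apex[1] == pytest.approx(60, abs=1.5)

    def test_bullet_chamber_apex_on_long_axis(self, default_phantom):
        spec = default_phantom.spec
        kp = q.find_lv_keypoints(default_phantom.masks[0])
        a = spec.semi_axis_long_ed
        assert kp.apex[0] == pytest.approx(spec.center[0] + a, abs=1.5)
        assert kp.apex[1] == pytest.approx(spec.center[1], abs=2)
        # mitral chord perpendicular to the long axis within discretization
        assert abs(kp.mitral_a[0] - kp.mitral_b[0]) <= 1.0

    def test_all_keypoints_lie_on_the_hull(self, default_phantom):
        from scipy.spatial import ConvexHull

        mask = default_phantom.masks[3]
        kp = q.find_lv_keypoints(mask)
        pts = np.argwhere(mask > 0).astype(float)
        hull_pts = {tuple(p) for p in pts[ConvexHull(pts[:, ::-1]).vertices]}
        for p in (kp.apex, kp.mitral_a, kp.mitral_b):
            assert tuple(p) in hull_pts

    def test_degenerate_masks_are_rejected(self):
        with pytest.raises(ValueError):
            q.find_lv_keypoints(np.zeros((10, 10)))
        single = np.zeros((10, 10))
        single[5, 5] = 1
        with pytest.raises(ValueError):
            q.find_lv_keypoints(single)


class TestMeasures:
    def test_length_from_hand_computed_distance(self):
        kp = q.Keypoints(apex=(200.0, 64.0), mitral_a=(40.0, 60.0),
                         mitral_b=(40.0, 68.0))
        assert q.lv_length(kp, 0.05) == pytest.approx(8.0)

    def test_length_scales_linearly_with_spacing(self):
        kp = q.Keypoints(apex=(100.0, 50.0), mitral_a=(10.0, 40.0),
                         mitral_b=(10.0, 60.0))
        assert q.lv_length(kp, 0.1) == pytest.approx(2 * q.lv_length(kp, 0.05))

    def test_coincident_apex_and_midpoint_rejected(self):
        kp = q.Keypoints(apex=(10.0, 50.0), mitral_a=(10.0, 40.0),
                         mitral_b=(10.0, 60.0))
        with pytest.raises(ValueError):
            q.lv_length(kp, 0.05)

    def test_area_is_count_times_spacing_squared(self):
        mask = np.zeros((30, 30))
        mask[5:15, 5:15] = 1
        assert q.region_area(mask, 0.05) == pytest.approx(100 * 0.0025)
        assert q.region_area(np.zeros((5, 5)), 0.05) == 0.0

    def test_area_translation_invariant(self, rng):
        mask = np.zeros((40, 40))
        mask[2:12, 3:13] = 1
        assert q.region_area(mask, 0.1) == q.region_area(np.roll(mask, 7), 0.1)


class TestSimpsonVolume:
    def test_hand_computed_value(self):
        assert q.simpson_volume(30.0, 8.0) == pytest.approx(
            8 * 900 / (3 * np.pi * 8))
        assert q.simpson_volume(30.0, 8.0) == pytest.approx(95.49, abs=0.01)

    def test_quadratic_in_area_inverse_in_length(self):
        v = q.simpson_volume(10.0, 5.0)
        assert q.simpson_volume(20.0, 5.0) == pytest.approx(4 * v)
        assert q.simpson_volume(10.0, 10.0) == pytest.approx(v / 2)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            q.simpson_volume(10.0, 0.0)

    def test_randomized_inputs_match_closed_form(self, rng):
        for _ in range(50):
            s, length = rng.uniform(1, 60), rng.uniform(2, 12)
            assert q.simpson_volume(s, length) == pytest.approx(
                8 * s * s / (3 * np.pi * length), rel=1e-12)


class TestEdEsDetection:
    def test_argmax_argmin(self):
        assert q.detect_ed_es([80, 100, 60, 90]) == (1, 2)

    def test_ties_resolve_to_the_earliest_frame(self):
        assert q.detect_ed_es([100, 100, 50]) == (0, 2)

    def test_constant_curve_warns(self):
        with pytest.warns(UserWarning):
            assert q.detect_ed_es([5.0, 5.0, 5.0]) == (0, 0)

    def test_phantom_ground_truth_masks_recover_true_indices(self):
        spec = ph.PhantomSpec(seed=21)
        seq = ph.generate_phantom_sequence(spec)
        rep = q.quantify_lv_sequence(seq.masks, spec.pixel_spacing)
        assert (rep.ed_index, rep.es_index) == (seq.true_ed_index,
                                                seq.true_es_index)


class TestEjectionFraction:
    @pytest.mark.parametrize("edv,esv,expected",
                             [(100, 40, 60), (80, 80, 0), (70, 0, 100)])
    def test_definition(self, edv, esv, expected):
        assert q.ejection_fraction(edv, esv) == pytest.approx(expected)

    def test_mislabeled_phases_rejected(self):
        with pytest.raises(ValueError):
            q.ejection_fraction(50.0, 60.0)


class TestLVSequence:
    def test_phantom_truth_recovered_within_two_points(self):
        spec = ph.PhantomSpec(seed=8)
        seq = ph.generate_phantom_sequence(spec)
        rep = q.quantify_lv_sequence(seq.masks, spec.pixel_spacing)
        assert abs(rep.ef - seq.true_ef) <= 2.0

    def test_identical_masks_give_zero_ef(self, default_phantom):
        masks = [default_phantom.masks[0]] * 4
        with pytest.warns(UserWarning):
            rep = q.quantify_lv_sequence(masks, 0.05)
        assert rep.ef == pytest.approx(0.0)

    def test_report_extrema_are_internally_consistent(self, default_phantom):
        rep = q.quantify_lv_sequence(default_phantom.masks,
                                     default_phantom.spec.pixel_spacing)
        assert rep.edv == pytest.approx(rep.volumes.max())
        assert rep.esv == pytest.approx(rep.volumes.min())
        assert 0 <= rep.ef < 100

    def test_empty_frames_are_flagged_and_interpolated(self, default_phantom):
        masks = list(default_phantom.masks)
        masks[2] = np.zeros_like(masks[2])
        rep = q.quantify_lv_sequence(masks, default_phantom.spec.pixel_spacing)
        assert rep.empty_frames[2]
        lo = min(rep.volumes[1], rep.volumes[3])
        hi = max(rep.volumes[1], rep.volumes[3])
        assert lo <= rep.volumes[2] <= hi

    def test_all_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            q.quantify_lv_sequence([np.zeros((10, 10))] * 3, 0.05)

    def test_ef_invariant_to_pixel_spacing(self, default_phantom):
        r1 = q.quantify_lv_sequence(default_phantom.masks, 0.03)
        r2 = q.quantify_lv_sequence(default_phantom.masks, 0.06)
        assert r1.ef == pytest.approx(r2.ef)


class TestRVSequence:
    def test_fac_definition(self):
        big, small = np.zeros((40, 40)), np.zeros((40, 40))
        big[5:29, 5:29] = 1    # 576 px
        small[5:29, 5:17] = 1  # 288 px
        rep = q.quantify_rv_sequence([big, small], 1.0, ed_index=0, es_index=1)
        assert rep.fac == pytest.approx(50.0)

    def test_equal_areas_give_zero_fac(self, default_phantom):
        m = default_phantom.masks[0]
        rep = q.quantify_rv_sequence([m, m], 0.05, 0, 1)
        assert rep.fac == pytest.approx(0.0)

    def test_phantom_truth_within_one_point(self):
        spec = ph.PhantomSpec(seed=4)
        seq = ph.generate_phantom_sequence(spec)
        rep = q.quantify_rv_sequence(seq.masks, spec.pixel_spacing,
                                     seq.true_ed_index, seq.true_es_index)
        a_ed, b_ed = ph._axes_at(spec, seq.true_ed_index)
        a_es, b_es = ph._axes_at(spec, seq.true_es_index)
        fac_true = 100.0 * (1 - (a_es * b_es) / (a_ed * b_ed))
        assert abs(rep.fac - fac_true) <= 1.0

    def test_missing_indices_are_rejected(self, default_phantom):
        with pytest.raises(ValueError, match="operator"):
            q.quantify_rv_sequence(default_phantom.masks, 0.05, None, None)

    def test_fac_invariant_to_pixel_spacing(self, default_phantom):
        r1 = q.quantify_rv_sequence(default_phantom.masks, 0.03, 0, 5)
        r2 = q.quantify_rv_sequence(default_phantom.masks, 0.06, 0, 5)
        assert r1.fac == pytest.approx(r2.fac)
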
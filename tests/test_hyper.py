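import numpy as np
import pandas as pd
import pytest

from wormquant import (
    HYPER_LAYOUT,
    ChannelStack,
    HyperSceneParams,
    RatioFieldSpec,
    compute_ratio_map,
    estimate_af_ratio,
    estimate_af_ratio_grid,
    make_hyper_scene,
    platereader_hyper,
    quantify_worm,
    render_inr,
    select_focal_plane,
    subtract_autofluorescence,
)
from wormquant.hyper import RatioMap

from conftest import control_pairs


def stack_from(values, channel="405"):
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]  # single z-slice
    spec = next(c for c in HYPER_LAYOUT if c.name == channel)
    return ChannelStack(arr, spec, subject_id="w")


class TestEstimateAFRatio:
    def test_exact_proportionality_recovers_r(self, rng):
        af = stack_from(rng.uniform(1, 100, (3, 8, 8)), "af")
        tgt = af.with_voxels(0.6 * af.voxels)
        model = estimate_af_ratio([(tgt, af)], "405")
        assert model.r["405"] == pytest.approx(0.6, abs=1e-12)
        assert model.rms_residual == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_closed_form(self):
        # R = sum(t*a)/sum(a^2) = 59.7/30 = 1.99
        af = stack_from([[1.0, 2.0], [3.0, 4.0]], "af")
        tgt = stack_from([[2.1, 3.9], [6.2, 7.8]])
        model = estimate_af_ratio([(tgt, af)], "405")
        assert model.r["405"] == pytest.approx(1.99)
        assert model.n_pixels_fit == 4

    def test_all_zero_af_channel_raises(self):
        af = stack_from(np.zeros((2, 2)), "af")
        tgt = stack_from(np.ones((2, 2)))
        with pytest.raises(ValueError, match="all zero"):
            estimate_af_ratio([(tgt, af)], "405")

    def test_empty_mask_raises(self, rng):
        af = stack_from(rng.uniform(1, 10, (2, 2)), "af")
        with pytest.raises(ValueError, match="empty mask"):
            estimate_af_ratio([(af, af)], "405", mask=np.zeros((2, 2), dtype=bool))

    def test_matches_brute_force_grid_minimizer(self, rng):
        # oracle equivalence on small pixel sets
        for _ in range(5):
            r_true = rng.uniform(0.1, 1.5)
            af_vals = rng.uniform(5, 80, (1, 10, 10))
            af = stack_from(af_vals.squeeze(0), "af")
            tgt = af.with_voxels(r_true * af.voxels + rng.normal(0, 2, af.shape))
            tgt = tgt.with_voxels(np.clip(tgt.voxels, 0, None))
            closed = estimate_af_ratio([(tgt, af)], "405").r["405"]
            grid = estimate_af_ratio_grid([(tgt, af)], "405", step=1e-4)
            assert abs(closed - grid) < 1e-3

    def test_per_group_models_are_independent(self, noisy_controls):
        half_a = control_pairs(noisy_controls[:4])
        half_b = control_pairs(noisy_controls[4:])
        ma = estimate_af_ratio(half_a, "405", group="EV")
        mb = estimate_af_ratio(half_b, "405", group="tald-1")
        assert ma.group == "EV" and mb.group == "tald-1"
        assert ma.n_pixels_fit == mb.n_pixels_fit
        assert ma.r["405"] != mb.r["405"]  # different animals, different fits


class TestSubtraction:
    def test_r_zero_is_bitexact_identity(self, rng):
        raw = stack_from(rng.uniform(0, 500, (4, 6, 6)))
        af = stack_from(rng.uniform(0, 100, (4, 6, 6)), "af")
        out = subtract_autofluorescence(raw, af, 0.0)
        assert np.array_equal(out.voxels, raw.voxels)

    def test_hand_evaluated_subtraction_and_clip(self):
        raw = stack_from([[10.0, 5.0]])
        af = stack_from([[4.0, 4.0]], "af")
        out = subtract_autofluorescence(raw, af, 2.0)
        assert out.voxels[0, 0, 0] == 2.0
        assert out.voxels[0, 0, 1] == 0.0  # clipped
        assert out.extras["unclipped"][0, 0, 1] == -3.0

    def test_shape_mismatch_and_negative_r_raise(self, rng):
        raw = stack_from(rng.uniform(0, 5, (2, 3, 3)))
        af = stack_from(rng.uniform(0, 5, (2, 4, 4)), "af")
        with pytest.raises(ValueError, match="shape"):
            subtract_autofluorescence(raw, af, 0.5)
        with pytest.raises(ValueError, match="nonnegative"):
            subtract_autofluorescence(raw, raw, -0.1)


class TestFocalPlane:
    def test_single_slice_returns_zero(self):
        s = stack_from(np.ones((1, 4, 4)))
        assert select_focal_plane(s, s, np.ones((4, 4), bool)) == 0

    def test_tie_breaks_to_lowest_z(self):
        # in-ROI combined sums 100, 250, 250 -> z = 1
        vox = np.zeros((3, 2, 2))
        vox[0], vox[1], vox[2] = 12.5, 31.25, 31.25
        s = stack_from(vox)
        assert select_focal_plane(s, s, np.ones((2, 2), bool)) == 1

    def test_empty_roi_raises(self):
        s = stack_from(np.ones((2, 3, 3)))
        with pytest.raises(ValueError, match="empty ROI"):
            select_focal_plane(s, s, np.zeros((3, 3), bool))


class TestRatioMap:
    def test_proportional_fields_give_constant_ratio(self, rng):
        f405 = rng.uniform(10, 100, (5, 5))
        rmap = compute_ratio_map(2.0 * f405, f405, denom_floor=1.0)
        assert rmap.valid.all()
        assert np.allclose(rmap.ratio, 2.0)

    def test_floor_invalidates_dark_pixels(self):
        f405 = np.array([[0.0, 5.0]])
        rmap = compute_ratio_map(np.ones((1, 2)), f405, denom_floor=1.0)
        assert not rmap.valid[0, 0] and rmap.valid[0, 1]

    def test_scale_invariance(self, rng):
        f405 = rng.uniform(5, 50, (6, 6))
        f488 = rng.uniform(5, 50, (6, 6))
        r1 = compute_ratio_map(f488, f405, 1.0)
        r2 = compute_ratio_map(7.3 * f488, 7.3 * f405, 1.0)
        sel = r1.valid & r2.valid
        assert np.allclose(r1.ratio[sel], r2.ratio[sel])

    def test_nonpositive_floor_rejected(self):
        with pytest.raises(ValueError, match="denom_floor"):
            compute_ratio_map(np.ones((2, 2)), np.ones((2, 2)), 0.0)


class TestQuantifyWorm:
    def test_constant_fields_same_in_both_modes(self):
        c405 = stack_from(2.0 * np.ones((1, 4, 4)))
        c488 = stack_from(3.0 * np.ones((1, 4, 4)), "488")
        roi = np.ones((4, 4), bool)
        for mode in ("ratio_of_sums", "mean_of_ratios"):
            assert quantify_worm(c405, c488, roi, mode=mode).roi_ratio == pytest.approx(1.5)

    def test_two_pixel_hand_computation(self):
        # F488 = (1, 3), F405 = (1, 2): ratio_of_sums 4/3, mean_of_ratios 1.25
        c405 = stack_from([[1.0, 2.0]])
        c488 = stack_from([[1.0, 3.0]], "488")
        roi = np.ones((1, 2), bool)
        ros = quantify_worm(c405, c488, roi, "ratio_of_sums", denom_floor=0.5)
        mor = quantify_worm(c405, c488, roi, "mean_of_ratios", denom_floor=0.5)
        assert ros.roi_ratio == pytest.approx(4.0 / 3.0)
        assert mor.roi_ratio == pytest.approx(1.25)
        assert ros.n_valid_pixels == 2

    def test_noiseless_scene_recovers_true_ratio(self, noiseless_scene):
        scene, _ = noiseless_scene
        c405 = subtract_autofluorescence(
            scene.raw_stacks["405"], scene.raw_stacks["af"], scene.params.r_true["405"]
        )
        res = quantify_worm(c405, scene.raw_stacks["488"], scene.roi.rois[0])
        assert res.roi_ratio == pytest.approx(1.8, rel=1e-9)

    def test_scale_invariance_of_pipeline(self, noiseless_scene):
        # multiplying all three raw channels by c > 0 leaves R-hat and roi_ratio unchanged
        scene, controls = noiseless_scene
        c = 3.7
        pairs = control_pairs(controls)
        scaled_pairs = [(t.with_voxels(c * t.voxels), a.with_voxels(c * a.voxels)) for t, a in pairs]
        r1 = estimate_af_ratio(pairs, "405").r["405"]
        r2 = estimate_af_ratio(scaled_pairs, "405").r["405"]
        assert r1 == pytest.approx(r2, rel=1e-12)

        def ratio(scale):
            c405 = subtract_autofluorescence(
                scene.raw_stacks["405"].with_voxels(scale * scene.raw_stacks["405"].voxels),
                scene.raw_stacks["af"].with_voxels(scale * scene.raw_stacks["af"].voxels),
                r1,
            )
            c488 = scene.raw_stacks["488"].with_voxels(scale * scene.raw_stacks["488"].voxels)
            return quantify_worm(c405, c488, scene.roi.rois[0]).roi_ratio

        assert ratio(1.0) == pytest.approx(ratio(c), rel=1e-9)

    def test_all_dark_roi_raises(self):
        c405 = stack_from(np.zeros((1, 3, 3)))
        c488 = stack_from(np.ones((1, 3, 3)), "488")
        with pytest.raises(ValueError, match="no valid pixels"):
            quantify_worm(c405, c488, np.ones((3, 3), bool), denom_floor=1.0)


class TestRenderINR:
    def test_invalid_pixels_render_black(self):
        rmap = RatioMap(np.ones((4, 4)), np.zeros((4, 4), bool), 1.0)
        rgb = render_inr(rmap, np.ones((4, 4)), (0.5, 2.0))
        assert np.all(rgb == 0.0)

    def test_zero_intensity_is_black_and_clipping_uniform(self):
        ratio = np.full((3, 3), 0.1)  # below display lo
        rmap = RatioMap(ratio, np.ones((3, 3), bool), 1.0)
        intensity = np.ones((3, 3))
        intensity[0, 0] = 0.0
        rgb = render_inr(rmap, intensity, (0.5, 2.0))
        assert np.all(rgb[0, 0] == 0.0)
        others = rgb[intensity > 0]
        assert np.allclose(others, others[0])  # uniform low-end colour

    def test_degenerate_display_range_rejected(self):
        rmap = RatioMap(np.ones((2, 2)), np.ones((2, 2), bool), 1.0)
        with pytest.raises(ValueError, match="display range"):
            render_inr(rmap, np.ones((2, 2)), (2.0, 2.0))


class TestPlateReader:
    def make_table(self):
        return pd.DataFrame(
            {
                "group": ["bg", "bg", "treated", "treated"],
                "f405": [20.0, 20.0, 100.0, 15.0],
                "f488": [40.0, 40.0, 160.0, 80.0],
            }
        )

    def test_hand_evaluated_background_subtraction(self):
        out = platereader_hyper(self.make_table(), "bg")
        treated = out[out.group == "treated"]
        assert treated.iloc[0]["ratio"] == pytest.approx((160 - 40) / (100 - 20))  # 1.5

    def test_nonpositive_denominator_flagged_invalid(self):
        out = platereader_hyper(self.make_table(), "bg")
        assert not out[out.group == "treated"].iloc[1]["valid"]
        assert np.isnan(out[out.group == "treated"].iloc[1]["ratio"])

    def test_zero_background_means_identity(self):
        tab = self.make_table()
        tab.loc[tab.group == "bg", ["f405", "f488"]] = 0.0
        out = platereader_hyper(tab, "bg")
        treated = out[out.group == "treated"]
        assert treated.iloc[0]["ratio"] == pytest.approx(1.6)

    def test_missing_background_group_raises(self):
        with pytest.raises(ValueError, match="background"):
            platereader_hyper(self.make_table(), "absent")


def test_noisy_r_recovery_within_two_percent(noisy_controls):
    model = estimate_af_ratio(control_pairs(noisy_controls), "405")
    assert abs(model.r["405"] - 0.35) / 0.35 <= 0.02
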
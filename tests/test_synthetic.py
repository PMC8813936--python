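"""Ground-truth scene construction and rendering."""

import numpy as np
import pytest

from cyclim import (AcquisitionPlan, CrosstalkMatrix, CyclePlan, NoiseModel,
                    apply_erasure, make_bead_scene, make_cell_scene,
                    render_exposure_series)
from cyclim.errors import ConfigError, PlacementError


class TestBeadScene:
    @pytest.mark.parametrize("fraction,expected", [(0.0, 0.0), (1.0, 1000.0)])
    def test_degenerate_fractions_give_exact_counts(self, fraction, expected):
        scene = make_bead_scene(8, fraction, 1000, bead_radius=20,
                                min_separation=5, field_size=(384, 384),
                                seed=0)
        counts = [o.epitopes["APC"] for o in scene.objects]
        assert counts == [expected] * 8

    def test_binomial_mean_within_3se(self):
        n, p, n_beads = 1000, 0.1, 50
        scene = make_bead_scene(n_beads, p, n, bead_radius=10,
                                min_separation=10,
                                field_size=(512, 512), seed=42)
        counts = np.array([o.epitopes["APC"] for o in scene.objects])
        se = np.sqrt(n * p * (1 - p) / n_beads)
        assert abs(counts.mean() - n * p) < 3 * se

    def test_binomial_moments_at_scale(self):
        # empirical mean/variance of the epitope draws vs np and np(1-p)
        n, p = 500, 0.3
        scene = make_bead_scene(600, p, n, bead_radius=3, min_separation=5,
                                field_size=(1024, 1024), seed=9)
        counts = np.array([o.epitopes["APC"] for o in scene.objects])
        se_mean = np.sqrt(n * p * (1 - p) / counts.size)
        assert abs(counts.mean() - n * p) < 4 * se_mean
        var_true = n * p * (1 - p)
        se_var = var_true * np.sqrt(2.0 / (counts.size - 1))  # normal approx
        assert abs(counts.var(ddof=1) - var_true) < 4 * se_var

    def test_same_seed_bit_identical(self):
        a = make_bead_scene(10, 0.4, 2000, seed=5, field_size=(512, 512))
        b = make_bead_scene(10, 0.4, 2000, seed=5, field_size=(512, 512))
        assert a.to_dict() == b.to_dict()

    def test_overfull_field_raises_placement_error(self):
        with pytest.raises(PlacementError):
            make_bead_scene(200, 0.5, 100, bead_radius=40,
                            field_size=(256, 256), seed=0)

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            make_bead_scene(5, 1.5, 100, seed=0)


class TestCellScene:
    def test_expected_labeled_count_at_ten_percent(self):
        # 57,000 copies at 10% labeling -> 5,700 expected per positive cell
        scene = make_cell_scene(40, 1.0, 0.10, field_size=(1280, 1280), seed=1)
        counts = np.array([o.epitopes["CD3"] for o in scene.objects])
        se = np.sqrt(57_000 * 0.1 * 0.9 / counts.size)
        assert abs(counts.mean() - 5700.0) < 3 * se

    def test_rare_labeling_mean(self):
        # 0.033% labeling of 57,000 copies -> ~18.8 labeled epitopes
        scene = make_cell_scene(400, 1.0, 0.00033, cell_radius=4,
                                min_separation=5,
                                field_size=(1024, 1024), seed=3)
        counts = np.array([o.epitopes["CD3"] for o in scene.objects])
        mean = 0.00033 * 57_000
        se = np.sqrt(mean / counts.size)  # binomial ~ Poisson here
        assert abs(counts.mean() - mean) < 3 * se

    def test_no_positive_cells_means_no_cd3(self):
        scene = make_cell_scene(20, 0.0, 0.5, field_size=(768, 768), seed=2)
        assert all(o.epitopes["CD3"] == 0.0 for o in scene.objects)
        assert all(o.epitopes["CD45"] > 0 for o in scene.objects)


class TestRendering:
    def test_zero_scene_zero_noise_gives_offset(self):
        scene = make_bead_scene(0, 0.0, 0, field_size=(64, 64), seed=0,
                                autofluorescence_level=0.0)
        plan = AcquisitionPlan(cycles=[CyclePlan({"APC": "APC"}, prestain=False)])
        noise = NoiseModel(read_offset=100.0, read_sigma=2.0)
        stack = render_exposure_series(scene, plan, noise, cycle=0,
                                       channel="APC", noiseless=True)
        assert np.all(stack.frames == 100.0)

    def test_noiseless_frames_follow_linear_model(self, bead_scene,
                                                  two_channel_plan, noise):
        h, w = bead_scene.field_size
        ff = 0.8 + 0.4 * np.linspace(0, 1, w)[None, :] * np.ones((h, 1))
        stack = render_exposure_series(bead_scene, two_channel_plan, noise,
                                       flatfield=ff, cycle=0, channel="APC",
                                       noiseless=True)
        mixed = two_channel_plan.crosstalk.mix(np.stack(
            [bead_scene.marker_rate_field("DAPI"),
             bead_scene.marker_rate_field("APC")]))
        rate = mixed[1] + bead_scene.autofluorescence_field("APC")
        for frame, exp in zip(stack.frames, stack.exposure_ms):
            np.testing.assert_allclose(frame, 100.0 + exp * ff * rate,
                                       rtol=0, atol=1e-9)

    def test_doubling_exposure_doubles_signal(self):
        scene = make_bead_scene(3, 1.0, 1000, bead_radius=20,
                                min_separation=5, field_size=(256, 256),
                                seed=4)
        plan = AcquisitionPlan(
            cycles=[CyclePlan({"APC": "APC"}, prestain=False)],
            exposure_series_ms=(50.0, 100.0))
        noise = NoiseModel(read_offset=100.0, saturation_level=1e9)
        stack = render_exposure_series(scene, plan, noise, cycle=0,
                                       channel="APC", noiseless=True)
        np.testing.assert_allclose(stack.frames[1] - 100.0,
                                   2 * (stack.frames[0] - 100.0), atol=1e-9)

    def test_saturation_iff_signal_exceeds_level(self):
        # bright object saturates the longest exposure exactly when
        # offset + gain*640*rate*flatfield >= saturation_level
        scene = make_bead_scene(1, 1.0, 300_000, bead_radius=30,
                                field_size=(128, 128), seed=6)
        rate = scene.marker_rate_field("APC").max()
        plan = AcquisitionPlan(cycles=[CyclePlan({"APC": "APC"}, prestain=False)])
        noise = NoiseModel(read_offset=100.0, saturation_level=65535.0)
        stack = render_exposure_series(scene, plan, noise, cycle=0,
                                       channel="APC", noiseless=True)
        should_saturate = 100.0 + 640.0 * rate >= 65535.0
        assert should_saturate  # the construction is in the saturating regime
        assert stack.frames[2].max() == 65535.0
        assert stack.frames[0].max() < 65535.0  # 60 ms stays in range

    def test_same_seed_bit_identical_stacks(self, bead_scene, two_channel_plan,
                                            camera_16bit):
        kw = dict(cycle=0, channel="APC", seed=11)
        a = render_exposure_series(bead_scene, two_channel_plan, camera_16bit, **kw)
        b = render_exposure_series(bead_scene, two_channel_plan, camera_16bit, **kw)
        assert np.array_equal(a.frames, b.frames)

    def test_hot_cold_pixels_fixed_across_frames(self, bead_scene,
                                                 two_channel_plan):
        noise = NoiseModel(read_offset=100.0, read_sigma=2.0,
                           saturation_level=65535.0, hot_rate=0.002,
                           cold_rate=0.002, sensor_seed=3)
        stack = render_exposure_series(bead_scene, two_channel_plan, noise,
                                       cycle=0, channel="APC", seed=1)
        hot, cold = noise.defect_masks(bead_scene.field_size)
        for frame in stack.frames:
            assert np.all(frame[hot] == 65535.0)
            assert np.all(frame[cold] == 0.0)

    def test_unknown_channel_rejected(self, bead_scene, two_channel_plan, noise):
        with pytest.raises(ConfigError):
            render_exposure_series(bead_scene, two_channel_plan, noise,
                                   cycle=0, channel="FITC")


class TestErasure:
    def test_complete_erasure_zeroes_rates(self):
        assert apply_erasure({"CD3": 100.0}, 0.0) == {"CD3": 0.0}

    def test_ninety_percent_reduction(self):
        # residual fraction 0.1 is exactly a 90% reduction
        assert apply_erasure({"CD3": 100.0}, 0.1) == {"CD3": pytest.approx(10.0)}

    def test_erasures_compose_multiplicatively(self):
        once = apply_erasure({"m": 100.0}, 0.1)
        twice = apply_erasure(once, 0.1)
        assert twice["m"] == pytest.approx(1.0)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ConfigError):
            apply_erasure({"m": 1.0}, 1.0)
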
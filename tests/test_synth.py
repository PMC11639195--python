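"""Synthetic acquisition generator: scene geometry, noise statistics,
camera pipeline, and determinism."""

import logging
import math

import numpy as np
import pytest

from cherenkov_denoise import (
    AcquisitionSpec,
    Image2D,
    NoiseModel,
    SceneSpec,
    make_dataset,
    make_truth_scene,
    psnr,
    simulate_cumulative,
)

QUIET = NoiseModel(
    read_sigma=0.0,
    impulse_rate=0.0,
    temporal_median_window=1,
    spatial_median_size=1,
    subtract_background=False,
)


class TestTruthScene:
    def test_zero_field_gives_all_zero_image(self):
        img = make_truth_scene(SceneSpec(field_level=0.0))
        assert np.all(img.pixels == 0)

    def test_edge_occludes_half_the_unmasked_pixels(self):
        spec = SceneSpec(
            height=200, width=200, edge_position=0.5, edge_angle=5.0, phantom_margin=0
        )
        img = make_truth_scene(spec)
        # oracle: count dark pixels row by row against the analytic
        # line x_edge(y) = 0.5*W + tan(5 deg) * (y - (H-1)/2)
        tan = math.tan(math.radians(5.0))
        expected_dark = sum(
            200 - min(200, max(0, math.ceil(0.5 * 200 + tan * (y - 99.5))))
            for y in range(200)
        )
        assert int(np.sum(img.pixels == 0)) == expected_dark
        assert abs(np.mean(img.pixels == 0) - 0.5) < tan * 0.5 + 0.01

    def test_same_spec_is_deterministic(self):
        a = make_truth_scene(SceneSpec())
        b = make_truth_scene(SceneSpec())
        assert np.array_equal(a.pixels, b.pixels)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(edge_angle=1.0),
            dict(edge_angle=20.0),
            dict(height=0),
            dict(phantom_margin=200),
            dict(vignette_sigma=0.0),
        ],
    )
    def test_invalid_scene_rejected(self, bad):
        with pytest.raises(ValueError):
            make_truth_scene(SceneSpec(**bad))


class TestSimulateCumulative:
    def test_zero_truth_quiet_camera_gives_zero(self):
        truth = Image2D(np.zeros((16, 16)))
        acq = AcquisitionSpec(frames_truth=10, frames_noisy=1, seed=0)
        out = simulate_cumulative(truth, acq, QUIET)
        assert np.all(out.pixels == 0)

    def test_mean_of_replicates_recovers_truth(self, rng):
        """Law of large numbers: the per-frame mean over Monte-Carlo
        replicates matches the expectation map within sampling error."""
        truth = Image2D(rng.uniform(5.0, 10.0, (8, 8)))
        acq = AcquisitionSpec(frames_truth=4, frames_noisy=4, seed=0)
        noise = NoiseModel(
            read_sigma=0.4,
            impulse_rate=0.0,
            temporal_median_window=1,
            spatial_median_size=1,
            subtract_background=False,
        )
        n_rep = 200
        frames = 4
        sums = np.stack(
            [
                simulate_cumulative(
                    truth, AcquisitionSpec(frames_truth=4, frames_noisy=frames, seed=s),
                    noise,
                ).pixels
                / frames
                for s in range(n_rep)
            ]
        )
        mean = sums.mean(axis=0)
        se = sums.std(axis=0, ddof=1) / math.sqrt(n_rep)
        z = np.abs(mean - truth.pixels) / se
        # per-pixel 3-sigma check; one 64-pixel excursion is within the
        # expected false-positive budget of a 3-sigma rule
        assert int(np.sum(z > 3.0)) <= 1
        assert float(z.max()) < 5.0

    def test_impulse_count_matches_binomial(self):
        truth = Image2D(np.zeros((200, 200)))
        rate = 0.01
        noise = NoiseModel(
            read_sigma=0.0,
            impulse_rate=rate,
            temporal_median_window=1,
            spatial_median_size=1,
            subtract_background=False,
        )
        acq = AcquisitionSpec(frames_truth=1, frames_noisy=1, seed=3)
        out = simulate_cumulative(truth, acq, noise)
        count = int(np.sum(out.pixels > 0))
        n = 200 * 200
        mean, sd = n * rate, math.sqrt(n * rate * (1 - rate))
        assert abs(count - mean) <= 4 * sd

    def test_impulses_only_ever_add_signal(self, rng):
        truth = Image2D(rng.uniform(2.0, 6.0, (32, 32)))
        acq = AcquisitionSpec(frames_truth=3, frames_noisy=3, seed=5)
        base = simulate_cumulative(truth, acq, QUIET)
        spiky = simulate_cumulative(
            truth,
            acq,
            NoiseModel(
                read_sigma=0.0,
                impulse_rate=0.05,
                temporal_median_window=1,
                spatial_median_size=1,
                subtract_background=False,
            ),
        )
        assert np.all(spiky.pixels >= base.pixels)

    def test_noise_variance_falls_with_frame_count(self, small_scene):
        """Counting statistics: plateau variance of (noisy - truth)
        decreases monotonically over >= 3 accumulation levels."""
        scene = make_truth_scene(small_scene)
        noise = NoiseModel()
        acq = AcquisitionSpec(frames_truth=300, frames_noisy=5, seed=2)
        truth = simulate_cumulative(scene, acq, noise, frames=300)
        variances = []
        for frames in (3, 6, 12):
            noisy = simulate_cumulative(scene, acq, noise, frames=frames)
            scaled = noisy.pixels * (300 / frames)
            resid = (scaled - truth.pixels)[30:60, 20:40]  # lit plateau ROI
            variances.append(float(resid.var()))
        assert variances[0] > variances[1] > variances[2]

    def test_no_negative_pixels_after_summation(self, small_scene):
        scene = make_truth_scene(small_scene)
        acq = AcquisitionSpec(frames_truth=5, frames_noisy=5, seed=9)
        out = simulate_cumulative(scene, acq, NoiseModel(read_sigma=2.0))
        assert np.all(out.pixels >= 0)

    def test_short_acquisition_disables_temporal_median(self, caplog):
        truth = Image2D(np.full((8, 8), 4.0))
        acq = AcquisitionSpec(frames_truth=2, frames_noisy=2, seed=0)
        noise = NoiseModel(temporal_median_window=5, spatial_median_size=1)
        with caplog.at_level(logging.WARNING, logger="cherenkov_denoise.synth"):
            simulate_cumulative(truth, acq, noise)
        assert any("temporal median" in r.message for r in caplog.records)

    def test_invalid_noise_model_rejected(self):
        with pytest.raises(ValueError):
            NoiseModel(impulse_rate=0.2).validate()
        with pytest.raises(ValueError):
            NoiseModel(temporal_median_window=4).validate()


class TestMakeDataset:
    def test_equal_frames_and_seed_reproduce_truth_exactly(self, small_scene):
        acq = AcquisitionSpec(frames_truth=6, frames_noisy=6, seed=21)
        truth, noisy = make_dataset(small_scene, acq, NoiseModel())
        assert np.array_equal(truth.pixels, noisy.pixels)

    def test_images_share_pixel_pitch_and_seeded_determinism(self, small_scene):
        acq = AcquisitionSpec(frames_truth=20, frames_noisy=4, seed=8)
        t1, n1 = make_dataset(small_scene, acq, NoiseModel())
        t2, n2 = make_dataset(small_scene, acq, NoiseModel())
        assert t1.pixel_pitch == n1.pixel_pitch
        assert np.array_equal(n1.pixels, n2.pixels)
        assert np.array_equal(t1.pixels, t2.pixels)

    def test_more_mu_means_higher_psnr(self, small_dataset):
        spec, acq, truth, noisy25 = small_dataset
        scene = make_truth_scene(spec)
        noisy50 = simulate_cumulative(scene, acq, NoiseModel(), frames=10)
        noisy50 = Image2D(noisy50.pixels * (acq.frames_truth / 10), noisy50.pixel_pitch)
        assert psnr(truth, noisy50) > psnr(truth, noisy25)

    def test_analytic_truth_is_flagged_and_noiseless(self, small_scene):
        acq = AcquisitionSpec(frames_truth=50, frames_noisy=5, seed=1)
        truth, _ = make_dataset(small_scene, acq, NoiseModel(), analytic_truth=True)
        assert truth.meta.get("analytic_truth") is True
        expected = make_truth_scene(small_scene).pixels * 50
        assert np.allclose(truth.pixels, expected)

    def test_inconsistent_acquisition_rejected(self):
        with pytest.raises(ValueError):
            AcquisitionSpec(frames_truth=5, frames_noisy=10).validate()
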
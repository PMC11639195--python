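"""Quality metrics: PSNR arithmetic, slanted-edge sharpness closed
forms, and NPS calibration/conservation."""

import math

import numpy as np
import pytest
from scipy.special import erf

from cherenkov_denoise import Image2D, compute_nps, esf_to_mtf, extract_esf, mtf_summary, psnr, rise_distance_10_90
from cherenkov_denoise.metrics import EdgeNotFoundError, MTFCurve


class TestPSNR:
    def test_hand_arithmetic(self):
        truth = Image2D(np.array([[0.0, 100.0], [100.0, 0.0]]))
        test = Image2D(np.array([[0.0, 110.0], [100.0, 0.0]]))
        # RMSE = sqrt(100/4) = 5 -> 20 log10(100/5)
        assert psnr(truth, test) == pytest.approx(20 * math.log10(20.0), abs=1e-9)

    def test_identical_images_are_infinite(self):
        img = Image2D(np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert psnr(img, img) == math.inf

    def test_doubling_residuals_costs_six_db(self, rng):
        truth = Image2D(np.abs(rng.normal(100.0, 10.0, (16, 16))))
        resid = rng.normal(0.0, 5.0, (16, 16))
        a = psnr(truth, Image2D(np.abs(truth.pixels + resid)))
        b = psnr(truth, Image2D(np.abs(truth.pixels + 2 * resid)))
        assert a - b == pytest.approx(20 * math.log10(2.0), abs=1e-9)

    def test_zero_truth_rejected(self):
        z = Image2D(np.zeros((4, 4)))
        with pytest.raises(ValueError):
            psnr(z, z)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            psnr(Image2D(np.ones((4, 4))), Image2D(np.ones((4, 5))))

    def test_monotone_in_noise_level(self, rng):
        truth = Image2D(np.abs(rng.normal(100.0, 5.0, (32, 32))))
        values = [
            psnr(truth, Image2D(np.abs(truth.pixels + rng.normal(0, s, truth.shape))))
            for s in (2.0, 5.0, 12.0)
        ]
        assert values[0] > values[1] > values[2]

    def test_data_type_peak_flag_changes_result(self, rng):
        truth = Image2D(np.abs(rng.normal(100.0, 5.0, (8, 8))))
        test = Image2D(truth.pixels + 1.0)
        assert psnr(truth, test, peak=65535.0) > psnr(truth, test)


def _blurred_edge(sigma_b: float, angle_deg: float = 5.0, h: int = 200, w: int = 120,
                  step: float = 100.0, shift: float = 0.0):
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    xe = w / 2 + shift + math.tan(math.radians(angle_deg)) * (yy - h / 2)
    t = (xx - xe) * math.cos(math.radians(angle_deg))
    if sigma_b == 0:
        return Image2D(np.where(t > 0, step, 0.0))
    return Image2D(step * 0.5 * (1 + erf(t / (sigma_b * math.sqrt(2)))))


class TestSlantedEdge:
    def test_edge_angle_recovered_within_02_degrees(self):
        esf = extract_esf(_blurred_edge(2.0, angle_deg=5.0), (0, 0, 200, 120))
        assert abs(esf.edge_angle_deg - 5.0) <= 0.2

    def test_flat_roi_raises_no_edge(self):
        flat = Image2D(np.full((50, 50), 10.0))
        with pytest.raises(EdgeNotFoundError):
            extract_esf(flat, (0, 0, 50, 50))

    def test_esf_matches_gaussian_cdf_profile(self):
        sigma_b, step = 2.0, 100.0
        esf = extract_esf(_blurred_edge(sigma_b), (0, 0, 200, 120))
        analytic = step * 0.5 * (1 + erf(esf.positions / (sigma_b * math.sqrt(2))))
        assert np.abs(esf.values - analytic).max() <= 0.02 * step

    def test_perfect_step_mtf_is_flat(self):
        mtf = esf_to_mtf(extract_esf(_blurred_edge(0.0), (0, 0, 200, 120)))
        assert mtf.values[mtf.freqs <= 0.25].min() >= 0.99

    def test_gaussian_mtf_matches_fourier_pair(self):
        sigma_b = 2.0
        mtf = esf_to_mtf(extract_esf(_blurred_edge(sigma_b), (0, 0, 200, 120)))
        sel = mtf.freqs <= 0.25
        analytic = np.exp(-2 * math.pi**2 * sigma_b**2 * mtf.freqs[sel] ** 2)
        assert np.abs(mtf.values[sel] - analytic).max() <= 0.02

    def test_mtf_is_intensity_scale_invariant(self):
        img = _blurred_edge(2.0)
        scaled = Image2D(img.pixels * 7.3)
        a = esf_to_mtf(extract_esf(img, (0, 0, 200, 120)))
        b = esf_to_mtf(extract_esf(scaled, (0, 0, 200, 120)))
        assert np.allclose(a.values, b.values, atol=1e-12)

    def test_mtf50_is_translation_invariant(self):
        a = mtf_summary(esf_to_mtf(extract_esf(_blurred_edge(2.0), (0, 0, 200, 120))))
        b = mtf_summary(
            esf_to_mtf(extract_esf(_blurred_edge(2.0, shift=3.0), (0, 0, 200, 120)))
        )
        assert abs(a["mtf50"] - b["mtf50"]) <= 0.01 * a["mtf50"]

    def test_mtf_summary_closed_forms(self):
        sigma_b = 2.0
        s = mtf_summary(esf_to_mtf(extract_esf(_blurred_edge(sigma_b), (0, 0, 200, 120))))
        want50 = math.sqrt(math.log(2) / (2 * math.pi**2 * sigma_b**2))
        want10 = math.sqrt(math.log(10) / (2 * math.pi**2 * sigma_b**2))
        assert s["mtf50"] == pytest.approx(want50, rel=0.03)
        assert s["mtf10"] == pytest.approx(want10, rel=0.03)

    def test_unreached_level_reported_absent(self):
        curve = MTFCurve(np.linspace(0, 0.5, 11), np.linspace(1.0, 0.4, 11))
        s = mtf_summary(curve)
        assert s["mtf10"] is None and s["mtf50"] is not None

    def test_rise_distance_closed_form_and_linearity(self):
        for sigma_b in (2.0, 4.0):
            esf = extract_esf(_blurred_edge(sigma_b), (0, 0, 200, 120))
            assert rise_distance_10_90(esf) == pytest.approx(2.563 * sigma_b, rel=0.03)

    def test_ideal_step_rise_within_one_bin(self):
        esf = extract_esf(_blurred_edge(0.0), (0, 0, 200, 120))
        assert rise_distance_10_90(esf) <= 1.0 / esf.oversampling


class TestNPS:
    def test_all_zero_image_has_zero_spectrum(self):
        res = compute_nps(Image2D(np.zeros((200, 200))), roi_size=64)
        assert np.all(res.nps2d == 0)
        assert np.all(res.radial_values == 0)

    def test_white_noise_calibration(self, rng):
        # sigma = 50 at 0.5 mm pitch -> mean 2D NPS = 2500 * 0.25
        img = Image2D(np.abs(rng.normal(5000.0, 50.0, (800, 800))))
        res = compute_nps(img, roi_size=100)
        assert res.n_rois >= 200
        assert res.nps2d.mean() == pytest.approx(625.0, rel=0.05)
        beyond_first = res.radial_values[1:]
        assert np.abs(beyond_first - beyond_first.mean()).max() <= 0.10 * beyond_first.mean()

    def test_parseval_total_power(self, rng):
        img = Image2D(np.abs(rng.normal(5000.0, 50.0, (400, 400))))
        res = compute_nps(img, roi_size=100)
        dy, dx = img.pixel_pitch
        n = res.roi_size
        bin_area = 1.0 / (n * dx) / (n * dy)
        assert res.nps2d.sum() * bin_area == pytest.approx(2500.0, rel=0.05)

    def test_radial_average_conserves_power(self, rng):
        img = Image2D(np.abs(rng.normal(5000.0, 50.0, (400, 400))))
        res = compute_nps(img, roi_size=100)
        # samples inside complete annuli, reconstructed from bin counts
        total_radial = float((res.radial_values * res.bin_counts).sum())
        fy = np.fft.fftshift(np.fft.fftfreq(100, d=0.5))
        rr = np.hypot(fy[:, None], fy[None, :])
        bw = res.radial_freqs[1] - res.radial_freqs[0]
        mask = np.rint(rr / bw) * bw <= np.abs(fy).max() + 1e-12
        assert total_radial == pytest.approx(float(res.nps2d[mask].sum()), rel=0.02)

    def test_too_few_rois_rejected(self):
        with pytest.raises(ValueError):
            compute_nps(Image2D(np.ones((100, 100))), roi_size=100)

    def test_region_smaller_than_roi_rejected(self):
        with pytest.raises(ValueError):
            compute_nps(Image2D(np.ones((200, 200))), roi_size=100, region=(0, 0, 80, 80))
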
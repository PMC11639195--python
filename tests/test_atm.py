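"""Adaptive trimmed mean: window-function identities, parameter
adaptation endpoints, and a literal per-pixel oracle."""

import math

import numpy as np
import pytest
from scipy.ndimage import uniform_filter

from cherenkov_denoise import Image2D
from cherenkov_denoise.filters import ATMParams, atm, atm_local_params, trimmed_mean_window


class TestTrimmedMeanWindow:
    def test_alpha_zero_is_plain_mean(self):
        assert trimmed_mean_window(range(1, 10), 0.0) == 5.0

    def test_alpha_half_is_median(self):
        assert trimmed_mean_window(range(1, 10), 0.5) == 5.0
        assert trimmed_mean_window([1, 1, 1, 1, 9, 9, 9, 9, 100], 0.5) == 9.0

    def test_sort_trim_average_by_hand(self):
        # ceil(0.12 * 9) = 2 trimmed per end -> mean(3, 4, 5, 6, 7) = 5
        assert trimmed_mean_window([1, 2, 3, 4, 5, 6, 7, 8, 100], 0.12) == 5.0

    def test_unsorted_input_is_sorted_first(self):
        assert trimmed_mean_window([100, 8, 1, 6, 3, 7, 2, 5, 4], 0.12) == 5.0

    def test_alpha_outside_domain_rejected(self):
        with pytest.raises(ValueError):
            trimmed_mean_window([1, 2, 3], 0.6)


class TestAdaptation:
    def test_low_signal_gets_maximum_window(self):
        # any signal below delta has p(x - delta) = 0 -> window size beta
        x = np.full((40, 40), 3.0)
        x[20, 20] = 1000.0
        m, _ = atm_local_params(Image2D(x), ATMParams(beta=31, lam=2.0, delta=5.0))
        assert np.all(m[x == 3.0] == 31)

    def test_brightest_pixel_gets_median_trim_at_lam_two(self):
        x = np.linspace(1, 500, 100).reshape(10, 10)
        _, alpha = atm_local_params(Image2D(x), ATMParams(lam=2.0))
        assert alpha.flat[np.argmax(x)] == 0.5

    def test_window_rounding_is_odd_ties_upward(self):
        # M(x) real values map to nearest odd with even values going up
        x = np.array([[0.0, 1000.0]])
        m, _ = atm_local_params(Image2D(x), ATMParams(beta=31, lam=2.0))
        assert np.all(m % 2 == 1)
        assert np.all((m >= 3) & (m <= 31))


def _atm_oracle(pixels: np.ndarray, beta: int, lam: float, delta: float) -> np.ndarray:
    """Literal per-pixel re-evaluation of the adaptive trimmed mean:
    window-size and trim-fraction formulas, ceiling trim counts, sort /
    zero-weight / average, all written out independently."""
    mx = pixels.max()
    pad = beta // 2
    v = np.pad(pixels, pad, mode="symmetric")
    out = np.empty_like(pixels)
    for i in range(pixels.shape[0]):
        for j in range(pixels.shape[1]):
            x = pixels[i, j]
            pos = x - delta if x - delta > 0 else 0.0
            m_real = (2 * beta * lam * mx) / (2 * lam * mx + beta * pos)
            m = int(2 * math.floor(m_real / 2.0) + 1)
            m = min(max(m, 3), beta)
            alpha = min(max(x / (lam * mx), 0.0), 0.5)
            half = m // 2
            ci, cj = i + pad, j + pad
            window = np.sort(
                v[ci - half : ci + half + 1, cj - half : cj + half + 1].ravel()
            )
            n = m * m
            k = math.ceil(round(alpha * n, 9))
            if n - 2 * k <= 0:
                out[i, j] = window[n // 2]
            else:
                out[i, j] = window[k : n - k].mean()
    return out


def test_atm_matches_literal_oracle_on_two_level_image():
    x = np.full((21, 21), 1000.0)
    x[10, 10] = 4000.0
    p = ATMParams(beta=31, lam=2.0, delta=5.0)
    got = atm(Image2D(x), p).pixels
    want = _atm_oracle(x, 31, 2.0, 5.0)
    assert np.array_equal(got, want)


def test_atm_matches_oracle_on_noisy_image(rng):
    x = np.abs(rng.normal(200.0, 60.0, (20, 20)))
    p = ATMParams(beta=9, lam=3.0, delta=5.0)
    got = atm(Image2D(x), p).pixels
    want = _atm_oracle(x, 9, 3.0, 5.0)
    assert np.allclose(got, want, rtol=1e-12, atol=1e-9)


def test_all_zero_image_unchanged():
    img = Image2D(np.zeros((10, 10)))
    out = atm(img, ATMParams())
    assert np.array_equal(out.pixels, img.pixels)


def test_constant_image_is_fixed_point():
    img = Image2D(np.full((15, 15), 123.0))
    out = atm(img, ATMParams(beta=7, lam=2.0))
    assert np.array_equal(out.pixels, img.pixels)


def test_huge_lambda_approaches_box_mean(rng):
    """As lam grows every window reaches beta and trimming shrinks to
    the single ceiling-forced element per end, so the filter matches
    the box mean up to that rounding rule."""
    beta = 9
    x = np.abs(rng.normal(1000.0, 50.0, (24, 24))) + 100.0
    out = atm(Image2D(x), ATMParams(beta=beta, lam=1e9, delta=5.0)).pixels
    box = uniform_filter(x, size=beta, mode="reflect")  # matches symmetric padding
    assert np.abs(out - box).max() <= 5e-3 * x.mean()


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        ATMParams(beta=8).validate()
    with pytest.raises(ValueError):
        ATMParams(lam=1.5).validate()
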
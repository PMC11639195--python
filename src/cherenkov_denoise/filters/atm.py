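"""Adaptive (alpha-)trimmed mean filtering.

A trimmed mean over an M x M window sorts the window values, discards
the ceil(alpha * M^2) smallest and largest entries and averages the
rest; alpha = 0 is the plain box mean, alpha -> 0.5 degenerates to the
median.  Originating in CT streak suppression, the adaptive variant
ties both parameters to the local signal level so that dim pixels -
where photon starvation dominates - receive large windows and heavy
trimming while bright pixels are nearly untouched:

    M(x)     = 2*beta*lam*Max / (2*lam*Max + beta * p(x - delta))
    alpha(x) = x / (lam * Max)            (clipped to [0, 0.5])

with Max the image maximum, p(z) = max(z, 0), beta the largest allowed
window, delta a low-signal cutoff (anything below delta gets the full
beta window) and lam >= 2 the aggressiveness (larger lam = milder).
M(x) is rounded to the nearest odd integer (ties upward) and clipped to
[3, beta].

Note the ceiling in the trim count: for any alpha > 0 at least one
element is trimmed from each end, so the exact box-mean limit is
attained only at alpha = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ..image import Image2D

__all__ = ["ATMParams", "trimmed_mean_window", "atm", "atm_local_params"]

_CHUNK = 4096  # pixels per vectorized batch; bounds peak memory


@dataclass(frozen=True)
class ATMParams:
    beta: int = 31  # maximum window size (odd)
    lam: float = 4.0  # aggressiveness; >= 2 so alpha <= 0.5
    delta: float = 5.0  # low-signal cutoff, counts

    def validate(self) -> None:
        if self.beta < 3 or self.beta % 2 == 0:
            raise ValueError("beta must be odd and >= 3")
        if not self.lam >= 2:
            raise ValueError("lam must be >= 2 (keeps alpha <= 0.5)")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")


def _trim_count(alpha: float, n: int) -> int:
    # ceil(alpha * n), guarded against float fuzz in exact products
    return int(math.ceil(round(alpha * n, 9)))


def trimmed_mean_window(values, alpha: float) -> float:
    """Trimmed mean of one window's values.

    Sorts ascending, zero-weights the ceil(alpha*n) entries at each
    end, averages the rest with uniform weight.  If trimming removes
    everything (alpha at the 0.5 endpoint), returns the median element.
    """
    if not (0.0 <= alpha <= 0.5):
        raise ValueError("alpha must lie in [0, 0.5]")
    x = np.sort(np.asarray(values, dtype=np.float64).ravel())
    n = x.size
    k = _trim_count(alpha, n)
    if n - 2 * k <= 0:
        return float(x[n // 2])
    return float(x[k : n - k].mean())


def atm_local_params(img: Image2D, p: ATMParams) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel window size (odd int) and trim fraction maps."""
    p.validate()
    x = img.pixels
    mx = float(x.max())
    if mx == 0:
        raise ValueError("all-zero image has no adaptive parameters")
    pos = np.maximum(x - p.delta, 0.0)
    m_real = (2.0 * p.beta * p.lam * mx) / (2.0 * p.lam * mx + p.beta * pos)
    # nearest odd integer, ties upward, clipped to [3, beta]
    m = 2 * np.floor(m_real / 2.0) + 1
    m = np.clip(m, 3, p.beta).astype(np.intp)
    alpha = np.clip(x / (p.lam * mx), 0.0, 0.5)
    return m, alpha


def atm(img: Image2D, p: ATMParams) -> Image2D:
    """Adaptive trimmed mean over per-pixel windows.

    Equivalent to applying :func:`trimmed_mean_window` at every pixel
    with the locally adapted (M, alpha); implemented by grouping pixels
    with equal window size and sorting their windows in batches.
    """
    p.validate()
    x = img.pixels
    if float(x.max()) == 0.0:
        return img.copy()
    m_map, a_map = atm_local_params(img, p)
    pad = p.beta // 2
    padded = np.pad(x, pad, mode="symmetric")
    out = np.empty_like(x)
    h, w = x.shape
    for m in np.unique(m_map):
        ii, jj = np.nonzero(m_map == m)
        n = int(m) * int(m)
        win = sliding_window_view(padded, (int(m), int(m)))
        off = pad - int(m) // 2
        for s in range(0, ii.size, _CHUNK):
            ib, jb = ii[s : s + _CHUNK], jj[s : s + _CHUNK]
            block = win[ib + off, jb + off].reshape(ib.size, n)
            block = np.sort(block, axis=1)
            csum = np.cumsum(block, axis=1)
            k = np.ceil(np.round(a_map[ib, jb] * n, 9)).astype(np.intp)
            keep = n - 2 * k
            hi = n - k
            total = csum[np.arange(ib.size), hi - 1]
            total -= np.where(k > 0, csum[np.arange(ib.size), np.maximum(k - 1, 0)], 0.0)
            vals = np.where(keep > 0, total / np.maximum(keep, 1), block[:, n // 2])
            out[ib, jb] = vals
    return img.with_pixels(out, filter="atm", beta=p.beta, lam=p.lam, delta=p.delta)
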
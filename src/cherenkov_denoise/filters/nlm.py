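"""Non-local means denoising: literal formulation and fast variant.

Both estimate each pixel as a similarity-weighted average of pixels in a
search window, the weight of a candidate being
``exp(-SSD(patch_s, patch_t) / sigma^2)`` with SSD summed over a small
patch (uniform patch kernel).  ``nlm_bruteforce`` evaluates this
definition directly per pixel and serves as the oracle.  ``nlm_fast``
computes, for every window shift d, the patch SSD of the whole image
against its d-shifted copy via an integral image of squared
differences, then accumulates one weighted shifted image per d - the
standard vectorized scheme.  The two agree to floating-point rounding.

Conventions (recorded explicitly because the usual "20x20 window /
4x4 patch" sizes are even): window and patch are centered half-sizes
``window // 2`` and ``patch // 2`` applied symmetrically, giving odd
effective supports (21 and 5 for the defaults).  The self term
d = (0, 0) enters with weight exp(0) = 1.  Boundaries use mirror
padding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..image import Image2D

__all__ = ["NLMParams", "nlm_bruteforce", "nlm_fast"]


@dataclass(frozen=True)
class NLMParams:
    sigma: float = 5000.0  # denoising aggressiveness, in image count units
    window: int = 20  # search-window side; half-size window // 2
    patch: int = 4  # patch side; half-size patch // 2

    def validate(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")
        if self.patch < 1 or self.window < self.patch:
            raise ValueError("need window >= patch >= 1")


def _half_sizes(p: NLMParams) -> tuple[int, int]:
    return p.window // 2, p.patch // 2


def nlm_bruteforce(img: Image2D, p: NLMParams, gaussian_patch: bool = False) -> Image2D:
    """Direct per-pixel evaluation of the weighted-average definition.

    With ``gaussian_patch`` the patch SSD is weighted by a Gaussian
    kernel (the original formulation's G); the default uniform kernel
    matches the fast variant.
    """
    p.validate()
    hw, hp = _half_sizes(p)
    v = np.pad(img.pixels, hw + hp, mode="symmetric")
    h, w = img.shape
    out = np.empty((h, w))
    if gaussian_patch:
        ax = np.arange(-hp, hp + 1, dtype=np.float64)
        kern = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2.0 * max(hp / 2.0, 0.5) ** 2))
    else:
        kern = np.ones((2 * hp + 1, 2 * hp + 1))
    sig2 = p.sigma**2
    side = 2 * hp + 1
    from numpy.lib.stride_tricks import sliding_window_view

    for i in range(h):
        for j in range(w):
            ci, cj = i + hw + hp, j + hw + hp
            target = v[ci - hp : ci + hp + 1, cj - hp : cj + hp + 1]
            neigh = v[ci - hw - hp : ci + hw + hp + 1, cj - hw - hp : cj + hw + hp + 1]
            cands = sliding_window_view(neigh, (side, side))  # (2hw+1, 2hw+1, side, side)
            ssd = np.einsum("ab,ijab->ij", kern, (cands - target) ** 2)
            wgt = np.exp(-ssd / sig2)
            centers = neigh[hp : hp + 2 * hw + 1, hp : hp + 2 * hw + 1]
            out[i, j] = float(np.sum(wgt * centers) / np.sum(wgt))
    return img.with_pixels(out, filter="nlm_bruteforce", sigma=p.sigma)


def _box_sum(a: np.ndarray, hp: int) -> np.ndarray:
    """Sum of a over (2hp+1)^2 boxes, valid mode, via an integral image."""
    S = np.zeros((a.shape[0] + 1, a.shape[1] + 1))
    S[1:, 1:] = a.cumsum(axis=0).cumsum(axis=1)
    side = 2 * hp + 1
    return (
        S[side:, side:] - S[:-side, side:] - S[side:, :-side] + S[:-side, :-side]
    )


def nlm_fast(img: Image2D, p: NLMParams) -> Image2D:
    """Integral-image non-local means; value-identical to the oracle."""
    p.validate()
    hw, hp = _half_sizes(p)
    r = hw + hp
    v = np.pad(img.pixels, r, mode="symmetric")
    h, w = img.shape
    acc = np.zeros((h, w))
    zsum = np.zeros((h, w))
    sig2 = p.sigma**2
    # region whose squared differences feed any patch of an original pixel
    for di in range(-hw, hw + 1):
        for dj in range(-hw, hw + 1):
            base = v[r - hp : r + h + hp, r - hp : r + w + hp]
            shifted = v[
                r - hp + di : r + h + hp + di, r - hp + dj : r + w + hp + dj
            ]
            sq = (base - shifted) ** 2
            ssd = _box_sum(sq, hp)  # (h, w): patch SSD at every pixel
            wgt = np.exp(-ssd / sig2)
            centers = v[r + di : r + h + di, r + dj : r + w + dj]
            acc += wgt * centers
            zsum += wgt
    return img.with_pixels(acc / zsum, filter="nlm", sigma=p.sigma)
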
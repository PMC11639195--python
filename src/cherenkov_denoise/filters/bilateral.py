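"""Bilateral filtering: joint domain (spatial) and range (intensity)
Gaussian weighting.

Each output pixel is a normalized weighted mean over a square support,
the weight of neighbor q being
``exp(-|p - q|^2 / (2 sigma_s^2)) * exp(-(I(p) - I(q))^2 / (2 sigma_r^2))``.
The domain kernel smooths homogeneous regions; the range kernel
suppresses contributions across intensity edges, preserving them.  As
sigma_r -> infinity the range kernel flattens and the filter reduces to
a truncated Gaussian blur of scale sigma_s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ..image import Image2D

__all__ = ["BilateralParams", "bilateral"]


@dataclass(frozen=True)
class BilateralParams:
    sigma_s: float = 6.0  # pixels, geometric closeness scale
    sigma_r: float = 1000.0  # counts, intensity similarity scale
    window: int | None = None  # support side; default 2*ceil(2*sigma_s)+1

    def validate(self) -> None:
        if not (self.sigma_s > 0 and self.sigma_r > 0):
            raise ValueError("sigma_s and sigma_r must be > 0")
        if self.window is not None and (self.window < 1 or self.window % 2 == 0):
            raise ValueError("window must be odd and >= 1")

    @property
    def support(self) -> int:
        if self.window is not None:
            return self.window
        return 2 * math.ceil(2.0 * self.sigma_s) + 1


def bilateral(img: Image2D, p: BilateralParams) -> Image2D:
    """Edge-preserving weighted mean (shift-and-accumulate over offsets)."""
    p.validate()
    x = img.pixels
    half = p.support // 2
    v = np.pad(x, half, mode="symmetric")
    h, w = x.shape
    acc = np.zeros((h, w))
    wsum = np.zeros((h, w))
    inv_2ss = 1.0 / (2.0 * p.sigma_s**2)
    inv_2sr = 1.0 / (2.0 * p.sigma_r**2)
    for di in range(-half, half + 1):
        for dj in range(-half, half + 1):
            gs = math.exp(-(di * di + dj * dj) * inv_2ss)
            shifted = v[half + di : half + h + di, half + dj : half + w + dj]
            gr = np.exp(-((shifted - x) ** 2) * inv_2sr)
            wgt = gs * gr
            acc += wgt * shifted
            wsum += wgt
    return img.with_pixels(
        acc / wsum, filter="bilateral", sigma_s=p.sigma_s, sigma_r=p.sigma_r
    )
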
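"""Core image container and file IO.

Cumulative Cherenkov images are nonnegative 2D grids of summed photon
counts with a physical pixel pitch in the object plane.  The pitch is
carried with the pixels so that noise-power spectra can be reported in
mm^-1 without re-threading acquisition metadata through every call.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["Image2D", "save_image", "load_image"]


@dataclass
class Image2D:
    """A nonnegative 2D intensity grid with object-plane pixel pitch.

    Parameters
    ----------
    pixels
        H x W array of finite, nonnegative intensities (summed-count
        units; float64 internally).
    pixel_pitch
        Physical size of one pixel in the object plane, mm per pixel,
        as ``(dy, dx)``.
    meta
        Free-form provenance metadata (scene/acquisition parameters,
        processing history).  Not interpreted by the numerics.
    """

    pixels: np.ndarray
    pixel_pitch: tuple[float, float] = (0.5, 0.5)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("pixels must be a 2D array with H, W >= 1")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("pixels must be nonnegative")
        dy, dx = self.pixel_pitch
        if not (dy > 0 and dx > 0):
            raise ValueError("pixel_pitch must be positive")
        self.pixel_pitch = (float(dy), float(dx))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray, **meta) -> "Image2D":
        """New image sharing this image's pitch; negatives are clipped.

        Filters use this so that tiny negative excursions from
        frequency-domain shrinkage never violate the nonnegativity
        invariant.
        """
        return Image2D(
            np.maximum(np.asarray(pixels, dtype=np.float64), 0.0),
            self.pixel_pitch,
            {**self.meta, **meta},
        )

    def copy(self) -> "Image2D":
        return Image2D(self.pixels.copy(), self.pixel_pitch, dict(self.meta))


def save_image(img: Image2D, path: str | Path) -> None:
    """Write a lossless 32-bit float TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, img.pixels.astype(np.float32))
    sidecar = {"pixel_pitch_mm": list(img.pixel_pitch), "meta": _jsonable(img.meta)}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True)
    )


def load_image(path: str | Path) -> Image2D:
    """Read a TIFF written by :func:`save_image` (sidecar optional)."""
    path = Path(path)
    pixels = tifffile.imread(path)
    pitch = (0.5, 0.5)
    meta: dict = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        data = json.loads(sidecar.read_text())
        pitch = tuple(data.get("pixel_pitch_mm", pitch))
        meta = data.get("meta", {})
    return Image2D(np.maximum(pixels, 0.0), pitch, meta)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
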
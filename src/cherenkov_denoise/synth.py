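"""Synthetic cumulative Cherenkov image generator.

The study's camera data (time-gated frames of a silicone phantom under a
linac beam, summed into cumulative images) is emulated here.  A scene is
a per-frame photon expectation map: a smooth beam plateau with vignette
falloff on a phantom silhouette, cut by a slanted occluder edge used
later for sharpness analysis.  Each simulated frame draws Poisson shot
noise on (scene + ambient background), adds Gaussian read noise and
sparse stray-radiation impulses, then passes through the camera-side
preprocessing the acquisition software applies (temporal median across
frames, spatial median per frame, background subtraction).  Frames are
summed into the cumulative image; the delivered linac output in MU is
proportional to the number of frames accumulated.

The noise level of an acquisition is therefore controlled exactly as in
the real system: a 9000 MU accumulation serves as the low-noise ground
truth, while 25 MU / 50 MU accumulations provide the noisy test images.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import median_filter

from .image import Image2D

__all__ = [
    "SceneSpec",
    "NoiseModel",
    "AcquisitionSpec",
    "make_truth_scene",
    "simulate_cumulative",
    "make_dataset",
]

logger = logging.getLogger(__name__)

#: default object-plane pixel pitch (mm/px); configurable, and flagged in
#: all NPS outputs since the real camera's object-plane sampling depends
#: on mounting geometry.
DEFAULT_PIXEL_PITCH = (0.5, 0.5)


@dataclass(frozen=True)
class SceneSpec:
    """Geometry and per-frame intensity of a synthetic phantom scene."""

    height: int = 256
    width: int = 256
    field_level: float = 2.0  # expected photons/pixel/frame on the plateau
    background_level: float = 0.5  # ambient photons/pixel/frame
    edge_angle: float = 5.0  # degrees of the occluder edge from vertical
    edge_position: float = 0.55  # fraction of width where the edge sits
    vignette_sigma: float = 160.0  # px; smooth falloff of the beam field
    phantom_margin: int = 16  # px of zero-signal border

    def validate(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("scene dimensions must be >= 1")
        if not (2.0 <= self.edge_angle <= 12.0):
            raise ValueError(
                "edge_angle must lie in [2, 12] degrees: slanted-edge "
                "sharpness analysis assumes a near-vertical tilted edge"
            )
        if not self.field_level >= 0:
            raise ValueError("field_level must be nonnegative")
        if self.field_level == 0:
            # allowed (zero-source scene) but the sharpness pipeline
            # will reject the resulting flat image
            pass
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")
        if self.vignette_sigma <= 0:
            raise ValueError("vignette_sigma must be > 0")
        if self.phantom_margin < 0 or 2 * self.phantom_margin >= min(
            self.height, self.width
        ):
            raise ValueError("phantom_margin leaves no interior")


@dataclass(frozen=True)
class NoiseModel:
    """Per-frame stochastic camera model.

    ``temporal_median_window`` / ``spatial_median_size`` emulate the
    camera acquisition software's built-in filtering; 1 disables a
    stage.  ``impulse_rate`` models stray x-ray photons striking the
    sensor; impulses only ever add signal (salt noise), with amplitudes
    drawn uniformly in ``impulse_amp`` so single hits saturate locally.
    """

    read_sigma: float = 0.5  # counts/frame, Gaussian read noise
    impulse_rate: float = 1e-4  # per pixel per frame
    impulse_amp: tuple[float, float] = (30.0, 80.0)  # counts
    temporal_median_window: int = 3  # odd frame count; 1 = disabled
    spatial_median_size: int = 3  # odd kernel size; 1 = disabled
    subtract_background: bool = True

    def validate(self) -> None:
        if self.read_sigma < 0:
            raise ValueError("read_sigma must be >= 0")
        if not (0.0 <= self.impulse_rate <= 0.05):
            raise ValueError("impulse_rate must lie in [0, 0.05]")
        lo, hi = self.impulse_amp
        if not (0 <= lo <= hi):
            raise ValueError("impulse_amp bounds must satisfy 0 <= lo <= hi")
        for w in (self.temporal_median_window, self.spatial_median_size):
            if w < 1 or w % 2 == 0:
                raise ValueError("median windows must be odd and >= 1")


@dataclass(frozen=True)
class AcquisitionSpec:
    """Frame counts and seed for one truth/noisy dataset.

    MU level is proportional to frame count: ``mu = frames * mu_per_frame``.
    """

    frames_truth: int = 1800  # 9000 MU at 5 MU/frame
    frames_noisy: int = 5  # 25 MU
    mu_per_frame: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if self.frames_truth < 1 or self.frames_noisy < 1:
            raise ValueError("frame counts must be >= 1")
        if self.frames_noisy > self.frames_truth:
            raise ValueError("frames_noisy must be <= frames_truth")
        if self.mu_per_frame <= 0:
            raise ValueError("mu_per_frame must be > 0")


def make_truth_scene(
    spec: SceneSpec, pixel_pitch: tuple[float, float] = DEFAULT_PIXEL_PITCH
) -> Image2D:
    """Noiseless per-frame photon expectation map of the scene.

    Smooth plateau with Gaussian vignette falloff, zero outside the
    phantom margin, zero on the occluded side of the slanted edge.
    Deterministic in ``spec``.
    """
    spec.validate()
    h, w = spec.height, spec.width
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    vignette = np.exp(
        -((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * spec.vignette_sigma**2)
    )
    # occluder edge: line x = x0 + tan(theta) * (y - cy); the lit field
    # is on the low-x side, the occluded side is dark
    x_edge = spec.edge_position * w + math.tan(math.radians(spec.edge_angle)) * (
        yy - cy
    )
    lit = (xx < x_edge).astype(np.float64)
    img = spec.field_level * vignette * lit
    m = spec.phantom_margin
    if m > 0:
        img[:m, :] = 0.0
        img[-m:, :] = 0.0
        img[:, :m] = 0.0
        img[:, -m:] = 0.0
    return Image2D(img, pixel_pitch, {"scene": spec.__dict__.copy()})


def _frame_rng(seed: int, frame: int) -> np.random.Generator:
    # one stream per dataset, split per frame by counter: frame-count
    # changes never reshuffle earlier frames
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(frame,)))


def _raw_frame(
    expect: np.ndarray, spec_background: float, noise: NoiseModel, rng: np.random.Generator
) -> np.ndarray:
    frame = rng.poisson(expect + spec_background).astype(np.float64)
    if noise.read_sigma > 0:
        frame += rng.normal(0.0, noise.read_sigma, size=frame.shape)
    if noise.impulse_rate > 0:
        hits = rng.random(frame.shape) < noise.impulse_rate
        if hits.any():
            lo, hi = noise.impulse_amp
            frame[hits] += rng.uniform(lo, hi, size=int(hits.sum()))
    return frame


def simulate_cumulative(
    truth: Image2D,
    acq: AcquisitionSpec,
    noise: NoiseModel,
    frames: int | None = None,
    background_level: float | None = None,
) -> Image2D:
    """Simulate one cumulative acquisition from a per-frame expectation map.

    For each frame: Poisson counts on (truth + background), Gaussian read
    noise, stray-radiation impulses; then the camera preprocessing chain
    (centered rolling temporal median with window truncation at the ends,
    spatial median per frame, subtraction of the configured background
    expectation); frames are summed and the sum clipped at zero.
    """
    acq.validate()
    noise.validate()
    expect = truth.pixels
    if not np.all(np.isfinite(expect)):
        raise ValueError("truth must be finite")
    n_frames = acq.frames_noisy if frames is None else int(frames)
    if background_level is None:
        background_level = float(truth.meta.get("scene", {}).get("background_level", 0.0))

    t_win = noise.temporal_median_window
    if t_win > n_frames:
        logger.warning(
            "temporal median window %d exceeds frame count %d; disabling", t_win, n_frames
        )
        t_win = 1
    half = t_win // 2

    def _postprocess(frame: np.ndarray) -> np.ndarray:
        if noise.spatial_median_size > 1:
            frame = median_filter(frame, size=noise.spatial_median_size, mode="mirror")
        if noise.subtract_background:
            frame = frame - background_level
        return frame

    total = np.zeros_like(expect)
    # streaming centered temporal median: frame t is emitted once raw
    # frames t-half .. t+half exist (window truncated at both ends), so
    # at most t_win raw frames are held in memory at a time
    buffer: dict[int, np.ndarray] = {}
    emitted = 0
    for f in range(n_frames):
        buffer[f] = _raw_frame(expect, background_level, noise, _frame_rng(acq.seed, f))
        while emitted < n_frames and min(emitted + half, n_frames - 1) <= f:
            lo = max(0, emitted - half)
            hi = min(n_frames - 1, emitted + half)
            if t_win == 1:
                med = buffer[emitted]
            else:
                med = np.median([buffer[k] for k in range(lo, hi + 1)], axis=0)
            total += _postprocess(med)
            emitted += 1
            next_lo = max(0, emitted - half)
            for k in [k for k in buffer if k < next_lo]:
                del buffer[k]
    out = np.maximum(total, 0.0)
    meta = {
        **truth.meta,
        "frames": n_frames,
        "mu": n_frames * acq.mu_per_frame,
        "seed": acq.seed,
        "noise": noise.__dict__.copy(),
    }
    return Image2D(out, truth.pixel_pitch, meta)


def make_dataset(
    spec: SceneSpec,
    acq: AcquisitionSpec,
    noise: NoiseModel,
    analytic_truth: bool = False,
    pixel_pitch: tuple[float, float] = DEFAULT_PIXEL_PITCH,
) -> tuple[Image2D, Image2D]:
    """Generate a (ground truth, noisy) cumulative image pair.

    The truth is a ``frames_truth`` accumulation (by default simulated
    through the same camera pipeline, so camera-side median bias is
    common to both images; set ``analytic_truth`` to use the noiseless
    expectation times ``frames_truth``, flagged in metadata).  The noisy
    image is a ``frames_noisy`` accumulation rescaled by
    ``frames_truth / frames_noisy`` so both share one intensity scale.
    """
    spec.validate()
    acq.validate()
    scene = make_truth_scene(spec, pixel_pitch)
    if analytic_truth:
        truth = Image2D(
            scene.pixels * acq.frames_truth,
            pixel_pitch,
            {**scene.meta, "analytic_truth": True, "mu": acq.frames_truth * acq.mu_per_frame},
        )
    else:
        truth = simulate_cumulative(scene, acq, noise, frames=acq.frames_truth)
    noisy = simulate_cumulative(scene, acq, noise, frames=acq.frames_noisy)
    scale = acq.frames_truth / acq.frames_noisy
    noisy = Image2D(noisy.pixels * scale, noisy.pixel_pitch, {**noisy.meta, "scale": scale})
    return truth, noisy


def acquisition_for_mu(acq: AcquisitionSpec, mu: float) -> AcquisitionSpec:
    """Acquisition with ``frames_noisy`` chosen to deliver ``mu`` MU."""
    frames = max(1, round(mu / acq.mu_per_frame))
    return replace(acq, frames_noisy=frames)
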
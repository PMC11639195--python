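"""Image-quality metrics: PSNR, slanted-edge sharpness, noise power
spectrum.

PSNR compares a test image against the low-noise ground truth as
``20 log10(max(truth) / RMSE)`` (peak taken from the truth image; a
data-type peak can be supplied instead, and the two conventions give
different numbers).

Sharpness uses the slanted-edge method: the 50%-crossing of each row of
an edge ROI locates the edge line; projecting every ROI pixel onto the
edge normal and binning at 4x oversampling yields the edge spread
function (ESF); its derivative is the line spread function (LSF); the
normalized Fourier magnitude of the LSF is the modulation transfer
function (MTF), summarized by MTF50/MTF10 (frequencies at 50% / 10%
modulation, cycles/pixel) and by the 10-90% rise distance in pixels.

Noise texture is summarized by the 2D noise power spectrum averaged
over overlapping mean-subtracted ROIs,
``NPS(vx, vy) = dx*dy / (M*N^2) * sum_m |FFT2(ROI_m)|^2``
(units counts^2 mm^2), radially averaged into a 1D spectrum in mm^-1
with per-bin standard deviation across ROIs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .image import Image2D

__all__ = [
    "psnr",
    "ESFCurve",
    "MTFCurve",
    "NPSResult",
    "extract_esf",
    "esf_to_mtf",
    "mtf_summary",
    "rise_distance_10_90",
    "compute_nps",
]


# ---------------------------------------------------------------- PSNR

def psnr(truth: Image2D, test: Image2D, peak: float | None = None) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images."""
    if truth.shape != test.shape:
        raise ValueError("images must have identical shapes")
    t = truth.pixels
    if peak is None:
        peak = float(t.max())
        if peak == 0:
            raise ValueError("all-zero truth image: peak undefined")
    rmse = float(np.sqrt(np.mean((test.pixels - t) ** 2)))
    if rmse == 0:
        return math.inf
    return 20.0 * math.log10(peak / rmse)


# ----------------------------------------------------- slanted edge

@dataclass
class ESFCurve:
    """Oversampled edge profile: intensity vs. signed distance (px) from
    the fitted edge along its normal."""

    positions: np.ndarray
    values: np.ndarray
    oversampling: int = 4
    edge_angle_deg: float = float("nan")

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")


@dataclass
class MTFCurve:
    """Modulation vs. spatial frequency (cycles/pixel), MTF(0) = 1."""

    freqs: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if abs(self.values[0] - 1.0) > 1e-9:
            raise ValueError("MTF must be normalized to 1 at zero frequency")


class EdgeNotFoundError(ValueError):
    """Raised when an ROI does not contain a usable slanted edge."""


def _row_crossing(row: np.ndarray) -> float | None:
    """Sub-pixel column of the 50% crossing of one row, or None."""
    k = max(1, row.size // 10)
    lo = float(np.mean(row[:k]))
    hi = float(np.mean(row[-k:]))
    if abs(hi - lo) < 1e-12 or abs(hi - lo) < 0.05 * max(abs(hi), abs(lo), 1e-12):
        return None
    mid = 0.5 * (lo + hi)
    # light smoothing stabilizes the crossing under noise
    sm = np.convolve(row, np.ones(3) / 3.0, mode="same")
    signs = sm - mid
    if lo > hi:
        signs = -signs
    idx = np.nonzero((signs[:-1] < 0) & (signs[1:] >= 0))[0]
    if idx.size == 0:
        return None
    # use the crossing nearest the midpoint of the transition range
    centroid = np.argmin(np.abs(signs))
    i = idx[np.argmin(np.abs(idx - centroid))]
    d = signs[i + 1] - signs[i]
    frac = 0.0 if d == 0 else -signs[i] / d
    return float(i + frac)


def extract_esf(
    img: Image2D, roi: tuple[int, int, int, int], oversampling: int = 4
) -> ESFCurve:
    """Oversampled ESF from a near-vertical slanted edge.

    ``roi`` is (row0, col0, height, width).  Each row's 50% crossing is
    located, the edge line is fit by least squares, all ROI pixels are
    projected onto the edge normal and averaged in bins of
    1/oversampling pixel.
    """
    r0, c0, hh, ww = roi
    a = img.pixels[r0 : r0 + hh, c0 : c0 + ww]
    if a.shape != (hh, ww) or hh < 4 or ww < 4:
        raise ValueError("ROI out of bounds or too small")
    crossings = [(_row_crossing(a[r]), r) for r in range(hh)]
    good = [(c, r) for c, r in crossings if c is not None]
    if len(good) < 0.8 * hh:
        raise EdgeNotFoundError("no edge: monotone transition missing in >20% of rows")
    cols = np.array([c for c, _ in good])
    rows = np.array([r for _, r in good], dtype=np.float64)
    slope, intercept = np.polyfit(rows, cols, 1)
    angle = math.degrees(math.atan(slope))
    # signed distance along the edge normal (positive toward larger col)
    rr, cc = np.mgrid[0:hh, 0:ww].astype(np.float64)
    t = (cc - (intercept + slope * rr)) / math.hypot(1.0, slope)
    bins = np.floor(t * oversampling).astype(np.int64)
    order = np.argsort(bins.ravel(), kind="stable")
    b_sorted = bins.ravel()[order]
    v_sorted = a.ravel()[order]
    uniq, start = np.unique(b_sorted, return_index=True)
    sums = np.add.reduceat(v_sorted, start)
    counts = np.diff(np.append(start, b_sorted.size))
    positions = (uniq + 0.5) / oversampling
    return ESFCurve(positions, sums / counts, oversampling, angle)


def _uniform_esf(esf: ESFCurve) -> tuple[np.ndarray, np.ndarray]:
    dx = 1.0 / esf.oversampling
    grid = np.arange(esf.positions[0], esf.positions[-1] + dx / 2, dx)
    return grid, np.interp(grid, esf.positions, esf.values)


def _tapered_window(n: int, center: int) -> np.ndarray:
    """Hann-tapered (Tukey-style) window: flat over the central half of
    the distance to the nearest end from ``center``, cosine taper to 0
    at the ends.  Centered on the LSF peak so a well-resolved LSF is
    untouched while far tails are suppressed."""
    i = np.arange(n, dtype=np.float64)
    reach = np.where(i >= center, max(n - 1 - center, 1), max(center, 1))
    u = np.abs(i - center) / reach
    w = np.ones(n)
    tail = u > 0.5
    w[tail] = 0.5 * (1.0 + np.cos(np.pi * (u[tail] - 0.5) / 0.5))
    return w


def esf_to_mtf(esf: ESFCurve, min_halfspan: float = 20.0) -> MTFCurve:
    """MTF as the normalized Fourier magnitude of the windowed LSF.

    The LSF is the two-point finite difference of the oversampled ESF
    (centered on the half-sample grid); the Fourier magnitude is
    divided by the difference filter's own |sinc| response so that an
    ideal step reports a flat MTF up to the binning limit.
    """
    grid, vals = _uniform_esf(esf)
    span_lo = -grid[0]
    span_hi = grid[-1]
    if span_lo < min_halfspan or span_hi < min_halfspan:
        raise ValueError(
            f"ESF must cover >= {min_halfspan} px on both sides of the edge"
        )
    dx = 1.0 / esf.oversampling
    lsf = np.diff(vals) / dx
    peak = int(np.argmax(np.abs(lsf)))
    lsf = lsf * _tapered_window(lsf.size, peak)
    area = np.abs(lsf.sum())
    if area == 0:
        raise ValueError("zero LSF area: flat ESF")
    spec = np.abs(np.fft.rfft(lsf))
    freqs = np.fft.rfftfreq(lsf.size, d=dx)
    # correct the discrete-derivative frequency response
    spec = spec / np.sinc(freqs * dx)
    keep = freqs <= 0.5 + 1e-12
    return MTFCurve(freqs[keep], spec[keep] / spec[0])


def mtf_summary(mtf: MTFCurve) -> dict[str, float | None]:
    """First crossings of the 50% and 10% levels (cycles/pixel);
    ``None`` when a level is never reached below Nyquist."""

    def _first_crossing(level: float) -> float | None:
        v = mtf.values
        below = np.nonzero(v < level)[0]
        if below.size == 0 or below[0] == 0:
            return None
        i = below[0]
        f0, f1 = mtf.freqs[i - 1], mtf.freqs[i]
        v0, v1 = v[i - 1], v[i]
        return float(f0 + (level - v0) * (f1 - f0) / (v1 - v0))

    return {"mtf50": _first_crossing(0.5), "mtf10": _first_crossing(0.1)}


def rise_distance_10_90(esf: ESFCurve) -> float:
    """Distance (px) between the 10% and 90% crossings of the edge rise.

    Plateau levels come from the outer 10% of the profile on each side;
    crossings are located by scanning outward from the steepest point of
    the transition and interpolating linearly, so plateau noise away
    from the edge cannot masquerade as a crossing.
    """
    grid, vals = _uniform_esf(esf)
    k = max(1, vals.size // 10)
    lo = float(np.median(vals[:k]))
    hi = float(np.median(vals[-k:]))
    if lo > hi:
        vals = vals[::-1].copy()
        grid = -grid[::-1].copy()
        lo, hi = hi, lo
    span = hi - lo
    if span <= 0 or span < 0.05 * max(abs(hi), abs(lo), 1e-12):
        raise ValueError("plateaus not identifiable: no rise present")
    l10, l90 = lo + 0.1 * span, lo + 0.9 * span
    # steepest point of a lightly smoothed copy anchors the transition
    # (boundary samples excluded: the smoothing kernel is partial there)
    sm = np.convolve(vals, np.ones(3) / 3.0, mode="same")
    d = np.abs(np.diff(sm))
    d[:2] = 0.0
    d[-2:] = 0.0
    center = int(np.argmax(d)) + 1

    def _interp(i: int, j: int, level: float) -> float:
        d = vals[j] - vals[i]
        frac = 0.0 if d == 0 else (level - vals[i]) / d
        return float(grid[i] + frac * (grid[j] - grid[i]))

    i = center
    while i > 0 and vals[i] > l10:
        i -= 1
    if vals[i] > l10:
        raise ValueError("plateaus not identifiable: rise incomplete")
    x10 = _interp(i, i + 1, l10)
    j = center
    while j < vals.size - 1 and vals[j] < l90:
        j += 1
    if vals[j] < l90:
        raise ValueError("plateaus not identifiable: rise incomplete")
    x90 = _interp(j - 1, j, l90)
    return abs(x90 - x10)


# ------------------------------------------------------------- NPS

@dataclass
class NPSResult:
    """2D and radially averaged noise power spectrum."""

    nps2d: np.ndarray  # fftshifted, counts^2 mm^2
    radial_freqs: np.ndarray  # mm^-1
    radial_values: np.ndarray  # mean over ROIs of per-ROI radial means
    radial_std: np.ndarray  # std across ROIs per bin
    bin_counts: np.ndarray  # 2D-frequency samples per radial bin
    roi_size: int
    n_rois: int
    pixel_pitch: tuple[float, float]


def compute_nps(
    img: Image2D,
    roi_size: int = 100,
    overlap_fraction: float = 0.5,
    region: tuple[int, int, int, int] | None = None,
) -> NPSResult:
    """Noise power spectrum over overlapping square ROIs.

    Each ROI has its own mean subtracted (first-order detrend; the
    synthetic plateaus are flat so no polynomial fit is applied), its
    squared 2D FFT magnitude is scaled by ``dx*dy / N^2`` and averaged
    across ROIs; radial binning about zero frequency uses one
    2D-frequency sample spacing (1/(N*dx)) per bin.  All mm^-1 axes are
    conditional on the configured pixel pitch.
    """
    if not (0.0 <= overlap_fraction < 1.0):
        raise ValueError("overlap_fraction must lie in [0, 1)")
    dy, dx = img.pixel_pitch
    a = img.pixels
    if region is not None:
        r0, c0, hh, ww = region
        a = a[r0 : r0 + hh, c0 : c0 + ww]
        if a.shape != (hh, ww):
            raise ValueError("region out of bounds")
    n = int(roi_size)
    if a.shape[0] < n or a.shape[1] < n:
        raise ValueError("analysis region smaller than roi_size")
    stride = max(1, int(round(n * (1.0 - overlap_fraction))))
    rows = list(range(0, a.shape[0] - n + 1, stride))
    cols = list(range(0, a.shape[1] - n + 1, stride))
    rois = [(r, c) for r in rows for c in cols]
    if len(rois) < 2:
        raise ValueError("need at least 2 ROIs; enlarge region or overlap")

    scale = (dx * dy) / (n * n)
    # radial bin assignment (shared by all ROIs)
    fy = np.fft.fftshift(np.fft.fftfreq(n, d=dy))
    fx = np.fft.fftshift(np.fft.fftfreq(n, d=dx))
    rr = np.hypot(fy[:, None], fx[None, :])
    bw = 1.0 / (n * dx)
    bin_idx = np.rint(rr / bw).astype(np.int64)
    nbins = bin_idx.max() + 1
    flat_bins = bin_idx.ravel()
    counts2d = np.bincount(flat_bins, minlength=nbins)

    nps_acc = np.zeros((n, n))
    profiles = np.empty((len(rois), nbins))
    for m, (r, c) in enumerate(rois):
        sub = a[r : r + n, c : c + n]
        sub = sub - sub.mean()
        p2 = np.abs(np.fft.fft2(sub)) ** 2 * scale
        p2 = np.fft.fftshift(p2)
        nps_acc += p2
        profiles[m] = np.bincount(flat_bins, weights=p2.ravel(), minlength=nbins) / np.maximum(
            counts2d, 1
        )
    nps2d = nps_acc / len(rois)
    freqs = np.arange(nbins) * bw
    # keep only complete annuli: beyond the axis Nyquist the sampled
    # square truncates the ring and the radial mean becomes biased
    nyquist = min(np.abs(fy).max(), np.abs(fx).max())
    nonempty = (counts2d > 0) & (freqs <= nyquist + 1e-12)
    radial_mean = profiles.mean(axis=0)
    radial_std = profiles.std(axis=0, ddof=1)
    return NPSResult(
        nps2d=nps2d,
        radial_freqs=freqs[nonempty],
        radial_values=radial_mean[nonempty],
        radial_std=radial_std[nonempty],
        bin_counts=counts2d[nonempty],
        roi_size=n,
        n_rois=len(rois),
        pixel_pitch=img.pixel_pitch,
    )
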
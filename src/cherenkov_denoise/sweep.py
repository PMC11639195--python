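"""PSNR-driven parameter optimization for each denoiser.

Mirrors the study procedure: apply a filter at every point of a
per-filter parameter grid, score each output by PSNR against the
ground truth, and keep the maximizer.  Published ranges: TV-L1
lambda in [0.01, 3.5]; NLM sigma in (0, 7000]; BM3D sigma in
(0, 10000]; ATM lambda in [2, 14]; bilateral sigma_s in [1, 18] with
sigma_r from 100*v to 11000*v, v the variance of a background patch.
Sigma axes that nominally start at 0 begin at the smallest positive
grid value since the weight formulas divide by sigma^2.

Ties are broken toward the least aggressive setting (largest TV/ATM
lambda, smallest sigma) by evaluating grid points in
aggressiveness-ascending order and requiring strict improvement.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .filters import (
    ATMParams,
    BilateralParams,
    BM3DParams,
    NLMParams,
    TVParams,
    atm,
    bilateral,
    bm3d,
    nlm_fast,
    tv_l1,
)
from .image import Image2D
from .metrics import psnr

__all__ = ["SweepGrid", "SweepResult", "sweep_filter", "default_grid", "FILTERS", "apply_filter"]

logger = logging.getLogger(__name__)

#: filter_id -> (param dataclass, callable, tie-break sort key per axis)
#: sort keys order grid points from least to most aggressive
FILTERS: dict[str, tuple[type, callable]] = {
    "tvl1": (TVParams, tv_l1),
    "nlm": (NLMParams, nlm_fast),
    "bm3d": (BM3DParams, bm3d),
    "atm": (ATMParams, atm),
    "bilateral": (BilateralParams, bilateral),
}

# aggressiveness direction per parameter: +1 = larger is more aggressive
_AGGRESSIVENESS = {
    "tvl1": {"lam": -1},
    "nlm": {"sigma": +1},
    "bm3d": {"noise_sigma": +1},
    "atm": {"lam": -1},
    "bilateral": {"sigma_s": +1, "sigma_r": +1},
}


@dataclass(frozen=True)
class SweepGrid:
    filter_id: str
    axes: dict[str, tuple[float, ...]]

    def validate(self) -> None:
        if self.filter_id not in FILTERS:
            raise ValueError(f"unknown filter_id {self.filter_id!r}")
        if not self.axes or any(len(v) == 0 for v in self.axes.values()):
            raise ValueError("every axis must be non-empty")

    def points(self) -> list[dict[str, float]]:
        names = list(self.axes)
        out = [
            dict(zip(names, combo))
            for combo in itertools.product(*(self.axes[n] for n in names))
        ]
        direction = _AGGRESSIVENESS.get(self.filter_id, {})
        return sorted(
            out,
            key=lambda pt: tuple(direction.get(n, 1) * pt[n] for n in names),
        )


@dataclass
class SweepResult:
    filter_id: str
    records: list[dict] = field(default_factory=list)  # params + "psnr_db" (None on failure)
    best_params: dict | None = None
    best_psnr: float = -math.inf
    noisy_psnr: float = math.nan

    @property
    def percent_increase(self) -> float:
        return 100.0 * (self.best_psnr - self.noisy_psnr) / self.noisy_psnr


def apply_filter(img: Image2D, filter_id: str, overrides: dict) -> Image2D:
    """Run one filter with parameter overrides on its defaults."""
    cls, fn = FILTERS[filter_id]
    return fn(img, cls(**overrides))


def sweep_filter(
    truth: Image2D, noisy: Image2D, grid: SweepGrid, base_params: dict | None = None
) -> SweepResult:
    """Evaluate every grid point and return the full trace plus argmax.

    Individual filter failures are recorded as missing and excluded
    from the argmax; an all-missing sweep raises.
    """
    grid.validate()
    if truth.shape != noisy.shape:
        raise ValueError("truth and noisy images must be aligned")
    cls, fn = FILTERS[grid.filter_id]
    base = dict(base_params or {})
    result = SweepResult(grid.filter_id, noisy_psnr=psnr(truth, noisy))
    for pt in grid.points():
        rec = dict(pt)
        try:
            den = fn(noisy, cls(**{**base, **pt}))
            rec["psnr_db"] = psnr(truth, den)
        except Exception as exc:  # pragma: no cover - defensive per-point isolation
            logger.warning("%s failed at %s: %s", grid.filter_id, pt, exc)
            rec["psnr_db"] = None
        result.records.append(rec)
        if rec["psnr_db"] is not None and rec["psnr_db"] > result.best_psnr:
            result.best_psnr = rec["psnr_db"]
            result.best_params = dict(pt)
    if result.best_params is None:
        raise RuntimeError(f"all grid points failed for {grid.filter_id}")
    _warn_on_boundary(grid, result)
    return result


def _warn_on_boundary(grid: SweepGrid, result: SweepResult) -> None:
    for name, values in grid.axes.items():
        if len(values) < 3:
            continue
        v = result.best_params[name]
        if v in (min(values), max(values)):
            logger.warning(
                "sweep argmax for %s sits on the %s boundary (%g); "
                "consider extending the grid",
                grid.filter_id,
                name,
                v,
            )


def default_grid(
    filter_id: str,
    background_variance: float | None = None,
    n_points: int | tuple[int, int] | None = None,
) -> SweepGrid:
    """The study's published sweep ranges, discretized.

    ``n_points`` defaults to 15 per axis (10 x 10 for the bilateral 2D
    sweep); log spacing is used where a range spans decades.
    """
    if filter_id == "tvl1":
        n = n_points or 15
        axes = {"lam": tuple(np.geomspace(0.01, 3.5, n))}
    elif filter_id == "nlm":
        n = n_points or 15
        axes = {"sigma": tuple(np.linspace(0.0, 7000.0, n + 1)[1:])}
    elif filter_id == "bm3d":
        n = n_points or 15
        axes = {"noise_sigma": tuple(np.linspace(0.0, 10000.0, n + 1)[1:])}
    elif filter_id == "atm":
        n = n_points or 15
        axes = {"lam": tuple(np.linspace(2.0, 14.0, n))}
    elif filter_id == "bilateral":
        if not (background_variance and background_variance > 0):
            raise ValueError("bilateral grid requires background_variance > 0")
        if n_points is None:
            ns, nr = 10, 10
        elif isinstance(n_points, tuple):
            ns, nr = n_points
        else:
            ns = nr = n_points
        v = background_variance
        axes = {
            "sigma_s": tuple(np.linspace(1.0, 18.0, ns)),
            "sigma_r": tuple(np.geomspace(100.0 * v, 11000.0 * v, nr)),
        }
    else:
        raise ValueError(f"unknown filter_id {filter_id!r}")
    return SweepGrid(filter_id, axes)
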
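"""Two-mirror scan-voltage calibration.

The OPM scans its light sheet with two galvo mirrors whose drive
amplitudes are in a fixed ratio.  The ratio sets the axial position of
the scan pivot point; only when the pivot sits in the primary
objective's pupil plane does the sheet keep a constant angle during the
scan, giving uniform illumination.  A mismatched ratio tilts the sheet
progressively as it scans, so the summed image intensity acquires a
linear trend with scan step.  The calibration procedure is:

1. for one mirror ratio, scan the volume, sum each frame's pixels,
   normalise by the mean, and fit intensity vs. step -> a slope;
2. sweep the ratio and fit slope vs. ratio -> the zero-slope ratio is
   the optimum for the current objective position;
3. repeat over objective Z positions and fit a line -> the calibration
   ``ratio_opt(z) = a + b*z`` used to retune the mirrors on the fly as
   the user focuses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scene import BeadStack

__all__ = [
    "RatioSweepResult",
    "CalibrationCurve",
    "NoCrossingError",
    "summed_intensity_series",
    "slope_for_ratio",
    "optimal_ratio",
    "calibration_curve",
]


class NoCrossingError(RuntimeError):
    """The slope-vs-ratio line has no usable zero crossing."""


def summed_intensity_series(
    series: BeadStack, offset: float = 0.0
) -> np.ndarray:
    """Mean-normalised per-step summed intensity of an oblique scan series.

    Each frame's pixels are summed; an optional constant camera offset
    (counts per pixel) is subtracted first, since a dark level biases
    the normalised slope.  The output has mean exactly 1.
    """
    if series.n_planes < 3:
        raise ValueError("series needs at least 3 steps")
    frames = series.voxels.astype(float)
    n_px = frames.shape[1] * frames.shape[2]
    totals = frames.reshape(series.n_planes, -1).sum(axis=1) - offset * n_px
    if np.any(totals <= 0):
        warnings.warn("non-positive frame total after offset subtraction", stacklevel=2)
    return totals / totals.mean()


def slope_for_ratio(values: np.ndarray) -> tuple[float, float]:
    """OLS slope (per step) of normalised intensity vs. step index."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 points")
    x = np.arange(v.size, dtype=float)
    (slope, intercept), cov = np.polyfit(x, v, 1, cov=True)
    return float(slope), float(math.sqrt(max(cov[0, 0], 0.0)))


@dataclass
class RatioSweepResult:
    """One voltage-ratio sweep at a fixed objective position."""

    objective_z: float
    entries: pd.DataFrame = field(repr=False)  # ratio, slope, slope_stderr
    ratio_opt: float = np.nan
    crossing_stderr: float = np.nan


def optimal_ratio(
    ratios: np.ndarray,
    slopes: np.ndarray,
    slope_stderrs: np.ndarray | None = None,
    objective_z: float = 0.0,
) -> RatioSweepResult:
    """Zero-slope voltage ratio from a sweep of (ratio, slope) pairs.

    Fits slope vs. ratio with OLS (the relationship is observed to be
    linear) and returns the ratio at which the line crosses zero, with
    its uncertainty propagated from the fit covariance.  Warns when the
    crossing extrapolates beyond the swept ratios.
    """
    rho = np.asarray(ratios, dtype=float)
    s = np.asarray(slopes, dtype=float)
    if rho.size < 2 or np.unique(rho).size < 2:
        raise ValueError("need >= 2 distinct ratios")
    if np.any(rho <= 0):
        raise ValueError("ratios must be > 0")
    if rho.size > 2:
        (b, a), cov = np.polyfit(rho, s, 1, cov=True)
    else:
        b, a = np.polyfit(rho, s, 1)
        cov = np.full((2, 2), np.nan)
    scale = float(np.abs(s).max()) if np.any(s) else 1.0
    if abs(b) < 1e-12 * max(scale, 1e-12):
        raise NoCrossingError("slope-vs-ratio line is flat; no zero crossing")
    rho0 = -a / b
    if not rho.min() <= rho0 <= rho.max():
        warnings.warn(
            f"optimal ratio {rho0:.4f} extrapolates beyond the sweep "
            f"[{rho.min():.4f}, {rho.max():.4f}]",
            stacklevel=2,
        )
    if np.all(np.isfinite(cov)):
        var = (cov[1, 1] + rho0**2 * cov[0, 0] + 2 * rho0 * cov[0, 1]) / b**2
        stderr = math.sqrt(max(var, 0.0))
    else:
        stderr = np.nan
    entries = pd.DataFrame(
        {
            "ratio": rho,
            "slope": s,
            "slope_stderr": slope_stderrs
            if slope_stderrs is not None
            else np.full(rho.size, np.nan),
        }
    )
    return RatioSweepResult(
        objective_z=objective_z,
        entries=entries,
        ratio_opt=float(rho0),
        crossing_stderr=float(stderr),
    )


@dataclass
class CalibrationCurve:
    """Linear calibration ``ratio_opt(z) = a + b*z`` over objective travel."""

    a: float
    b: float
    residuals: pd.DataFrame = field(repr=False)  # objective_z, ratio_opt, residual

    def predict(self, objective_z: float | np.ndarray) -> float | np.ndarray:
        """Optimal mirror ratio at an objective Z position (mm)."""
        out = self.a + self.b * np.asarray(objective_z, dtype=float)
        return float(out) if out.ndim == 0 else out


def calibration_curve(
    objective_z: np.ndarray, ratio_opts: np.ndarray
) -> CalibrationCurve:
    """Fit the mirror-ratio calibration line over objective positions."""
    z = np.asarray(objective_z, dtype=float)
    r = np.asarray(ratio_opts, dtype=float)
    if z.size < 2 or np.unique(z).size < 2:
        raise ValueError("need >= 2 distinct objective positions")
    b, a = np.polyfit(z, r, 1)
    resid = r - (a + b * z)
    residuals = pd.DataFrame(
        {"objective_z": z, "ratio_opt": r, "residual": resid}
    )
    return CalibrationCurve(a=float(a), b=float(b), residuals=residuals)
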
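"""Remote-focusing-volume distortion: depth-dependent magnification error.

Axial misconjugation of the primary and remote objectives makes the
apparent magnification change with imaging depth: beads appear to shift
radially, proportionally to their distance from the image centre.  This
module quantifies that distortion from bead measurements:

* match beads measured at depth Z to their reference at Z = 0 in polar
  coordinates (same angle, nearest radius);
* fit the radial displacement vs. radius through the origin -> the
  fractional magnification error at that depth;
* fit error vs. depth through the origin -> an error *rate* (%/µm) per
  remote-objective displacement;
* fit error rate vs. displacement -> the zero crossing, i.e. the optimal
  axial position of the remote objective.

Sign convention: positive error = apparent magnification increase.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .psf import BeadRecord, measure_psfs, records_to_frame
from .scene import BeadStack

__all__ = [
    "MatchedPairs",
    "DistortionProfile",
    "NoCrossingError",
    "match_beads_polar",
    "radial_displacement_rate",
    "magnification_error_profile",
    "optimal_remote_position",
]


class NoCrossingError(RuntimeError):
    """The fitted line has no usable zero crossing."""


@dataclass
class MatchedPairs:
    """Bead pairs matched between a reference and a probe depth."""

    r_ref: np.ndarray
    r_probe: np.ndarray

    @property
    def dr(self) -> np.ndarray:
        return self.r_probe - self.r_ref

    def __len__(self) -> int:
        return self.r_ref.size


def _as_polar_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = records_to_frame(list(records))
    if df.empty:
        return pd.DataFrame(columns=["r", "theta"])
    if "fit_ok" in df.columns:
        df = df[df["fit_ok"]]
    return df[["r", "theta"]].reset_index(drop=True)


def match_beads_polar(
    ref, probe, theta_tol: float = math.radians(2.0)
) -> MatchedPairs:
    """Match probe beads to reference beads with the same polar angle.

    For each probe bead, reference candidates within ``theta_tol``
    (circular difference) are considered and the one with the smallest
    radial separation is proposed; one-to-one assignment is then enforced
    greedily in order of ascending |Δr|.  Unmatched beads are dropped.
    Accepts lists of :class:`BeadRecord` or DataFrames with r/theta.
    """
    ref_df = _as_polar_frame(ref)
    probe_df = _as_polar_frame(probe)
    if ref_df.empty or probe_df.empty:
        return MatchedPairs(np.empty(0), np.empty(0))
    proposals = []  # (|dr|, probe_idx, ref_idx)
    r_ref = ref_df["r"].to_numpy()
    t_ref = ref_df["theta"].to_numpy()
    for i, (rp, tp) in enumerate(zip(probe_df["r"], probe_df["theta"])):
        dtheta = np.abs(np.angle(np.exp(1j * (t_ref - tp))))
        cand = np.flatnonzero(dtheta <= theta_tol)
        if cand.size == 0:
            continue
        j = cand[np.argmin(np.abs(r_ref[cand] - rp))]
        proposals.append((abs(r_ref[j] - rp), i, int(j)))
    proposals.sort()
    used_ref: set[int] = set()
    used_probe: set[int] = set()
    keep_r_ref, keep_r_probe = [], []
    for _, i, j in proposals:
        if i in used_probe or j in used_ref:
            continue
        used_probe.add(i)
        used_ref.add(j)
        keep_r_ref.append(r_ref[j])
        keep_r_probe.append(probe_df["r"].iloc[i])
    return MatchedPairs(np.asarray(keep_r_ref), np.asarray(keep_r_probe))


def radial_displacement_rate(pairs: MatchedPairs) -> tuple[float, float]:
    """Through-origin slope of Δr vs. reference radius, with its stderr.

    The slope is the fractional magnification error at the probed depth
    (a bead at the centre cannot displace radially, hence no intercept).
    """
    if len(pairs) < 2 or np.unique(pairs.r_ref).size < 2:
        raise ValueError("need >= 2 pairs spanning distinct radii")
    r = pairs.r_ref
    dr = pairs.dr
    srr = float(np.sum(r * r))
    slope = float(np.sum(r * dr)) / srr
    resid = dr - slope * r
    stderr = math.sqrt(float(np.sum(resid**2)) / (len(pairs) - 1) / srr)
    return slope, stderr


@dataclass
class DistortionProfile:
    """Distortion summary at one remote-objective displacement.

    ``per_depth`` holds (depth µm, error %, stderr %, n pairs) rows;
    ``error_rate`` is the through-origin slope of error % vs. depth
    (%/µm) with its standard error.
    """

    displacement_mm: float
    per_depth: pd.DataFrame = field(repr=False)
    error_rate: float = 0.0
    error_rate_stderr: float = 0.0


def magnification_error_profile(
    stacks: "dict[float, BeadStack]",
    remote_displacement_mm: float = 0.0,
    theta_tol: float = math.radians(2.0),
    measured: "dict[float, list[BeadRecord]] | None" = None,
) -> DistortionProfile:
    """Per-depth magnification error and its rate for one displacement.

    ``stacks`` maps slab depth (µm; must include 0 as the reference) to
    the acquired stack.  Each stack is measured with the PSF pipeline,
    beads at each depth are matched to the Z = 0 reference, and the
    percent error vs. depth is fitted through the origin.  Pre-measured
    records can be supplied to skip re-measurement.
    """
    if 0.0 not in stacks:
        raise ValueError("depth series must include the Z=0 reference")
    if measured is None:
        measured = {z: measure_psfs(s) for z, s in stacks.items()}
    ref = measured[0.0]
    rows = []
    for z in sorted(stacks):
        if z == 0.0:
            continue
        pairs = match_beads_polar(ref, measured[z], theta_tol=theta_tol)
        if len(pairs) < 2:
            continue
        slope, stderr = radial_displacement_rate(pairs)
        rows.append(
            {
                "depth": z,
                "error_pct": 100.0 * slope,
                "stderr_pct": 100.0 * stderr,
                "n_pairs": len(pairs),
            }
        )
    per_depth = pd.DataFrame(rows, columns=["depth", "error_pct", "stderr_pct", "n_pairs"])
    if len(per_depth) < 2:
        raise ValueError("fewer than 2 usable depths for the error-rate fit")
    zz = per_depth["depth"].to_numpy(dtype=float)
    ee = per_depth["error_pct"].to_numpy(dtype=float)
    szz = float(np.sum(zz * zz))
    rate = float(np.sum(zz * ee)) / szz
    resid = ee - rate * zz
    rate_se = math.sqrt(float(np.sum(resid**2)) / (len(zz) - 1) / szz)
    return DistortionProfile(
        displacement_mm=remote_displacement_mm,
        per_depth=per_depth,
        error_rate=rate,
        error_rate_stderr=rate_se,
    )


def optimal_remote_position(
    displacements_mm: np.ndarray, error_rates: np.ndarray
) -> tuple[float, float]:
    """Zero crossing of the error rate vs. remote-objective displacement.

    An ordinary least-squares line is fitted to error_rate(D); its root
    D0 is the displacement at which the remote volume is undistorted.
    Returns (D0, stderr).  Warns when D0 extrapolates beyond the sampled
    range; raises :class:`NoCrossingError` for a flat fitted line.
    """
    d = np.asarray(displacements_mm, dtype=float)
    r = np.asarray(error_rates, dtype=float)
    if d.size < 2 or np.unique(d).size < 2:
        raise ValueError("need >= 2 distinct displacements")
    (b, a), cov = np.polyfit(d, r, 1, cov=True) if d.size > 2 else (
        np.polyfit(d, r, 1),
        np.full((2, 2), np.nan),
    )
    if abs(b) < 1e-12 * max(1.0, float(np.abs(r).max())):
        raise NoCrossingError("fitted error-rate line is flat; no zero crossing")
    d0 = -a / b
    if not d.min() <= d0 <= d.max():
        warnings.warn(
            f"optimal position {d0:.2f} mm extrapolates beyond the sampled "
            f"range [{d.min():.2f}, {d.max():.2f}] mm",
            stacklevel=2,
        )
    # delta-method propagation of the root's uncertainty
    if np.all(np.isfinite(cov)):
        var = (cov[1, 1] + d0**2 * cov[0, 0] + 2 * d0 * cov[0, 1]) / b**2
        stderr = math.sqrt(max(var, 0.0))
    else:
        stderr = np.nan
    return float(d0), float(stderr)
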
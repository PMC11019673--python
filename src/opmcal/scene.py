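"""Synthetic bead scenes for exercising the OPM calibration pipeline.

The instrument analyses in this package (PSF metrology, remote-volume
distortion, scan-mirror calibration, deskew) were designed against bead
samples: sub-diffraction fluorescent beads immobilised on a coverslip or
suspended in an agarose gel.  This module generates such scenes with
known ground truth and renders them the way the instrument would record
them:

* straight-path Z-stacks of a bead field, with an anisotropic Gaussian
  PSF whose lateral/axial FWHMs grow with radial field position and with
  depth away from the primary focal plane;
* a depth-proportional radial magnification distortion (beads appear
  scaled about the image centre by ``1 + distortion_rate * depth``),
  emulating axial misconjugation of the primary and remote objectives;
* oblique scan series whose per-step global illumination varies linearly
  with the mismatch between the two-mirror voltage ratio and the optimal
  ratio for the current objective position;
* genuinely oblique (tilted-plane) volumes for deskew round trips;
* Poisson shot noise, Gaussian read noise and a constant camera offset.

Every stochastic operation is driven by an explicit integer seed so that
renders are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PsfFieldModel",
    "SceneTruth",
    "BeadStack",
    "StackGeometry",
    "NoiseModel",
    "DensityError",
    "RenderError",
    "generate_bead_field",
    "render_stack",
    "render_depth_series",
    "render_scan_series",
    "render_oblique_stack",
    "displacement_to_distortion_rate",
]

FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # ≈ 2.355


class DensityError(RuntimeError):
    """Requested bead density cannot satisfy the minimum separation."""


class RenderError(ValueError):
    """Scene truth and requested render geometry are inconsistent."""


@dataclass(frozen=True)
class PsfFieldModel:
    """Spatially varying Gaussian PSF widths.

    FWHMs are in nanometres at the image centre / focal plane and grow
    linearly with radial field position ``r`` (µm) and with ``|depth|``
    (µm away from the primary focal plane):

    ``fwhm_lat(r, z) = fwhm_lat0 * (1 + radial_growth*r) * (1 + depth_growth_lat*|z|)``

    and analogously for the axial width.  Defaults emulate a remote
    focusing train built around a 100X/1.35 silicone objective: ~255 nm
    lateral and ~690 nm axial at centre focus, with a centre-to-edge
    growth of order 10% across a 200 µm field.
    """

    fwhm_lat0: float = 255.0
    fwhm_ax0: float = 688.0
    radial_growth: float = 8.0e-4
    depth_growth_lat: float = 2.0e-3
    depth_growth_ax: float = 3.0e-3

    def __post_init__(self) -> None:
        if not (self.fwhm_ax0 >= self.fwhm_lat0 > 0):
            raise ValueError("require fwhm_ax0 >= fwhm_lat0 > 0")
        for name in ("radial_growth", "depth_growth_lat", "depth_growth_ax"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def fwhms_at(self, r_um: float, depth_um: float) -> tuple[float, float]:
        """(lateral, axial) FWHM in nm at field radius r and depth z."""
        radial = 1.0 + self.radial_growth * r_um
        lat = self.fwhm_lat0 * radial * (1.0 + self.depth_growth_lat * abs(depth_um))
        ax = self.fwhm_ax0 * radial * (1.0 + self.depth_growth_ax * abs(depth_um))
        return lat, ax


@dataclass(frozen=True)
class SceneTruth:
    """Ground truth of a synthetic bead scene.

    ``positions`` are (N, 3) bead coordinates (x, y, z) in µm, centred:
    x and y are measured from the image centre, z from the slab centre
    (the plane brought to best focus).  ``distortion_rate`` is the
    fractional radial magnification error per µm of imaging depth.
    ``ratio_opt_map = (a, b)`` gives the optimal mirror voltage ratio as
    ``a + b * objective_z_mm``; ``gradient_gain`` converts a ratio
    mismatch into a per-scan-step fractional illumination slope.
    """

    positions: np.ndarray
    fov: tuple[float, float, float]
    flux: float = 7000.0
    psf_model: PsfFieldModel = field(default_factory=PsfFieldModel)
    distortion_rate: float = 0.0
    ratio_opt_map: tuple[float, float] = (1.015, 0.0025)
    gradient_gain: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        object.__setattr__(self, "positions", pos)
        if self.flux <= 0:
            raise ValueError("flux must be > 0")
        half = np.asarray(self.fov) / 2.0
        if np.any(np.abs(pos) > half + 1e-9):
            raise ValueError("bead positions must lie inside the declared FOV")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    def ratio_opt(self, objective_z_mm: float) -> float:
        """Optimal mirror voltage ratio at an objective Z position (mm)."""
        a, b = self.ratio_opt_map
        return a + b * objective_z_mm

    def with_(self, **kwargs) -> "SceneTruth":
        """Copy with selected fields replaced."""
        return replace(self, **kwargs)


@dataclass
class BeadStack:
    """A rendered 3D intensity volume plus its acquisition geometry.

    ``voxels`` is ordered (z, y, x) for straight stacks and
    (step, y, oblique-axis) for oblique series.  ``pixel_xy`` is the
    in-plane sampling (µm/px); ``step_z`` is the plane spacing for
    straight stacks or the mirror scan step for oblique series.  The
    image centre sits at pixel ((nx-1)/2, (ny-1)/2).
    """

    voxels: np.ndarray
    pixel_xy: float
    step_z: float
    modality: str = "straight"
    tilt_deg: float | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be 3D (z/step, y, x)")
        if self.pixel_xy <= 0 or self.step_z <= 0:
            raise ValueError("pixel_xy and step_z must be > 0")
        if self.modality not in ("straight", "oblique"):
            raise ValueError("modality must be 'straight' or 'oblique'")
        if self.modality == "oblique" and self.tilt_deg is None:
            raise ValueError("oblique stacks require tilt_deg")
        if np.any(self.voxels < 0):
            raise ValueError("voxel values must be >= 0")

    @property
    def n_planes(self) -> int:
        return self.voxels.shape[0]

    @property
    def centre_px(self) -> tuple[float, float]:
        """(cx, cy) image centre in pixel coordinates."""
        _, ny, nx = self.voxels.shape
        return (nx - 1) / 2.0, (ny - 1) / 2.0


@dataclass(frozen=True)
class StackGeometry:
    """Request for a straight-path Z-stack render.

    ``depth`` is the slab position (µm) relative to the primary focal
    plane; it drives both the PSF depth growth and the magnification
    distortion.  Defaults mirror the bead-stack acquisition used for PSF
    metrology: 54 planes at 150 nm with 108.3 nm pixels.
    """

    nx: int
    ny: int
    n_planes: int = 54
    pixel_xy: float = 0.1083
    step_z: float = 0.15
    depth: float = 0.0

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.n_planes) < 1:
            raise ValueError("geometry extents must be >= 1")
        if self.pixel_xy <= 0 or self.step_z <= 0:
            raise ValueError("pixel_xy and step_z must be > 0")


@dataclass(frozen=True)
class NoiseModel:
    """Camera noise: Poisson shot noise, Gaussian read noise, offset.

    Defaults give a read noise of 1.6 counts and a 100-count bias, a
    generic sCMOS operating point; the default scene flux then yields a
    peak bead SNR of roughly 20.
    """

    poisson: bool = True
    read_sigma: float = 1.6
    offset: float = 100.0


def displacement_to_distortion_rate(
    displacement_mm: float,
    d0_mm: float = 0.4,
    rate_per_mm: float = 1.5e-4,
) -> float:
    """Magnification-error rate (fraction/µm depth) for a remote-objective offset.

    The injected model is linear and antisymmetric about the true optimum
    ``d0_mm``: moving the remote objective above its optimal position
    makes the apparent magnification grow with depth above the focal
    plane (positive rate) and vice versa.  The default coefficient keeps
    the error below ~0.5% for ±10 µm depths over the ±3 mm misalignment
    range representative of routine focusing travel.
    """
    return rate_per_mm * (displacement_mm - d0_mm)


def generate_bead_field(
    fov: tuple[float, float, float],
    n_beads: int,
    min_separation: float = 2.0,
    seed: int = 0,
    max_tries_per_bead: int = 400,
    **truth_kwargs,
) -> SceneTruth:
    """Draw a uniform random bead field with a minimum pairwise separation.

    Rejection sampling: candidates are drawn uniformly in the centred
    FOV box and kept if at least ``min_separation`` (µm, 3D Euclidean)
    from every accepted bead.  Deterministic under a fixed seed.

    Raises
    ------
    DensityError
        If the requested density is infeasible (the per-bead rejection
        cap is exhausted).
    """
    fov = tuple(float(v) for v in fov)
    if len(fov) != 3 or min(fov) <= 0:
        raise ValueError("fov must be three positive extents")
    if n_beads < 1:
        raise ValueError("n_beads must be >= 1")
    rng = np.random.default_rng(seed)
    half = np.asarray(fov) / 2.0
    accepted = np.empty((0, 3))
    tries = 0
    cap = max_tries_per_bead * n_beads
    while accepted.shape[0] < n_beads:
        if tries >= cap:
            raise DensityError(
                f"placed {accepted.shape[0]}/{n_beads} beads after {tries} draws; "
                f"reduce density or min_separation"
            )
        cand = rng.uniform(-half, half)
        tries += 1
        if accepted.shape[0] and n_beads > 1:
            d2 = np.sum((accepted - cand) ** 2, axis=1)
            if d2.min() < min_separation**2:
                continue
        accepted = np.vstack([accepted, cand])
    return SceneTruth(positions=accepted, fov=fov, seed=seed, **truth_kwargs)


def _apply_noise(expected: np.ndarray, noise: NoiseModel | None, rng) -> np.ndarray:
    if noise is None:
        return expected.astype(np.float32)
    out = expected
    if noise.poisson:
        out = rng.poisson(out).astype(np.float64)
    if noise.read_sigma > 0:
        out = out + rng.normal(0.0, noise.read_sigma, size=out.shape)
    out = out + noise.offset
    return np.clip(out, 0.0, None).astype(np.float32)


def _add_gaussian_3d(
    expected: np.ndarray,
    zc: float,
    yc: float,
    xc: float,
    sz: float,
    sy: float,
    sx: float,
    amplitude_integral: float,
    n_sigma: float = 5.0,
) -> None:
    """Accumulate a normalised separable Gaussian (units: grid steps)."""
    nz, ny, nx = expected.shape
    zlo = max(int(math.floor(zc - n_sigma * sz)), 0)
    zhi = min(int(math.ceil(zc + n_sigma * sz)) + 1, nz)
    ylo = max(int(math.floor(yc - n_sigma * sy)), 0)
    yhi = min(int(math.ceil(yc + n_sigma * sy)) + 1, ny)
    xlo = max(int(math.floor(xc - n_sigma * sx)), 0)
    xhi = min(int(math.ceil(xc + n_sigma * sx)) + 1, nx)
    if zlo >= zhi or ylo >= yhi or xlo >= xhi:
        return
    norm = 1.0 / ((2.0 * math.pi) ** 1.5 * sz * sy * sx)
    gz = np.exp(-0.5 * ((np.arange(zlo, zhi) - zc) / sz) ** 2)
    gy = np.exp(-0.5 * ((np.arange(ylo, yhi) - yc) / sy) ** 2)
    gx = np.exp(-0.5 * ((np.arange(xlo, xhi) - xc) / sx) ** 2)
    expected[zlo:zhi, ylo:yhi, xlo:xhi] += (
        amplitude_integral * norm
    ) * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]


def render_stack(
    truth: SceneTruth,
    geometry: StackGeometry,
    noise: NoiseModel | None = NoiseModel(),
    seed: int | None = None,
) -> BeadStack:
    """Render a straight-path Z-stack of the scene.

    Each bead becomes a separable anisotropic 3D Gaussian whose widths
    come from the truth's :class:`PsfFieldModel` evaluated at the bead's
    field radius and total depth (``geometry.depth`` plus the bead's own
    z).  Lateral positions are scaled by ``1 + distortion_rate * depth``
    about the image centre.  Noise-free expected counts integrate to
    ``flux`` per bead up to field-of-view truncation.
    """
    gx_um = geometry.nx * geometry.pixel_xy
    gy_um = geometry.ny * geometry.pixel_xy
    if gx_um < truth.fov[0] - 1e-9 or gy_um < truth.fov[1] - 1e-9:
        raise RenderError(
            f"render window {gx_um:.1f}x{gy_um:.1f} µm is smaller than the "
            f"scene FOV {truth.fov[0]:.1f}x{truth.fov[1]:.1f} µm"
        )
    expected = np.zeros((geometry.n_planes, geometry.ny, geometry.nx))
    cx = (geometry.nx - 1) / 2.0
    cy = (geometry.ny - 1) / 2.0
    cz = (geometry.n_planes - 1) / 2.0
    for x, y, zb in truth.positions:
        depth = geometry.depth + zb
        r = math.hypot(x, y)
        fwhm_lat, fwhm_ax = truth.psf_model.fwhms_at(r, depth)
        s_lat = fwhm_lat / FWHM_PER_SIGMA / 1000.0  # µm
        s_ax = fwhm_ax / FWHM_PER_SIGMA / 1000.0
        scale = 1.0 + truth.distortion_rate * depth
        xpx = cx + scale * x / geometry.pixel_xy
        ypx = cy + scale * y / geometry.pixel_xy
        zpx = cz + zb / geometry.step_z
        _add_gaussian_3d(
            expected,
            zpx,
            ypx,
            xpx,
            s_ax / geometry.step_z,
            s_lat / geometry.pixel_xy,
            s_lat / geometry.pixel_xy,
            truth.flux,
        )
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    voxels = _apply_noise(expected, noise, rng)
    return BeadStack(voxels=voxels, pixel_xy=geometry.pixel_xy, step_z=geometry.step_z)


def render_depth_series(
    truth: SceneTruth,
    geometry: StackGeometry,
    depths: "list[float]",
    noise: NoiseModel | None = NoiseModel(),
    seed: int | None = None,
) -> "dict[float, BeadStack]":
    """Render one Z-stack per slab depth (µm from the primary focal plane).

    Emulates stepping the bead sample to a series of depths and
    re-acquiring a stack at each, as done for remote-volume distortion
    mapping.  Noise draws differ between depths but are reproducible.
    """
    base = truth.seed if seed is None else seed
    out: dict[float, BeadStack] = {}
    for i, d in enumerate(depths):
        geo = replace(geometry, depth=float(d))
        out[float(d)] = render_stack(truth, geo, noise=noise, seed=base + 7919 * i)
    return out


def _add_gaussian_2d(
    frame: np.ndarray,
    yc: float,
    xc: float,
    sy: float,
    sx: float,
    amplitude_integral: float,
    n_sigma: float = 5.0,
) -> None:
    """Accumulate a normalised 2D Gaussian (units: pixels)."""
    ny, nx = frame.shape
    ylo = max(int(math.floor(yc - n_sigma * sy)), 0)
    yhi = min(int(math.ceil(yc + n_sigma * sy)) + 1, ny)
    xlo = max(int(math.floor(xc - n_sigma * sx)), 0)
    xhi = min(int(math.ceil(xc + n_sigma * sx)) + 1, nx)
    if ylo >= yhi or xlo >= xhi:
        return
    norm = 1.0 / (2.0 * math.pi * sy * sx)
    gy = np.exp(-0.5 * ((np.arange(ylo, yhi) - yc) / sy) ** 2)
    gx = np.exp(-0.5 * ((np.arange(xlo, xhi) - xc) / sx) ** 2)
    frame[ylo:yhi, xlo:xhi] += (amplitude_integral * norm) * gy[:, None] * gx[None, :]


def _render_base_frame(
    truth: SceneTruth, ny: int, nx: int, pixel_xy: float
) -> np.ndarray:
    """Noise-free 2D projection of the bead field (for scan series)."""
    frame = np.zeros((ny, nx))
    cx = (nx - 1) / 2.0
    cy = (ny - 1) / 2.0
    for x, y, zb in truth.positions:
        r = math.hypot(x, y)
        fwhm_lat, _ = truth.psf_model.fwhms_at(r, zb)
        s_lat = fwhm_lat / FWHM_PER_SIGMA / 1000.0 / pixel_xy
        _add_gaussian_2d(
            frame, cy + y / pixel_xy, cx + x / pixel_xy, s_lat, s_lat, truth.flux
        )
    return frame


def render_scan_series(
    truth: SceneTruth,
    ratio: float,
    objective_z_mm: float = 0.0,
    n_steps: int = 100,
    step_x: float = 1.4,
    frame_shape: tuple[int, int] = (160, 256),
    pixel_xy: float = 0.1083,
    tilt_deg: float = 28.0,
    noise: NoiseModel | None = NoiseModel(),
    seed: int | None = None,
) -> BeadStack:
    """Render an oblique mirror-scan series at one voltage ratio.

    Emulates scanning the light sheet across an agarose-embedded bead
    field: every step images statistically identical content, but when
    the two-mirror voltage ratio differs from the optimum for the current
    objective position the pivot point leaves the pupil plane, the sheet
    angle drifts during the scan, and the collected intensity acquires a
    linear trend.  The per-step global illumination factor is::

        1 + gradient_gain * (ratio - ratio_opt(objective_z)) * (step - (n_steps-1)/2)

    so the expected slope of the mean-normalised summed intensity is
    exactly ``gradient_gain * (ratio - ratio_opt)`` per step.
    """
    if n_steps < 3:
        raise RenderError("scan series needs at least 3 steps")
    ny, nx = frame_shape
    base = _render_base_frame(truth, ny, nx, pixel_xy)
    mismatch = ratio - truth.ratio_opt(objective_z_mm)
    mid = (n_steps - 1) / 2.0
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    frames = np.empty((n_steps, ny, nx), dtype=np.float32)
    for s in range(n_steps):
        factor = 1.0 + truth.gradient_gain * mismatch * (s - mid)
        if factor < 0:
            raise RenderError("illumination factor went negative; gain/ratio too large")
        frames[s] = _apply_noise(factor * base, noise, rng)
    return BeadStack(
        voxels=frames,
        pixel_xy=pixel_xy,
        step_z=step_x,
        modality="oblique",
        tilt_deg=tilt_deg,
    )


def render_oblique_stack(
    truth: SceneTruth,
    n_steps: int,
    ny: int,
    nx_obl: int,
    scan_step: float = 0.117,
    pixel_obl: float = 0.117,
    pixel_y: float = 0.117,
    tilt_deg: float = 28.0,
    noise: NoiseModel | None = NoiseModel(),
    seed: int | None = None,
) -> BeadStack:
    """Render a geometrically faithful oblique scan volume of the scene.

    Frame ``s`` images the plane tilted by ``tilt_deg`` about the Y axis
    and displaced by ``s * scan_step`` along X.  A sample on that plane
    at oblique-axis pixel ``i`` and row ``j`` sits at cartesian::

        x = x0 + s*scan_step + i*pixel_obl*cos(t)
        y = y0 + j*pixel_y
        z = z0 + i*pixel_obl*sin(t)

    with the origin offsets chosen so the sampled volume is centred on
    the scene.  Bead PSFs are evaluated in the cartesian sample frame, so
    a correct deskew recovers the injected positions and widths.
    """
    if truth.distortion_rate != 0.0:
        raise RenderError("oblique rendering assumes an undistorted remote volume")
    t = math.radians(tilt_deg)
    sin_t, cos_t = math.sin(t), math.cos(t)
    # centre the sampled box on the scene origin
    x_extent = (n_steps - 1) * scan_step + (nx_obl - 1) * pixel_obl * cos_t
    x0 = -x_extent / 2.0
    y0 = -(ny - 1) * pixel_y / 2.0
    z0 = -(nx_obl - 1) * pixel_obl * sin_t / 2.0
    voxel_vol = scan_step * pixel_y * pixel_obl * sin_t
    expected = np.zeros((n_steps, ny, nx_obl))
    for xb, yb, zb in truth.positions:
        r = math.hypot(xb, yb)
        fwhm_lat, fwhm_ax = truth.psf_model.fwhms_at(r, zb)
        s_lat = fwhm_lat / FWHM_PER_SIGMA / 1000.0
        s_ax = fwhm_ax / FWHM_PER_SIGMA / 1000.0
        # oblique-axis ROI from the axial extent of the PSF
        i_c = (zb - z0) / (pixel_obl * sin_t)
        i_half = 5.0 * (s_ax / sin_t + s_lat) / pixel_obl
        ilo = max(int(math.floor(i_c - i_half)), 0)
        ihi = min(int(math.ceil(i_c + i_half)) + 1, nx_obl)
        if ilo >= ihi:
            continue
        jc = (yb - y0) / pixel_y
        j_half = 5.0 * s_lat / pixel_y
        jlo = max(int(math.floor(jc - j_half)), 0)
        jhi = min(int(math.ceil(jc + j_half)) + 1, ny)
        if jlo >= jhi:
            continue
        ii = np.arange(ilo, ihi)
        z_pl = z0 + ii * pixel_obl * sin_t
        x_off = ii * pixel_obl * cos_t  # x contribution of the oblique axis
        # step ROI: x = x0 + s*scan_step + x_off must reach xb +- 5 s_lat
        s_min = (xb - 5.0 * s_lat - x0 - x_off.max()) / scan_step
        s_max = (xb + 5.0 * s_lat - x0 - x_off.min()) / scan_step
        slo = max(int(math.floor(s_min)), 0)
        shi = min(int(math.ceil(s_max)) + 1, n_steps)
        if slo >= shi:
            continue
        ss = np.arange(slo, shi)
        x_grid = x0 + ss[:, None] * scan_step + x_off[None, :]  # (S, I)
        gz = np.exp(-0.5 * ((z_pl - zb) / s_ax) ** 2)  # (I,)
        gsx = np.exp(-0.5 * ((x_grid - xb) / s_lat) ** 2)  # (S, I)
        gy = np.exp(-0.5 * ((y0 + np.arange(jlo, jhi) * pixel_y - yb) / s_lat) ** 2)
        norm = truth.flux * voxel_vol / ((2.0 * math.pi) ** 1.5 * s_lat**2 * s_ax)
        expected[slo:shi, jlo:jhi, ilo:ihi] += (
            norm * gsx[:, None, :] * gy[None, :, None] * (gz[None, None, :])
        )
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    voxels = _apply_noise(expected, noise, rng)
    return BeadStack(
        voxels=voxels,
        pixel_xy=pixel_y,
        step_z=scan_step,
        modality="oblique",
        tilt_deg=tilt_deg,
    )
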
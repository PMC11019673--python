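"""First-order design arithmetic for a remote-focusing OPM train.

An oblique plane microscope relays the 3D focal volume of a primary
objective into the space of a remote objective so that tilted planes can
be imaged without moving the sample. Aberration-free remote focusing
requires the overall magnification between the primary-objective space
and the remote-objective space to equal the ratio of the immersion
refractive indices, ``n1 / n2``.  With objectives specified by their
nominal magnification against a design tube-lens standard (``f_design``,
180 mm for Olympus), that condition fixes the focal length of the remote
tube lens; the helpers here solve it and the related scan-geometry
scalings (field of view, field-curvature focal shift, misalignment
equivalence between objective spaces, cylindrical beam expansion).

All lengths are carried in micrometres internally; constructors and the
reporting helpers accept/emit the conventional units (mm for focal
lengths, µm/nm for sample-space quantities).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "OpticalConfig",
    "InvalidConfigError",
    "remote_tube_lens_focal",
    "lateral_image_to_sample",
    "axial_image_to_sample",
    "misalignment_equivalence_factor",
    "cylindrical_expansion",
    "design_report",
]

MM = 1000.0  # µm per mm


class InvalidConfigError(ValueError):
    """Raised when an optical parameter violates its physical domain."""


@dataclass(frozen=True)
class OpticalConfig:
    """Parameters of the remote-focusing train.

    Parameters
    ----------
    f_tl1 : float
        Primary tube-lens focal length, mm.
    M1_nominal, M2_nominal : float
        Nominal magnifications of the primary and remote objectives
        (against ``f_design``).
    f_design : float
        Tube-lens standard both objectives are specified for, mm.
    n1, n2 : float
        Immersion refractive indices of the primary and remote spaces.
    f_tl2 : float
        Remote tube-lens focal length actually built, mm.
    tilt_deg : float
        Tilt of the tertiary imaging telescope, degrees.
    """

    f_tl1: float = 180.0
    M1_nominal: float = 100.0
    M2_nominal: float = 40.0
    f_design: float = 180.0
    n1: float = 1.406
    n2: float = 1.0
    f_tl2: float = 321.0
    tilt_deg: float = 28.0

    def __post_init__(self) -> None:
        for name in ("f_tl1", "M1_nominal", "M2_nominal", "f_design", "f_tl2"):
            if not getattr(self, name) > 0:
                raise InvalidConfigError(f"{name} must be > 0")
        if self.n1 < 1 or self.n2 < 1:
            raise InvalidConfigError("refractive indices must be >= 1")
        if not 0 < self.tilt_deg < 90:
            raise InvalidConfigError("tilt_deg must lie in (0, 90)")

    @property
    def f_obj1(self) -> float:
        """Primary objective focal length, mm (f_design / M_nominal)."""
        return self.f_design / self.M1_nominal

    @property
    def f_obj2(self) -> float:
        """Remote objective focal length, mm."""
        return self.f_design / self.M2_nominal


def remote_tube_lens_focal(cfg: OpticalConfig) -> float:
    """Ideal remote tube-lens focal length, mm.

    Solves the index-matching magnification condition
    ``M1 * (f_design / M2) / f_tl2* = n1 / n2`` for ``f_tl2*``.  For a
    100X silicone-oil primary (n = 1.406) and a 40X air remote objective
    on the 180 mm standard this gives 320.06 mm; the exact solution is
    returned, rounding to a catalogue value is up to the caller.
    """
    return cfg.M1_nominal * (cfg.f_design / cfg.M2_nominal) * cfg.n2 / cfg.n1


def lateral_image_to_sample(extent: float, M: float) -> float:
    """Demagnify a lateral extent at the primary image plane into sample space.

    ``extent`` and the return value share units (extent/M).  E.g. a 20 mm
    image-plane field at 100X corresponds to 200 µm at the sample.
    """
    if M <= 0:
        raise InvalidConfigError("magnification must be > 0")
    return extent / M


def axial_image_to_sample(shift: float, M: float) -> float:
    """Demagnify an axial (focal) shift at the image plane into sample space.

    Axial extents scale with the square of the lateral magnification, so
    the sample-space shift is ``shift / M**2``: 0.92 mm of image-plane
    field curvature at 100X is only 92 nm of focal shift at the sample.
    """
    if M <= 0:
        raise InvalidConfigError("magnification must be > 0")
    return shift / M**2


def misalignment_equivalence_factor(cfg: OpticalConfig) -> float:
    """Remote-objective displacement equivalent to unit primary displacement.

    The two objective spaces are conjugated through their tube lenses, so
    an axial displacement ``d`` of the primary objective is equivalent to
    displacing the remote objective by ``d * (f_tl2 / f_tl1)**2``
    (longitudinal magnification of the relay).  For the 180 mm / 321 mm
    pair this is 3.18: ±1 mm of focusing travel maps to roughly ±3 mm of
    remote-objective misalignment.
    """
    return (cfg.f_tl2 / cfg.f_tl1) ** 2


def cylindrical_expansion(f_first: float, f_last: float) -> float:
    """Beam expansion of a two-lens cylindrical telescope, ``f_last / f_first``."""
    if f_first <= 0 or f_last <= 0:
        raise InvalidConfigError("focal lengths must be > 0")
    return f_last / f_first


def design_report(cfg: OpticalConfig) -> dict[str, float]:
    """Headline design numbers for a configuration (lengths in mm, 2 dp).

    Returns the ideal remote tube-lens focal length, the as-built value,
    and the misalignment equivalence factor of the as-built relay.
    """
    return {
        "f_tl2_ideal_mm": round(remote_tube_lens_focal(cfg), 2),
        "f_tl2_built_mm": round(cfg.f_tl2, 2),
        "misalignment_equivalence": round(misalignment_equivalence_factor(cfg), 2),
    }
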
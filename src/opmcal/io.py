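"""Stack and ground-truth I/O: ImageJ-style TIFF plus YAML sidecars."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
import yaml

from .scene import BeadStack, PsfFieldModel, SceneTruth

__all__ = ["write_stack", "read_stack", "write_truth", "read_truth"]


def write_stack(path: str | Path, stack: BeadStack) -> None:
    """Write a stack as multi-page TIFF (axes ZYX) with a YAML sidecar.

    The sidecar (``<name>.yaml``) carries the acquisition geometry so a
    read round-trips the full :class:`BeadStack`.
    """
    path = Path(path)
    tifffile.imwrite(
        path,
        stack.voxels.astype(np.float32),
        imagej=True,
        metadata={"axes": "ZYX", "spacing": stack.step_z, "unit": "um"},
        resolution=(1.0 / stack.pixel_xy, 1.0 / stack.pixel_xy),
    )
    meta = {
        "pixel_xy_um": float(stack.pixel_xy),
        "step_z_um": float(stack.step_z),
        "modality": stack.modality,
        "tilt_deg": None if stack.tilt_deg is None else float(stack.tilt_deg),
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(meta, sort_keys=False))


def read_stack(path: str | Path) -> BeadStack:
    """Read a stack written by :func:`write_stack`."""
    path = Path(path)
    voxels = tifffile.imread(path)
    meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
    return BeadStack(
        voxels=voxels,
        pixel_xy=meta["pixel_xy_um"],
        step_z=meta["step_z_um"],
        modality=meta["modality"],
        tilt_deg=meta["tilt_deg"],
    )


def write_truth(path: str | Path, truth: SceneTruth) -> None:
    """Serialise scene ground truth to YAML."""
    doc = {
        "fov_um": [float(v) for v in truth.fov],
        "flux": float(truth.flux),
        "distortion_rate_per_um": float(truth.distortion_rate),
        "ratio_opt_map": [float(v) for v in truth.ratio_opt_map],
        "gradient_gain": float(truth.gradient_gain),
        "seed": int(truth.seed),
        "psf_model": {
            "fwhm_lat0_nm": truth.psf_model.fwhm_lat0,
            "fwhm_ax0_nm": truth.psf_model.fwhm_ax0,
            "radial_growth_per_um": truth.psf_model.radial_growth,
            "depth_growth_lat_per_um": truth.psf_model.depth_growth_lat,
            "depth_growth_ax_per_um": truth.psf_model.depth_growth_ax,
        },
        "positions_um": truth.positions.tolist(),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_truth(path: str | Path) -> SceneTruth:
    """Load scene ground truth written by :func:`write_truth`."""
    doc = yaml.safe_load(Path(path).read_text())
    pm = doc["psf_model"]
    return SceneTruth(
        positions=np.asarray(doc["positions_um"], dtype=float),
        fov=tuple(doc["fov_um"]),
        flux=doc["flux"],
        psf_model=PsfFieldModel(
            fwhm_lat0=pm["fwhm_lat0_nm"],
            fwhm_ax0=pm["fwhm_ax0_nm"],
            radial_growth=pm["radial_growth_per_um"],
            depth_growth_lat=pm["depth_growth_lat_per_um"],
            depth_growth_ax=pm["depth_growth_ax_per_um"],
        ),
        distortion_rate=doc["distortion_rate_per_um"],
        ratio_opt_map=tuple(doc["ratio_opt_map"]),
        gradient_gain=doc["gradient_gain"],
        seed=doc["seed"],
    )
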
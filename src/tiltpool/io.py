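"""Raster and manifest I/O.

Scenes are stored as single-channel 32-bit float TIFFs (range and the two
luminance images), an 8-bit TIFF validity mask, and a JSON sidecar with the
viewing geometry.  On disk rasters are top-row-first (the usual image
convention); in memory the package uses bottom-row-first (y upward), so
arrays are flipped on load and save.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .geometry import RangeScene, TiltMap, ViewingGeometry

__all__ = ["save_scene", "load_scene", "save_tilt_map", "load_tilt_map"]

_SIDECAR = "geometry.json"


def _write(path, arr, dtype=np.float32):
    tifffile.imwrite(str(path), np.flipud(np.asarray(arr)).astype(dtype))


def _read(path, dtype=float):
    return np.flipud(tifffile.imread(str(path))).astype(dtype)


def save_scene(scene: RangeScene, outdir):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write(outdir / "range.tif", scene.range_m)
    _write(outdir / "left.tif", scene.left_image)
    _write(outdir / "right.tif", scene.right_image)
    _write(outdir / "valid_mask.tif", scene.valid_mask, np.uint8)
    if scene.half_occlusion is not None:
        _write(outdir / "half_occlusion.tif", scene.half_occlusion, np.uint8)
    geom = scene.geometry
    sidecar = {
        "pixel_scale_arcmin": geom.pixel_scale,
        "ipd_cm": geom.ipd_cm,
        "fixation_distance_m": geom.fixation_distance_m,
        "image_size": list(geom.image_size),
    }
    (outdir / _SIDECAR).write_text(json.dumps(sidecar, indent=2))
    return outdir


def load_scene(indir) -> RangeScene:
    indir = Path(indir)
    meta = json.loads((indir / _SIDECAR).read_text())
    geom = ViewingGeometry(pixel_scale=meta["pixel_scale_arcmin"],
                           ipd_cm=meta["ipd_cm"],
                           fixation_distance_m=meta["fixation_distance_m"],
                           image_size=tuple(meta["image_size"]))
    occ_path = indir / "half_occlusion.tif"
    return RangeScene(
        range_m=_read(indir / "range.tif"),
        left_image=_read(indir / "left.tif"),
        right_image=_read(indir / "right.tif"),
        geometry=geom,
        valid_mask=_read(indir / "valid_mask.tif", bool),
        half_occlusion=_read(occ_path, bool) if occ_path.exists() else None)


def save_tilt_map(tilt: TiltMap, outdir):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write(outdir / "tilt_signed.tif", tilt.tilt_signed)
    _write(outdir / "slant.tif", tilt.slant)
    _write(outdir / "tilt_defined.tif", tilt.defined_mask, np.uint8)
    return outdir


def load_tilt_map(indir) -> TiltMap:
    indir = Path(indir)
    signed = _read(indir / "tilt_signed.tif")
    return TiltMap(tilt_signed=signed, tilt_unsigned=signed % 180.0,
                   slant=_read(indir / "slant.tif"),
                   defined_mask=_read(indir / "tilt_defined.tif", bool))
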
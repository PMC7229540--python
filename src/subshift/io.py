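"""Raster I/O: PNG/TIFF in, normalized grayscale ImageGrid out.

Integer rasters are scaled by their dtype range to [0, 1]; color images
are collapsed to luma with the Rec. 601 weights.  Saving quantizes to
16-bit (1/65535 round-trip error).  DICOM/NIfTI are out of scope —
convert to TIFF first.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .core import ImageGrid, ShiftVector
from .synthetic import SyntheticCase

__all__ = ["load_image", "save_image", "write_case", "read_case"]

REC601 = np.array([0.299, 0.587, 0.114])


def load_image(path) -> ImageGrid:
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # imageio raises assorted backend errors
        raise ValueError(f"cannot read image {path} ({path.suffix or 'no extension'}): {exc}") from exc
    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / float(np.iinfo(arr.dtype).max)
    else:
        arr = arr.astype(float)
    if arr.ndim == 3:
        if arr.shape[2] in (3, 4):
            arr = arr[..., :3] @ REC601
        elif arr.shape[2] == 1:
            arr = arr[..., 0]
        else:
            raise ValueError(f"unsupported channel count {arr.shape[2]} in {path}")
    elif arr.ndim != 2:
        raise ValueError(f"unsupported image dimensionality {arr.ndim} in {path}")
    try:
        return ImageGrid(arr)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def save_image(path, image) -> None:
    """Write as 16-bit grayscale; values are clipped to [0, 1] first."""
    arr = image.pixels if isinstance(image, ImageGrid) else np.asarray(image, float)
    quant = np.clip(arr, 0.0, 1.0)
    iio.imwrite(Path(path), np.round(quant * 65535.0).astype(np.uint16))


def write_case(case: SyntheticCase, outdir) -> Path:
    """Persist a synthetic pair as two 16-bit TIFFs plus a JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_image(outdir / "reference.tif", case.reference)
    save_image(outdir / "moving.tif", case.moving)
    sidecar = {
        "truth": {"dy": case.truth.dy, "dx": case.truth.dx},
        "noise_sigma": case.noise_sigma,
        "seed": case.seed,
        "size": list(case.size),
        "aliasing": case.aliasing,
        "convention": "moving = reference translated by +truth (circular)",
    }
    (outdir / "case.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    return outdir


def read_case(casedir) -> SyntheticCase:
    casedir = Path(casedir)
    meta = json.loads((casedir / "case.json").read_text())
    return SyntheticCase(
        reference=load_image(casedir / "reference.tif"),
        moving=load_image(casedir / "moving.tif"),
        truth=ShiftVector(meta["truth"]["dy"], meta["truth"]["dx"]),
        noise_sigma=meta["noise_sigma"],
        seed=meta["seed"],
        size=tuple(meta["size"]),
        aliasing=meta.get("aliasing", False),
    )
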
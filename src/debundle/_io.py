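"""Raster and sidecar I/O.

Images are float [0, 1] in memory; PNG output is 8-bit, TIFF output is
float32.  JSON sidecars carry core centers and region specs alongside
simulated rasters.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .metrics import RegionSpec
from .synthesis import to_grayscale_unit


def load_raster(path: str | Path) -> np.ndarray:
    """Read PNG/JPEG/TIFF as a grayscale float [0, 1] raster."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return to_grayscale_unit(arr)


def save_raster(path: str | Path, image: np.ndarray) -> None:
    """Write a [0, 1] raster: 8-bit PNG or float32 TIFF by extension."""
    path = Path(path)
    img = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img.astype(np.float32))
    elif path.suffix.lower() == ".png":
        iio.imwrite(path, np.round(img * 255).astype(np.uint8))
    else:
        raise ValueError(f"unsupported raster extension {path.suffix!r}")


def save_sidecar(path: str | Path, core_centers: np.ndarray | None = None,
                 regions: dict[str, RegionSpec] | None = None,
                 extra: dict | None = None) -> None:
    payload: dict = dict(extra or {})
    if core_centers is not None:
        payload["core_centers"] = np.asarray(core_centers).tolist()
    if regions is not None:
        payload["regions"] = {k: v.to_dict() for k, v in regions.items()}
    Path(path).write_text(json.dumps(payload))


def load_sidecar(path: str | Path) -> dict:
    payload = json.loads(Path(path).read_text())
    if "core_centers" in payload:
        payload["core_centers"] = np.asarray(payload["core_centers"])
    if "regions" in payload:
        payload["regions"] = {
            k: RegionSpec.from_dict(v) for k, v in payload["regions"].items()}
    return payload
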
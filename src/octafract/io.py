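"""Raster readers/writers for en face angiograms.

Single-channel 8- or 16-bit TIFF and PNG are supported. Intensities are
rescaled to [0, 1] by dividing by the dtype maximum (not the image maximum),
so images acquired at different dynamic ranges stay comparable. A JSON
sidecar carries the scan metadata (layer, field of view, grid size, signal
strength index).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .model import EnFaceAngiogram, Layer, ScanGeometry

_DTYPE_MAX = {np.dtype("uint8"): 255.0, np.dtype("uint16"): 65535.0}


def _load_raw(path: Path) -> np.ndarray:
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif suffix == ".png":
        arr = np.asarray(Image.open(path))
    else:
        raise ValueError(f"unsupported image format {suffix!r} (use TIFF or PNG)")
    return arr


def read_angiogram(
    path: str | Path,
    layer: Layer | str,
    geometry: ScanGeometry,
    signal_strength_index: float | None = None,
) -> EnFaceAngiogram:
    """Read a single-channel raster image as an :class:`EnFaceAngiogram`.

    Raises
    ------
    ValueError
        If the file is multi-channel, has an unsupported dtype, or its shape
        does not match ``geometry``.
    """
    path = Path(path)
    arr = _load_raw(path)
    if arr.ndim != 2:
        raise ValueError(
            f"{path.name}: expected a single-channel image, got shape {arr.shape}"
        )
    if arr.shape != geometry.shape:
        raise ValueError(
            f"{path.name}: image shape {arr.shape} does not match scan geometry "
            f"{geometry.shape}"
        )
    if arr.dtype == bool:
        pixels = arr.astype(float)
    else:
        if arr.dtype not in _DTYPE_MAX:
            raise ValueError(
                f"{path.name}: unsupported dtype {arr.dtype}; expected 8- or 16-bit"
            )
        pixels = arr.astype(float) / _DTYPE_MAX[arr.dtype]
    return EnFaceAngiogram(
        pixels=pixels,
        layer=Layer(layer),
        geometry=geometry,
        signal_strength_index=signal_strength_index,
    )


def write_angiogram(path: str | Path, angiogram: EnFaceAngiogram, bits: int = 16) -> None:
    """Write an angiogram as an 8- or 16-bit TIFF/PNG (intensities x dtype max)."""
    path = Path(path)
    if bits == 8:
        arr = np.round(np.clip(angiogram.pixels, 0, 1) * 255).astype(np.uint8)
    elif bits == 16:
        arr = np.round(np.clip(angiogram.pixels, 0, 1) * 65535).astype(np.uint16)
    else:
        raise ValueError("bits must be 8 or 16")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    elif suffix == ".png":
        Image.fromarray(arr).save(path)
    else:
        raise ValueError(f"unsupported image format {suffix!r} (use TIFF or PNG)")


def write_sidecar(path: str | Path, angiogram: EnFaceAngiogram) -> None:
    """Write the JSON metadata sidecar next to an image file."""
    meta = {
        "layer": angiogram.layer.value,
        "field_of_view_mm": angiogram.geometry.field_of_view_mm,
        "grid_size_px": angiogram.geometry.grid_size_px,
        "signal_strength_index": angiogram.signal_strength_index,
    }
    Path(path).write_text(json.dumps(meta, indent=2) + "\n")


def read_sidecar(path: str | Path) -> dict:
    meta = json.loads(Path(path).read_text())
    return meta


def read_angiogram_with_sidecar(image_path: str | Path) -> EnFaceAngiogram:
    """Read an image whose metadata lives in ``<image>.json`` next to it."""
    image_path = Path(image_path)
    meta = read_sidecar(image_path.with_suffix(image_path.suffix + ".json"))
    geometry = ScanGeometry(
        field_of_view_mm=meta["field_of_view_mm"],
        grid_size_px=meta["grid_size_px"],
    )
    return read_angiogram(
        image_path,
        layer=meta["layer"],
        geometry=geometry,
        signal_strength_index=meta.get("signal_strength_index"),
    )
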
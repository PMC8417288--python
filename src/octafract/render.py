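"""Rendered maps: colored ratio contours and the three-class palette image.

The contour PNG is a pictorial probability-of-vessel index (filled contours
of the normalized ratio); the class PNG uses the conventional palette:
red = vessel, yellow = small-vessel spacing, blue = large-vessel spacing.
Outputs are deterministic bytes for a fixed input and palette.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # noqa: E402 — headless, deterministic backend
import matplotlib.pyplot as plt
import numpy as np
import tifffile
from PIL import Image

from .fractal import FractalRatioMap
from .metrics import LARGE_SPACING, SMALL_SPACING, VESSEL, PixelClassMap

#: RGB palette per class label (red vessels, yellow small, blue large spacing).
CLASS_PALETTE = {
    VESSEL: (220, 30, 30),
    SMALL_SPACING: (240, 210, 40),
    LARGE_SPACING: (40, 70, 220),
}


def write_ratio_tiff(path: str | Path, ratio: FractalRatioMap) -> None:
    """Export the normalized ratio map as a 32-bit float TIFF."""
    tifffile.imwrite(Path(path), ratio.values.astype(np.float32))


def render_ratio_contour(
    path: str | Path,
    ratio: FractalRatioMap,
    levels: int = 10,
    cmap: str = "viridis",
) -> None:
    """Filled-contour PNG of the normalized ratio in [0, 1]."""
    fig, ax = plt.subplots(figsize=(4, 4), dpi=150)
    ax.contourf(ratio.values[::-1], levels=np.linspace(0, 1, levels + 1), cmap=cmap)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(Path(path), bbox_inches="tight", pad_inches=0, metadata={"Software": None})
    plt.close(fig)


def render_class_map(path: str | Path, classes: PixelClassMap) -> None:
    """Indexed-palette PNG of the class map with the fixed red/yellow/blue palette."""
    labels = classes.labels
    img = Image.fromarray(labels.astype(np.uint8), mode="P")
    palette = [0] * 768
    for label, rgb in CLASS_PALETTE.items():
        palette[3 * label : 3 * label + 3] = rgb
    img.putpalette(palette)
    img.save(Path(path))


def render_maps(
    ratio: FractalRatioMap, classes: PixelClassMap, out_dir: str | Path, prefix: str = "map"
) -> dict[str, Path]:
    """Write the contour, class-map and float-TIFF exports into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ratio_contour_png": out / f"{prefix}_ratio_contour.png",
        "class_map_png": out / f"{prefix}_classes.png",
        "ratio_tiff": out / f"{prefix}_ratio.tif",
    }
    render_ratio_contour(paths["ratio_contour_png"], ratio)
    render_class_map(paths["class_map_png"], classes)
    write_ratio_tiff(paths["ratio_tiff"], ratio)
    return paths
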
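"""Local box-counting fractal dimension and the normalized ratio map.

The local fractal dimension (FD) of a binarized angiogram represents the
presence of vessels: a pixel centred in a dense capillary mesh sees a nearly
space-filling pattern (FD -> 2), a pixel on an isolated vessel sees a curve
(FD -> 1), and a pixel in an avascular region sees nothing (FD = 0 by
convention). Dividing the FD map by its own maximum gives the normalized
ratio in [0, 1] that drives the vessel / small-spacing / large-spacing
classification.

Box-counting convention
-----------------------
For each pixel a square window of ``window_px`` (odd) is centred on it and
clipped at the image border. For every box size ``s`` the clipped window is
tiled with s x s boxes anchored at the window's top-left corner; trailing
partial boxes that do not fit are discarded (floor tiling). ``N(s)`` is the
number of boxes containing at least one foreground pixel, and the FD is the
least-squares slope of ``log N(s)`` against ``log(1/s)``. Floor tiling keeps
the scales consistent (a filled window measures 2.0 exactly for power-of-two
box sizes) whereas counting partial boxes would bias the slope low.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .model import BinaryMask, EnFaceAngiogram

DEFAULT_WINDOW_PX = 33
DEFAULT_BOX_SIZES_PX = (16, 8, 4, 2)


@dataclass
class FractalMap:
    """Per-pixel local box-counting dimension in [0, 2]."""

    values: np.ndarray
    window_px: int
    box_sizes_px: tuple[int, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.box_sizes_px = tuple(int(s) for s in self.box_sizes_px)


@dataclass
class FractalRatioMap:
    """FD map normalized by its own maximum; values in [0, 1]."""

    values: np.ndarray
    max_fd: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def binarize(angiogram: EnFaceAngiogram) -> BinaryMask:
    """Threshold an angiogram by between-class-variance maximization (Otsu).

    A constant image yields an all-background mask with a warning; a mask with
    more than 60% foreground (e.g. inverted contrast) also warns.
    """
    pixels = angiogram.pixels
    if np.ptp(pixels) == 0:
        warnings.warn(
            "constant image: no threshold exists, returning all-background mask",
            stacklevel=2,
        )
        return BinaryMask(np.zeros_like(pixels, dtype=bool), angiogram.geometry)
    if pixels.max() <= 1.0:
        # histogram over the calibrated [0, 1] domain, not the per-image range,
        # so near-identical images cannot land on different bin edges; upper
        # bin edges make "> thr" match the bin cut (the cut bin is background)
        counts, edges = np.histogram(pixels, bins=256, range=(0.0, 1.0))
        thr = threshold_otsu(hist=(counts, edges[1:]))
    else:
        thr = threshold_otsu(pixels)
    fg = pixels > thr
    frac = fg.mean()
    if frac > 0.6:
        warnings.warn(
            f"foreground fraction {frac:.2f} > 0.6: check image contrast "
            "(vessels are expected bright on dark)",
            stacklevel=2,
        )
    return BinaryMask(fg, angiogram.geometry)


def _integral_image(mask: np.ndarray) -> np.ndarray:
    n, m = mask.shape
    ii = np.zeros((n + 1, m + 1), dtype=np.int64)
    np.cumsum(np.cumsum(mask, axis=0), axis=1, out=ii[1:, 1:])
    return ii


def _box_occupancy(ii: np.ndarray, s: int) -> np.ndarray:
    """occ[a, b] = True iff the s x s box with top-left (a, b) holds foreground."""
    counts = ii[s:, s:] - ii[:-s, s:] - ii[s:, :-s] + ii[:-s, :-s]
    return counts > 0


def local_fractal_dimension(
    mask: BinaryMask,
    window_px: int = DEFAULT_WINDOW_PX,
    box_sizes_px: tuple[int, ...] = DEFAULT_BOX_SIZES_PX,
) -> FractalMap:
    """Sliding-window box-counting dimension at every pixel.

    Parameters
    ----------
    mask : BinaryMask
        Binarized angiogram; True marks vessel pixels.
    window_px : int
        Odd window side; must be >= the largest box size. 33 px (~0.33 mm at
        a 3-mm field of view) spans several capillary spacings while staying
        local.
    box_sizes_px : tuple of int
        Strictly decreasing box sizes; at least 3 are required for the
        log-log slope to be reliable.

    Pixels whose clipped window contains no foreground get dimension 0.
    """
    sizes = tuple(int(s) for s in box_sizes_px)
    if len(sizes) < 3:
        raise ValueError("at least 3 box sizes are required for a reliable slope")
    if any(s2 >= s1 for s1, s2 in zip(sizes, sizes[1:])):
        raise ValueError("box sizes must be strictly decreasing")
    if sizes[-1] < 1:
        raise ValueError("box sizes must be positive")
    if window_px % 2 == 0 or window_px < 1:
        raise ValueError("window_px must be odd and positive")
    if window_px < sizes[0]:
        raise ValueError("window_px must be >= the largest box size")

    grid = mask.pixels
    n, m = grid.shape
    r = window_px // 2
    ii = _integral_image(grid)

    rows = np.arange(n)
    cols = np.arange(m)
    ws_r = np.maximum(rows - r, 0)
    we_r = np.minimum(rows + r + 1, n)
    ws_c = np.maximum(cols - r, 0)
    we_c = np.minimum(cols + r + 1, m)

    # window occupancy: FD is 0 wherever the clipped window holds no foreground
    win_counts = (
        ii[we_r[:, None], we_c[None, :]]
        - ii[ws_r[:, None], we_c[None, :]]
        - ii[we_r[:, None], ws_c[None, :]]
        + ii[ws_r[:, None], ws_c[None, :]]
    )
    has_fg = win_counts > 0

    log_counts = np.empty((len(sizes), n, m), dtype=float)
    for si, s in enumerate(sizes):
        occ = _box_occupancy(ii, s)
        boxes = np.zeros((n, m), dtype=np.int32)
        kmax = window_px // s
        for k in range(kmax):
            top_r = ws_r + k * s
            valid_r = top_r + s <= we_r
            occ_rows = occ[np.minimum(top_r, occ.shape[0] - 1), :]
            occ_rows = occ_rows & valid_r[:, None]
            for l in range(kmax):
                top_c = ws_c + l * s
                valid_c = top_c + s <= we_c
                col = occ_rows[:, np.minimum(top_c, occ.shape[1] - 1)]
                boxes += col & valid_c[None, :]
        # clamp: a window with foreground only in a discarded border strip can
        # count 0 boxes at some scale; log(1) keeps the regression finite
        log_counts[si] = np.log(np.maximum(boxes, 1))

    x = -np.log(np.asarray(sizes, dtype=float))
    xc = x - x.mean()
    weights = xc / (xc**2).sum()
    fd = np.tensordot(weights, log_counts, axes=(0, 0))
    fd = np.clip(fd, 0.0, 2.0)
    fd[~has_fg] = 0.0
    return FractalMap(values=fd, window_px=window_px, box_sizes_px=sizes)


def normalized_ratio_map(fd: FractalMap) -> FractalRatioMap:
    """Divide the FD map by its own maximum.

    Self-normalization makes the classification bands robust to the window
    and box-size choice. An all-zero map (no vessels anywhere) yields
    all-zero ratios with a warning.
    """
    max_fd = float(fd.values.max(initial=0.0))
    if max_fd <= 0.0:
        warnings.warn(
            "fractal map is all zero (no foreground): ratio map set to 0",
            stacklevel=2,
        )
        return FractalRatioMap(values=np.zeros_like(fd.values), max_fd=0.0)
    return FractalRatioMap(values=fd.values / max_fd, max_fd=max_fd)
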
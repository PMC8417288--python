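"""Domain types shared by every pipeline stage.

Coordinate convention: images are 0-based, row-major, origin at the top-left
pixel; the fovea sits at the grid centre ``((N-1)/2, (N-1)/2)`` for an N-pixel
axis. All physical quantities are in millimetres.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np


class Layer(str, enum.Enum):
    """Retinal slab an en face angiogram was projected from."""

    SCP = "SCP"  # superficial capillary plexus
    DCP = "DCP"  # deep capillary plexus
    OR = "OR"  # outer retina
    CC = "CC"  # choriocapillaris


#: Device-reported scan quality below which a report is flagged (not rejected).
LOW_SSI_THRESHOLD = 40.0


@dataclass(frozen=True)
class ScanGeometry:
    """Physical geometry of an en face scan.

    Parameters
    ----------
    field_of_view_mm : float
        Side length of the square scan area, e.g. 3.0 for a 3 x 3 mm macular
        scan centred on the fovea.
    grid_size_px : int
        Number of pixels per axis (304 for a 304 A-scan x 304 B-scan volume).
    center_px : tuple of float, optional
        (row, col) pixel coordinate of the fovea. Defaults to the grid centre.
    """

    field_of_view_mm: float = 3.0
    grid_size_px: int = 304
    center_px: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.field_of_view_mm <= 0:
            raise ValueError("field_of_view_mm must be positive")
        if self.grid_size_px <= 0:
            raise ValueError("grid_size_px must be positive")
        if self.center_px is None:
            c = (self.grid_size_px - 1) / 2.0
            object.__setattr__(self, "center_px", (c, c))
        r, c = self.center_px
        n = self.grid_size_px
        if not (0 <= r <= n - 1 and 0 <= c <= n - 1):
            raise ValueError("fovea center must lie inside the grid")

    @property
    def pixel_pitch_mm(self) -> float:
        """Physical size of one (square) pixel."""
        return self.field_of_view_mm / self.grid_size_px

    @property
    def shape(self) -> tuple[int, int]:
        return (self.grid_size_px, self.grid_size_px)

    def pixel_area_mm2(self) -> float:
        """Area of a single pixel in mm^2 (pitch squared)."""
        return self.pixel_pitch_mm**2

    def radial_distance_mm(self) -> np.ndarray:
        """Per-pixel distance from the fovea centre, in mm."""
        rr, cc = np.indices(self.shape)
        r0, c0 = self.center_px
        return np.hypot(rr - r0, cc - c0) * self.pixel_pitch_mm


def pixel_area_mm2(geometry: ScanGeometry) -> float:
    """Area of one pixel, ``(field_of_view_mm / grid_size_px)**2``."""
    return geometry.pixel_area_mm2()


@dataclass
class EnFaceAngiogram:
    """Single-channel en face flow image.

    ``pixels`` holds decorrelation-like intensities rescaled to [0, 1];
    ``signal_strength_index`` is the device quality metric (scans < 40 are
    flagged in reports, never rejected by the analysis).
    """

    pixels: np.ndarray
    layer: Layer
    geometry: ScanGeometry
    signal_strength_index: float | None = None
    pa_removed: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("angiogram pixels must be a 2-D array")
        if self.pixels.shape != self.geometry.shape:
            raise ValueError(
                f"pixel grid {self.pixels.shape} does not match geometry "
                f"{self.geometry.shape}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("angiogram intensities must be finite")
        if self.pixels.size and self.pixels.min() < 0:
            raise ValueError("angiogram intensities must be non-negative")
        self.layer = Layer(self.layer)

    @property
    def low_signal(self) -> bool:
        ssi = self.signal_strength_index
        return ssi is not None and ssi < LOW_SSI_THRESHOLD


@dataclass
class BinaryMask:
    """Boolean foreground mask sharing the geometry of its source image."""

    pixels: np.ndarray
    geometry: ScanGeometry

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.shape != self.geometry.shape:
            raise ValueError(
                f"mask shape {self.pixels.shape} does not match geometry "
                f"{self.geometry.shape}"
            )

    def count(self) -> int:
        return int(self.pixels.sum())


@dataclass
class VascularMetrics:
    """Band percentages and FAZ area for one layer over one analysis region.

    The three percentages are computed over the same region and partition it,
    so they sum to 100 up to floating-point rounding. ``faz_area_mm2`` is
    ``None`` when no avascular region could be found (reported as absent, the
    situation described clinically as "no FAZ seen").
    """

    vessel_density_pct: float
    small_spacing_pct: float
    large_spacing_pct: float
    layer: Layer
    faz_area_mm2: float | None = None
    region: str = "whole_image"

    def __post_init__(self) -> None:
        for name in ("vessel_density_pct", "small_spacing_pct", "large_spacing_pct"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{name}={v} outside [0, 100]")
        if self.faz_area_mm2 is not None and self.faz_area_mm2 < 0:
            raise ValueError("faz_area_mm2 must be non-negative")
        self.layer = Layer(self.layer)

    def as_dict(self) -> dict:
        return {
            "layer": self.layer.value,
            "region": self.region,
            "vessel_density_pct": self.vessel_density_pct,
            "small_spacing_pct": self.small_spacing_pct,
            "large_spacing_pct": self.large_spacing_pct,
            "faz_area_mm2": self.faz_area_mm2,
        }
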
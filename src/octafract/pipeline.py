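"""End-to-end analysis of one eye's SCP/DCP angiogram pair.

Stage order is fixed: (DCP only) projection-artifact removal, then
binarization, local fractal dimension, normalized ratio, three-band
classification, band percentages over the whole image and the parafoveal
ring, FAZ measurement, and z-scores against a normative reference. The DCP
is always quantified after artifact removal when removal is enabled
(the default), since contamination by superficial vessels inflates its
apparent vessel density.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

from .fractal import (
    DEFAULT_BOX_SIZES_PX,
    DEFAULT_WINDOW_PX,
    FractalRatioMap,
    binarize,
    local_fractal_dimension,
    normalized_ratio_map,
)
from .metrics import (
    ClassBands,
    PixelClassMap,
    band_percentages,
    classify_pixels,
    measure_faz_from_mask,
    parafoveal_ring,
    whole_image_region,
)
from .model import EnFaceAngiogram, Layer, VascularMetrics
from .projection import ProjectionEstimate, estimate_projection, remove_projection


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the analysis pipeline."""

    window_px: int = DEFAULT_WINDOW_PX
    box_sizes_px: tuple[int, ...] = DEFAULT_BOX_SIZES_PX
    bands: ClassBands = field(default_factory=ClassBands)
    remove_projection_artifact: bool = True
    ring_inner_d_mm: float = 1.0
    ring_outer_d_mm: float = 2.5
    faz_closing_radius_px: int = 10

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        from pathlib import Path

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "bands" in raw:
            raw["bands"] = ClassBands(**raw["bands"])
        if "box_sizes_px" in raw:
            raw["box_sizes_px"] = tuple(raw["box_sizes_px"])
        return cls(**raw)


@dataclass
class NormativeReference:
    """Per-layer normative (mean, sd) for each vascular metric.

    The shipped defaults encode a published normative cohort for this scan
    protocol; they are device- and population-specific and should be replaced
    for any other instrument.
    """

    per_layer: dict[str, dict[str, tuple[float, float]]]

    def __post_init__(self) -> None:
        for layer, metrics in self.per_layer.items():
            for name, (mean, sd) in metrics.items():
                if sd <= 0:
                    raise ValueError(f"{layer}.{name}: sd must be positive, got {sd}")

    @classmethod
    def default(cls) -> "NormativeReference":
        ref = importlib.resources.files("octafract") / "data" / "normative_reference.yaml"
        return cls.from_yaml_text(ref.read_text())

    @classmethod
    def from_yaml_text(cls, text: str) -> "NormativeReference":
        raw = yaml.safe_load(text)
        per_layer = {
            layer: {k: (float(v["mean"]), float(v["sd"])) for k, v in metrics.items()}
            for layer, metrics in raw.items()
        }
        return cls(per_layer=per_layer)

    @classmethod
    def from_yaml(cls, path) -> "NormativeReference":
        from pathlib import Path

        return cls.from_yaml_text(Path(path).read_text())


def compare_to_normative(
    metrics: VascularMetrics, ref: NormativeReference
) -> dict[str, float]:
    """z = (measured - mean) / sd per metric; |z| > 2 counts as outside normal."""
    layer = metrics.layer.value
    if layer not in ref.per_layer:
        raise ValueError(f"no normative reference for layer {layer}")
    zs: dict[str, float] = {}
    values = metrics.as_dict()
    for name, (mean, sd) in ref.per_layer[layer].items():
        measured = values.get(name)
        if measured is None:
            continue
        zs[name] = (measured - mean) / sd
    return zs


@dataclass
class LayerResult:
    """Everything computed for one plexus."""

    metrics_whole: VascularMetrics
    metrics_ring: VascularMetrics
    faz_area_mm2: float | None
    ratio: FractalRatioMap
    classes: PixelClassMap
    z_scores: dict[str, float]


@dataclass
class EyeReport:
    """Per-eye analysis output with quality flags."""

    scp: LayerResult
    dcp: LayerResult
    projection: ProjectionEstimate | None
    flags: list[str]

    def as_dict(self) -> dict:
        def layer_dict(lr: LayerResult) -> dict:
            return {
                "whole_image": lr.metrics_whole.as_dict(),
                "parafoveal_ring": lr.metrics_ring.as_dict(),
                "faz_area_mm2": lr.faz_area_mm2,
                "z_scores": lr.z_scores,
            }

        proj = None
        if self.projection is not None:
            proj = {
                "scale_alpha": self.projection.scale_alpha,
                "correlation_r": self.projection.correlation_r,
                "ls_slope": self.projection.ls_slope,
                "clamped": self.projection.clamped,
            }
        return {
            "SCP": layer_dict(self.scp),
            "DCP": layer_dict(self.dcp),
            "projection_estimate": proj,
            "flags": sorted(self.flags),
        }


def _analyze_layer(
    image: EnFaceAngiogram,
    config: AnalysisConfig,
    ref: NormativeReference | None,
) -> tuple[LayerResult, list[str]]:
    flags: list[str] = []
    mask = binarize(image)
    fd = local_fractal_dimension(mask, config.window_px, config.box_sizes_px)
    ratio = normalized_ratio_map(fd)
    classes = classify_pixels(ratio, config.bands, image.geometry)
    whole = band_percentages(classes, whole_image_region(image.geometry), image.layer)
    ring = band_percentages(
        classes,
        parafoveal_ring(image.geometry, config.ring_inner_d_mm, config.ring_outer_d_mm),
        image.layer,
    )
    faz = measure_faz_from_mask(
        mask.pixels, image.geometry, closing_radius_px=config.faz_closing_radius_px
    )
    if faz is None:
        flags.append(f"faz_absent_{image.layer.value}")
    whole.faz_area_mm2 = faz
    zs = compare_to_normative(whole, ref) if ref is not None else {}
    return (
        LayerResult(
            metrics_whole=whole,
            metrics_ring=ring,
            faz_area_mm2=faz,
            ratio=ratio,
            classes=classes,
            z_scores=zs,
        ),
        flags,
    )


def analyze_eye(
    scp: EnFaceAngiogram,
    dcp: EnFaceAngiogram,
    config: AnalysisConfig | None = None,
    normative: NormativeReference | None = None,
) -> EyeReport:
    """Run the full quantification pipeline on one SCP/DCP pair."""
    config = config or AnalysisConfig()
    if normative is None:
        normative = NormativeReference.default()
    if scp.geometry != dcp.geometry:
        raise ValueError("SCP and DCP geometries differ")
    flags: list[str] = []
    for img in (scp, dcp):
        if img.low_signal:
            flags.append(f"low_ssi_{img.layer.value}")

    projection: ProjectionEstimate | None = None
    dcp_for_metrics = dcp
    if config.remove_projection_artifact:
        projection = estimate_projection(scp, dcp)
        if projection.clamped:
            flags.append("projection_scale_clamped")
        dcp_for_metrics = remove_projection(scp, dcp, projection)

    scp_result, f1 = _analyze_layer(scp, config, normative)
    dcp_result, f2 = _analyze_layer(dcp_for_metrics, config, normative)
    flags.extend(f1)
    flags.extend(f2)
    return EyeReport(scp=scp_result, dcp=dcp_result, projection=projection, flags=flags)
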
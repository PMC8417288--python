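"""Projection-artifact removal from the deep capillary plexus.

Light that has passed through flowing superficial blood decorrelates, so the
deep-layer angiogram carries a ghost copy of the superficial vasculature.
The removal is software-based: the zero-lag normalized cross-correlation
between the layers is computed, a whole-image scaling factor is estimated,
and the scaled superficial image is subtracted from the deep one.

Estimating the scaling factor
-----------------------------
The subtraction needs an amplitude, not a unit-free coefficient. The naive
least-squares slope of DCP on SCP (covariance over variance) is biased low
whenever the artifact saturates bright pixels at the intensity ceiling, and
restricting the fit to unsaturated pixels only replaces that bias with a
truncation bias. The estimator used here is therefore a conditional-median
amplitude: the superficial image is split into its flow and background
populations (between-class-variance threshold), and

    alpha = (median DCP over SCP-flow px - median DCP over SCP-background px)
            / (median SCP over SCP-flow px - median SCP over SCP-background px)

Medians are immune to the saturated tail and to the deep layer's own
vasculature as long as deep flow covers less than half of each population,
which holds for en face angiograms. The least-squares slope and the Pearson
correlation are reported alongside as diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .model import EnFaceAngiogram

#: alpha outside this range is clamped (with a warning): a projection
#: artifact cannot plausibly exceed 1.5x the superficial signal.
ALPHA_CLAMP = (0.0, 1.5)


@dataclass(frozen=True)
class ProjectionEstimate:
    """Fitted contamination of the deep layer by the superficial one.

    ``scale_alpha`` is the conditional-median amplitude used for subtraction;
    ``ls_slope`` is the classical least-squares slope and ``correlation_r``
    the zero-lag normalized cross-correlation, both reported for reference.
    """

    scale_alpha: float
    correlation_r: float
    ls_slope: float
    clamped: bool = False


def zero_lag_correlation(scp: EnFaceAngiogram, dcp: EnFaceAngiogram) -> float:
    """Pearson correlation of the mean-subtracted images over all pixels."""
    x = scp.pixels.ravel()
    y = dcp.pixels.ravel()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant image: correlation is undefined")
    xm = x - x.mean()
    ym = y - y.mean()
    return float((xm @ ym) / np.sqrt((xm @ xm) * (ym @ ym)))


def estimate_projection(
    scp: EnFaceAngiogram, dcp: EnFaceAngiogram
) -> ProjectionEstimate:
    """Correlation and scaling factor between superficial and deep layers.

    Raises
    ------
    ValueError
        If either image is constant (correlation undefined) or the
        geometries differ.
    """
    if scp.geometry != dcp.geometry:
        raise ValueError("SCP and DCP geometries differ")
    x = scp.pixels.ravel()
    y = dcp.pixels.ravel()
    r = zero_lag_correlation(scp, dcp)

    xm = x - x.mean()
    ls = float((xm @ (y - y.mean())) / (xm @ xm))

    fg = x > threshold_otsu(scp.pixels)
    if not fg.any() or fg.all():
        alpha = ls  # no two populations to compare; fall back to the slope
    else:
        dx = float(np.median(x[fg]) - np.median(x[~fg]))
        dy = float(np.median(y[fg]) - np.median(y[~fg]))
        alpha = dy / dx if dx > 0 else ls

    lo, hi = ALPHA_CLAMP
    clamped = not (lo <= alpha <= hi)
    if clamped:
        warnings.warn(
            f"projection scale {alpha:.3f} clamped to [{lo}, {hi}]", stacklevel=2
        )
        alpha = float(np.clip(alpha, lo, hi))
    return ProjectionEstimate(
        scale_alpha=alpha, correlation_r=r, ls_slope=ls, clamped=clamped
    )


def remove_projection(
    scp: EnFaceAngiogram,
    dcp: EnFaceAngiogram,
    estimate: ProjectionEstimate | None = None,
) -> EnFaceAngiogram:
    """Subtract ``alpha x SCP`` from the DCP, clipped to [0, 1].

    Clipping at zero slightly raises background statistics (decorrelation
    signal is non-negative); the corrected image keeps the DCP layer label
    with ``pa_removed=True``.
    """
    if scp.geometry != dcp.geometry:
        raise ValueError("SCP and DCP geometries differ")
    if estimate is None:
        estimate = estimate_projection(scp, dcp)
    corrected = np.clip(dcp.pixels - estimate.scale_alpha * scp.pixels, 0.0, 1.0)
    return EnFaceAngiogram(
        pixels=corrected,
        layer=dcp.layer,
        geometry=dcp.geometry,
        signal_strength_index=dcp.signal_strength_index,
        pa_removed=True,
    )
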
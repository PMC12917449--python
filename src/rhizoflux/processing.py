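"""Inverse imaging chain: raw counts -> transmission -> optical thickness
-> per-pixel volumetric water content.

The chain mirrors standard neutron-radiograph quantification: dark-current
subtraction, flat-field normalization, subtraction of an additive scattered
fraction, logarithmic transformation to optical thickness, and subtraction
of the dry-box optical thickness (aluminum walls + dry soil) so that the
residual is attributable to water alone:

    T      = (counts - dark) / (flat - dark) - scatter_frac
    OT     = -ln(T)
    theta  = (OT - OT_dry) / (mu_w * path_thickness)

All reference frames pass through the identical correction path before
use (the dry-box optical thickness is computed, never assumed).  Pixels
whose corrected transmission falls below a small positive floor are marked
invalid rather than silently clamped; negative water contents are floored
at zero with the floored-pixel count reported, as a noise diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import AttenuationParams, RadiographFrame, RhizoboxSpec

__all__ = [
    "TRANSMISSION_FLOOR",
    "CorrectionSet",
    "WaterContentMap",
    "correct_frame",
    "optical_thickness",
    "water_content",
    "total_water",
    "process_frame",
    "process_series",
]

#: Transmission floor below which a pixel is flagged invalid.
TRANSMISSION_FLOOR = 1e-6


@dataclass
class CorrectionSet:
    """Reference frames and the scattered fraction used to correct counts."""

    flat: np.ndarray
    dark: np.ndarray
    dry_reference: np.ndarray
    scatter_frac: float = 0.0

    def __post_init__(self) -> None:
        self.flat = np.asarray(self.flat, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        self.dry_reference = np.asarray(self.dry_reference, dtype=float)
        if self.flat.shape != self.dark.shape or self.flat.shape != self.dry_reference.shape:
            raise ValueError("reference frames must share one shape")
        if np.any(self.flat - self.dark <= 0.0):
            raise ValueError("flat - dark must be strictly positive everywhere")


@dataclass
class WaterContentMap:
    """Per-pixel volumetric water content with a validity mask."""

    theta: np.ndarray
    valid_mask: np.ndarray
    n_floored: int = 0  # pixels with negative theta floored at 0

    def __post_init__(self) -> None:
        if self.theta.shape != self.valid_mask.shape:
            raise ValueError("theta and valid_mask must share one shape")


def _counts(frame) -> np.ndarray:
    if isinstance(frame, RadiographFrame):
        return np.asarray(frame.counts, dtype=float)
    return np.asarray(frame, dtype=float)


def correct_frame(frame, corrections: CorrectionSet):
    """Dark/flat/scatter-corrected transmission map.

    Returns ``(T, valid_mask)``: transmission clipped below at
    ``TRANSMISSION_FLOOR`` with clipped pixels recorded as invalid.
    """
    counts = _counts(frame)
    if counts.shape != corrections.flat.shape:
        raise ValueError(
            f"frame shape {counts.shape} != reference shape {corrections.flat.shape}"
        )
    t = (counts - corrections.dark) / (corrections.flat - corrections.dark)
    t = t - corrections.scatter_frac
    valid = t > TRANSMISSION_FLOOR
    return np.where(valid, t, TRANSMISSION_FLOOR), valid


def optical_thickness(transmission: np.ndarray) -> np.ndarray:
    """OT = -ln(T).  Invalid (floored) pixels propagate as large OT."""
    return -np.log(transmission)


def water_content(
    ot: np.ndarray,
    dry_ot: np.ndarray,
    atten: AttenuationParams,
    box: RhizoboxSpec,
    valid_mask: np.ndarray | None = None,
) -> WaterContentMap:
    """Water content from the water-only optical thickness.

    ``theta = (OT - OT_dry) / (mu_w * path_thickness)`` per pixel; negative
    values are floored at 0 and counted.
    """
    denom = atten.mu_w * box.path_thickness
    if denom == 0.0:
        raise ValueError("mu_w * path_thickness must be nonzero")
    theta = (np.asarray(ot, dtype=float) - np.asarray(dry_ot, dtype=float)) / denom
    negative = theta < 0.0
    n_floored = int(np.count_nonzero(negative))
    theta = np.where(negative, 0.0, theta)
    if valid_mask is None:
        valid_mask = np.ones_like(theta, dtype=bool)
    return WaterContentMap(theta=theta, valid_mask=valid_mask.copy(), n_floored=n_floored)


def total_water(water_map: WaterContentMap, box: RhizoboxSpec) -> float:
    """Total water volume (cm3): sum of theta * pixel area * path thickness
    over valid pixels."""
    cell = box.pixel_size**2 * box.path_thickness
    return float(np.sum(water_map.theta[water_map.valid_mask]) * cell)


def make_corrections(
    flat_frame, dark_frame, dry_frame, scatter_frac: float = 0.0
) -> tuple[CorrectionSet, np.ndarray]:
    """Build a CorrectionSet and the dry-box optical thickness.

    The dry reference passes through the same correction path as every
    sample frame.
    """
    corr = CorrectionSet(
        flat=_counts(flat_frame),
        dark=_counts(dark_frame),
        dry_reference=_counts(dry_frame),
        scatter_frac=scatter_frac,
    )
    t_dry, _ = correct_frame(corr.dry_reference, corr)
    return corr, optical_thickness(t_dry)


def process_frame(
    frame,
    corrections: CorrectionSet,
    dry_ot: np.ndarray,
    atten: AttenuationParams,
    box: RhizoboxSpec,
) -> WaterContentMap:
    """Full chain for one frame: counts -> theta map."""
    t, valid = correct_frame(frame, corrections)
    return water_content(optical_thickness(t), dry_ot, atten, box, valid_mask=valid)


def process_series(
    frames,
    corrections: CorrectionSet,
    dry_ot: np.ndarray,
    atten: AttenuationParams,
    box: RhizoboxSpec,
):
    """Process an iterable of frames lazily.

    Yields ``(frame, WaterContentMap)`` pairs; use
    :func:`rhizoflux.dynamics.compartment_series` to reduce them against a
    mask set.
    """
    for frame in frames:
        yield frame, process_frame(frame, corrections, dry_ot, atten, box)
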
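"""Root segmentation, skeletonization and rhizosphere/bulk mask building.

The measurement convention follows projection radiography of a thin box:
each skeleton pixel integrates the root plus the soil in front of and
behind it along the ~1 cm beam path, so the "rhizosphere" compartment is
the skeleton pixel set itself (a root+adjacent-soil column), not a
geometric annulus.  The bulk compartment is the soil region minus a disk
dilation of the skeleton wide enough to exclude root-associated pixels.

Segmentation is intended to run once per sample on the time-averaged
water-content map of the wet phase (highest root/soil contrast) and the
resulting masks are held fixed across the time series.  For low-contrast
substrates a manually delineated skeleton can be imported from a polyline
CSV instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, morphology, restoration

from .simulate import rasterize_skeleton

__all__ = [
    "MaskSet",
    "denoise",
    "segment_roots",
    "skeletonize_mask",
    "import_manual_skeleton",
    "build_masks",
]


@dataclass
class MaskSet:
    """Skeleton, rhizosphere and bulk masks partitioning the soil region.

    Invariants: rhizosphere contains the skeleton, rhizosphere and bulk are
    disjoint, and bulk is the soil region minus the disk-dilated skeleton.
    """

    skeleton: np.ndarray
    rhizosphere: np.ndarray
    bulk: np.ndarray
    dilation_radius_px: int

    def __post_init__(self) -> None:
        shapes = {self.skeleton.shape, self.rhizosphere.shape, self.bulk.shape}
        if len(shapes) != 1:
            raise ValueError("all masks must share one shape")
        if np.any(self.skeleton & ~self.rhizosphere):
            raise ValueError("rhizosphere must contain the skeleton")
        if np.any(self.rhizosphere & self.bulk):
            raise ValueError("rhizosphere and bulk must be disjoint")


def denoise(image: np.ndarray, median_size: int = 3) -> np.ndarray:
    """Median filter followed by nonlocal-means.

    The median stage removes impulse noise; nonlocal means (patch 5,
    search window 11) smooths Poisson-limited texture with strength tied
    to the estimated noise standard deviation.  A noise-free image passes
    through nearly unchanged.
    """
    image = np.asarray(image, dtype=float)
    med = ndimage.median_filter(image, size=median_size)
    sigma = restoration.estimate_sigma(med)
    if sigma <= 0 or not np.isfinite(sigma):
        return med
    return restoration.denoise_nl_means(
        med,
        patch_size=5,
        patch_distance=5,  # 11 x 11 search window
        h=0.8 * sigma,
        sigma=sigma,
        fast_mode=True,
    )


def segment_roots(
    image: np.ndarray,
    block_size: int = 51,
    offset_k: float = 3.0,
    min_size: int = 30,
    opening_radius: int = 0,
    closing_radius: int = 2,
) -> np.ndarray:
    """Adaptive-threshold + morphology segmentation of bright root structures.

    A pixel is foreground when it exceeds its local (Gaussian-weighted)
    mean by ``offset_k`` times a robust estimate of the image noise; the
    mask is then optionally opened to drop speckle, closed (radius 2) to
    bridge thin gaps, and filtered for connected components smaller than
    ``min_size`` pixels.  The default opening radius is 0 because roots
    only one or two pixels wide do not survive a disk opening; the
    component-size filter does the speckle rejection instead.  The rule is
    invariant to any affine intensity rescaling with positive gain,
    because both the local mean and the noise scale transform along with
    the image.

    Returns an empty mask (with no error) when nothing stands out.
    """
    image = np.asarray(image, dtype=float)
    local_mean = filters.threshold_local(image, block_size=block_size, method="gaussian")
    residual = image - local_mean
    # robust residual scale; median absolute deviation avoids the roots
    # themselves inflating the threshold
    sigma = 1.4826 * np.median(np.abs(residual - np.median(residual)))
    if sigma == 0.0:
        sigma = np.finfo(float).tiny
    mask = residual > offset_k * sigma
    if opening_radius > 0:
        mask = morphology.opening(mask, morphology.disk(opening_radius))
    if closing_radius > 0:
        mask = morphology.closing(mask, morphology.disk(closing_radius))
    mask = _drop_small(mask, min_size)
    return mask


def _drop_small(mask: np.ndarray, min_size: int) -> np.ndarray:
    """Remove connected components with fewer than ``min_size`` pixels."""
    labels, n = ndimage.label(mask)
    if n == 0 or min_size <= 1:
        return mask
    counts = np.bincount(labels.ravel())
    keep = counts >= min_size
    keep[0] = False
    return keep[labels]


def skeletonize_mask(mask: np.ndarray) -> np.ndarray:
    """Topology-preserving thinning of a binary mask to 1-px centerlines."""
    mask = np.asarray(mask, dtype=bool)
    return morphology.skeletonize(mask)


def import_manual_skeleton(path, frame_shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a manually delineated skeleton.

    Accepts a polyline CSV with columns ``branch,row,col`` (one vertex per
    line, 0-based pixel coordinates, origin top-left).  Out-of-bounds
    vertices are rejected with the offending branch named.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"branch", "row", "col"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"malformed skeleton file {path}: need columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    rows, cols = frame_shape
    bad = df[(df.row < 0) | (df.row > rows - 1) | (df.col < 0) | (df.col > cols - 1)]
    if len(bad):
        b = bad.iloc[0]
        raise ValueError(
            f"skeleton vertex ({b.row}, {b.col}) of branch {int(b.branch)} "
            f"lies outside the {rows}x{cols} frame"
        )
    polylines = [g[["row", "col"]].to_numpy(float) for _, g in df.groupby("branch")]
    return rasterize_skeleton(polylines, frame_shape)


def build_masks(
    skeleton: np.ndarray,
    soil_region: np.ndarray,
    dilation_radius_px: int,
) -> MaskSet:
    """Build the rhizosphere (= skeleton) and bulk (= soil minus dilated
    skeleton) masks.

    ``dilation_radius_px`` is typically ``ceil(0.1 cm / pixel_size)``; it
    must leave some bulk soil.
    """
    skeleton = np.asarray(skeleton, dtype=bool)
    soil_region = np.asarray(soil_region, dtype=bool)
    if skeleton.shape != soil_region.shape:
        raise ValueError("skeleton and soil_region must share one shape")
    if np.any(skeleton & ~soil_region):
        raise ValueError("skeleton must lie within the soil region")
    if dilation_radius_px < 0:
        raise ValueError("dilation_radius_px must be >= 0")
    if dilation_radius_px == 0:
        dilated = skeleton
    else:
        dilated = morphology.dilation(skeleton, morphology.disk(dilation_radius_px))
    bulk = soil_region & ~dilated
    if skeleton.any() and not bulk.any():
        raise ValueError(
            f"dilation radius {dilation_radius_px} px covers the entire soil "
            "region: no bulk soil remains"
        )
    return MaskSet(
        skeleton=skeleton,
        rhizosphere=skeleton & soil_region,
        bulk=bulk,
        dilation_radius_px=dilation_radius_px,
    )
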
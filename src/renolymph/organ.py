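"""Whole-kidney volume and normalized lymphatic metrics.

Kidney volume is estimated from an intensity channel (the
autofluorescence envelope when present): Gaussian smoothing with
σ = 5 pixels in-plane (the z sigma is scaled by the spacing ratio so
smoothing is physically isotropic), Li thresholding, per-slice and 3D
hole filling, then the largest 3D connected component.  The normalized
metrics divide branch count and network volume by kidney volume;
branch density is reported per mm³ and occupancy as a percentage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from .config import OrganSegmentationParams
from .core import BinaryMask, ChannelStack, UM3_PER_MM3, VoxelGrid, physical_volume
from .graph import NetworkSummary
from .segmentation import auto_threshold

__all__ = ["OrganMetrics", "estimate_kidney_volume", "normalize_metrics", "organ_channel"]

logger = logging.getLogger(__name__)


@dataclass
class OrganMetrics:
    kidney_volume: float  # mm³
    branches_per_mm3: float
    occupancy_percent: float  # % of kidney volume occupied by the network

    def as_dict(self) -> dict:
        return {
            "kidney_volume_mm3": self.kidney_volume,
            "branches_per_mm3": self.branches_per_mm3,
            "occupancy_percent": self.occupancy_percent,
        }


def organ_channel(stack: ChannelStack, preferred: Optional[str] = None) -> VoxelGrid:
    """Channel used for kidney-volume estimation.

    ``preferred`` wins when given; otherwise AUTOFLUOR when present,
    else the LYVE-1 channel (whose smoothed envelope approximates the
    organ outline).
    """
    if preferred is not None:
        return stack[preferred]
    if "AUTOFLUOR" in stack:
        return stack["AUTOFLUOR"]
    logger.info("no AUTOFLUOR channel; estimating organ volume from LYVE1")
    return stack["LYVE1"]


def estimate_kidney_volume(
    grid: VoxelGrid, params: Optional[OrganSegmentationParams] = None
) -> Tuple[float, BinaryMask]:
    """Estimate whole-kidney volume (mm³) and return the organ mask.

    Pipeline: Gaussian smooth (σ in pixels, in-plane convention) → Li
    (or configured) threshold → intermeans refinement → fill holes per
    z-slice and in 3D → keep the largest 3D component → voxel volume
    sum, reported in mm³.

    The refinement iterates the threshold to the mean of the two class
    means (IsoData), starting from the histogram threshold.  On smooth
    organ surfaces the minimum-cross-entropy threshold sits far down
    the Gaussian-blurred edge skirt and inflates the volume by >10%;
    the intermeans fixed point places the boundary at the edge's
    half-height, where the enclosed volume matches the true surface.
    """
    params = params or OrganSegmentationParams()
    data = grid.data.astype(np.float32)
    if data.max() == data.min():
        raise ValueError("constant image: cannot segment the organ")
    sz, sy, sx = grid.spacing
    sigma = (params.gaussian_sigma * sy / sz, params.gaussian_sigma, params.gaussian_sigma)
    smoothed = ndimage.gaussian_filter(data, sigma=sigma)
    smoothed_grid = VoxelGrid(
        np.clip(smoothed, 0, 2 ** grid.dtype_bits - 1), grid.spacing, grid.dtype_bits
    )
    mask = auto_threshold(smoothed_grid, params.threshold_method)
    threshold = mask.threshold
    if params.refine_intermeans:
        for _ in range(50):
            below, above = smoothed < threshold, smoothed >= threshold
            if not below.any() or not above.any():
                break
            refined = 0.5 * (smoothed[below].mean() + smoothed[above].mean())
            if abs(refined - threshold) < 1e-3:
                break
            threshold = refined
        mask = BinaryMask(smoothed >= threshold, grid.spacing)
        mask.threshold = threshold
    filled = mask.data
    if params.fill_holes:
        for z in range(filled.shape[0]):
            filled[z] = ndimage.binary_fill_holes(filled[z])
        filled = ndimage.binary_fill_holes(filled)
    struct = ndimage.generate_binary_structure(3, 3 if params.connectivity == 26 else 1)
    labels, n = ndimage.label(filled, structure=struct)
    if n == 0:
        raise ValueError("organ segmentation produced an empty mask")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    organ = BinaryMask(labels == int(sizes.argmax()), grid.spacing)
    volume_mm3 = physical_volume(organ) / UM3_PER_MM3
    return volume_mm3, organ


def normalize_metrics(summary: NetworkSummary, kidney_volume_mm3: float) -> OrganMetrics:
    """Branch density (per mm³) and network occupancy (% of kidney volume)."""
    if kidney_volume_mm3 <= 0:
        raise ValueError("kidney volume must be positive")
    network_mm3 = summary.total_volume / UM3_PER_MM3
    return OrganMetrics(
        kidney_volume=float(kidney_volume_mm3),
        branches_per_mm3=summary.n_branches / kidney_volume_mm3,
        occupancy_percent=100.0 * network_mm3 / kidney_volume_mm3,
    )
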
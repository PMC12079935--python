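"""Threshold-based metabolic tumor segmentation and perimeter extraction.

The lesion is the 26-connected component, seeded at the hotspot, of all
voxels at or above a fraction of the hotspot SUV (default 40%). The tumor
boundary is the outermost layer of mask voxels: those with at least one
face-adjacent (6-neighborhood) neighbor outside the mask, the grid border
counting as outside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DegenerateLesionError, InvalidArgumentError, InvalidInputError
from .image_core import PETVolume, VoxelIndex

__all__ = ["SegmentationResult", "segment_tumor", "extract_perimeter", "perimeter_mask"]

_CONN26 = np.ones((3, 3, 3), dtype=bool)  # vertex adjacency for the tumor body
_CONN6 = ndimage.generate_binary_structure(3, 1)  # face adjacency for the boundary


@dataclass(frozen=True)
class SegmentationResult:
    """One segmented lesion: mask, hotspot seed, threshold, boundary layer."""

    mask: np.ndarray
    hotspot: VoxelIndex
    threshold_suv: float
    perimeter: frozenset[VoxelIndex]
    perimeter_array: np.ndarray = field(repr=False)  # (n, 3) int voxel indices

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


def perimeter_mask(mask: np.ndarray) -> np.ndarray:
    """Boolean array marking mask voxels with a face-neighbor outside the mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise InvalidInputError("mask is empty")
    interior = ndimage.binary_erosion(mask, structure=_CONN6, border_value=0)
    return mask & ~interior


def extract_perimeter(mask: np.ndarray) -> frozenset[VoxelIndex]:
    """The outermost layer of mask voxels, as a set of voxel indices."""
    boundary = perimeter_mask(mask)
    return frozenset(
        VoxelIndex(int(i), int(j), int(k)) for i, j, k in zip(*np.nonzero(boundary))
    )


def segment_tumor(
    volume: PETVolume,
    hotspot: VoxelIndex,
    threshold_fraction: float = 0.40,
) -> SegmentationResult:
    """Segment the lesion containing ``hotspot`` by relative thresholding.

    ``threshold_suv = threshold_fraction * SUV(hotspot)``; the mask is the
    26-connected component of ``{SUV >= threshold_suv}`` containing the
    hotspot (inclusive comparison, so the hotspot itself always belongs).
    """
    frac = float(threshold_fraction)
    if not (0.0 < frac < 1.0):
        raise InvalidArgumentError(f"threshold fraction must lie in (0, 1), got {frac}")
    if not volume.contains_index(hotspot):
        raise InvalidArgumentError(f"hotspot {tuple(hotspot)} outside volume {volume.shape}")
    hotspot = VoxelIndex(*(int(c) for c in hotspot))
    peak = float(volume.values[hotspot])
    if peak <= 0:
        raise DegenerateLesionError(f"hotspot SUV must be positive, got {peak}")

    threshold = frac * peak
    above = volume.values >= threshold
    labels, _ = ndimage.label(above, structure=_CONN26)
    mask = labels == labels[hotspot]

    boundary = perimeter_mask(mask)
    coords = np.argwhere(boundary)
    perimeter = frozenset(VoxelIndex(*(int(c) for c in row)) for row in coords)
    return SegmentationResult(
        mask=mask,
        hotspot=hotspot,
        threshold_suv=threshold,
        perimeter=perimeter,
        perimeter_array=coords,
    )
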
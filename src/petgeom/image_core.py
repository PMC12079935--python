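"""PET volume representation, isotropic resampling, and hotspot location.

Conventions used throughout the package:

* voxel indices are 0-based ``(i, j, k)`` triples;
* the physical position of a voxel center is ``index * spacing`` in mm;
* all distances are Euclidean distances between voxel centers, in mm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import ndimage

from .errors import InvalidArgumentError, InvalidInputError

__all__ = ["PETVolume", "VoxelIndex", "resample_isotropic", "find_hotspot"]


class VoxelIndex(NamedTuple):
    """0-based grid coordinates of one voxel."""

    i: int
    j: int
    k: int


@dataclass(frozen=True)
class PETVolume:
    """A 3D standardized-uptake-value grid with physical voxel spacing.

    Parameters
    ----------
    values
        3D array of SUV (dimensionless, body-weight normalized). Must be
        finite and non-negative.
    spacing
        Voxel edge lengths ``(sx, sy, sz)`` in mm, strictly positive.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        values = np.ascontiguousarray(np.asarray(self.values, dtype=np.float64))
        if values.ndim != 3:
            raise InvalidInputError(f"expected a 3D volume, got {values.ndim}D")
        if values.size == 0 or min(values.shape) < 1:
            raise InvalidInputError("volume must contain at least one voxel")
        if not np.all(np.isfinite(values)):
            raise InvalidInputError("SUV values must all be finite")
        if np.any(values < 0):
            raise InvalidInputError("SUV values must be non-negative")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3:
            raise InvalidArgumentError("spacing must have three components")
        if any(not np.isfinite(s) or s <= 0 for s in spacing):
            raise InvalidArgumentError(f"spacing must be strictly positive, got {spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def position_mm(self, index: Sequence[int]) -> np.ndarray:
        """Physical coordinates (mm) of a voxel center."""
        return np.asarray(index, dtype=np.float64) * np.asarray(self.spacing)

    def contains_index(self, index: Sequence[int]) -> bool:
        return all(0 <= int(c) < n for c, n in zip(index, self.shape))


def resample_isotropic(volume: PETVolume, target_spacing_mm: float = 3.0) -> PETVolume:
    """Resample a volume onto an isotropic grid by trilinear interpolation.

    The output grid keeps the voxel-center-at-origin convention: new centers
    lie at ``j * target`` mm along each axis, covering the span of the input
    voxel centers (physical extent preserved to within one voxel). Values are
    clipped at zero.

    A volume already on the target isotropic grid is returned unchanged
    (identity grid, bit-for-bit).
    """
    target = float(target_spacing_mm)
    if not np.isfinite(target) or target <= 0:
        raise InvalidArgumentError(f"target spacing must be positive, got {target_spacing_mm}")
    if volume.values.size == 0:
        raise InvalidInputError("cannot resample an empty volume")

    if all(abs(s - target) <= 1e-12 * target for s in volume.spacing):
        return PETVolume(volume.values.copy(), (target, target, target))

    new_shape = tuple(
        max(1, int(np.floor((n - 1) * s / target + 1e-9)) + 1)
        for n, s in zip(volume.shape, volume.spacing)
    )
    # Interpolation coordinates in input index units: j * target / s.
    axes = [
        np.arange(m, dtype=np.float64) * (target / s)
        for m, s in zip(new_shape, volume.spacing)
    ]
    grid = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([g.ravel() for g in grid])
    resampled = ndimage.map_coordinates(
        volume.values, coords, order=1, mode="nearest"
    ).reshape(new_shape)
    np.clip(resampled, 0.0, None, out=resampled)
    return PETVolume(resampled, (target, target, target))


def find_hotspot(
    volume: PETVolume, search_mask: Optional[np.ndarray] = None
) -> VoxelIndex:
    """Locate the voxel with maximum SUV.

    Ties are broken by the lexicographically smallest ``(i, j, k)``. When
    ``search_mask`` is given the maximum is taken over the masked region only.
    """
    values = volume.values
    if search_mask is not None:
        mask = np.asarray(search_mask, dtype=bool)
        if mask.shape != values.shape:
            raise InvalidArgumentError(
                f"search mask shape {mask.shape} does not match volume shape {values.shape}"
            )
        if not mask.any():
            raise InvalidInputError("search mask selects no voxels")
        # SUV >= 0, so -1 can never win inside the mask.
        values = np.where(mask, values, -1.0)
    flat = int(np.argmax(values))  # first occurrence in C order == lexicographic min
    return VoxelIndex(*(int(c) for c in np.unravel_index(flat, values.shape)))
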
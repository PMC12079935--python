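"""Conventional and geometric PET parameters for one segmented lesion.

Quantities computed per lesion:

* ``suv_max``, ``suv_mean`` — extrema over the segmented mask;
* ``mtv_ml`` — metabolic tumor volume in mL;
* ``tlg`` — total lesion glycolysis, ``suv_mean * mtv_ml`` by construction;
* ``r_equiv_mm`` — radius of the sphere with the lesion's volume,
  ``(3 V / 4 pi)^(1/3)`` with V in mm^3;
* ``nhoc_max`` — hotspot-to-centroid distance divided by ``r_equiv_mm``;
* ``nhop_max`` — minimum hotspot-to-perimeter distance divided by
  ``r_equiv_mm``.

``nhoc_max`` grows and ``nhop_max`` shrinks as the hotspot migrates from the
lesion center toward its edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .errors import InvalidArgumentError, InvalidInputError
from .image_core import PETVolume, VoxelIndex, find_hotspot, resample_isotropic
from .segmentation import SegmentationResult, segment_tumor

__all__ = [
    "TumorMetrics",
    "compute_mtv",
    "compute_suv_stats",
    "compute_tlg",
    "compute_centroid",
    "equivalent_sphere_radius",
    "compute_nhoc",
    "compute_nhop",
    "extract_metrics",
    "METRICS_CSV_COLUMNS",
]

METRICS_CSV_COLUMNS = (
    "suv_max",
    "suv_mean",
    "mtv_ml",
    "tlg",
    "nhoc_max",
    "nhop_max",
    "r_equiv_mm",
    "centroid_x_mm",
    "centroid_y_mm",
    "centroid_z_mm",
    "flags",
)


@dataclass(frozen=True)
class TumorMetrics:
    """All per-lesion parameters, plus provenance of how they were obtained."""

    suv_max: float
    suv_mean: float
    mtv_ml: float
    tlg: float
    centroid_mm: tuple[float, float, float]
    r_equiv_mm: float
    nhoc_max: float
    nhop_max: float
    hotspot: VoxelIndex
    flags: tuple[str, ...] = ()
    provenance: Mapping[str, object] = field(default_factory=dict)

    def to_row(self) -> dict[str, object]:
        """One CSV row with the frozen column schema."""
        cx, cy, cz = self.centroid_mm
        return {
            "suv_max": self.suv_max,
            "suv_mean": self.suv_mean,
            "mtv_ml": self.mtv_ml,
            "tlg": self.tlg,
            "nhoc_max": self.nhoc_max,
            "nhop_max": self.nhop_max,
            "r_equiv_mm": self.r_equiv_mm,
            "centroid_x_mm": cx,
            "centroid_y_mm": cy,
            "centroid_z_mm": cz,
            "flags": ";".join(self.flags),
        }


def _validated_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise InvalidInputError("mask is empty")
    return mask


def compute_mtv(mask: np.ndarray, spacing: Sequence[float]) -> float:
    """Metabolic tumor volume in mL: voxel count times voxel volume."""
    mask = _validated_mask(mask)
    sx, sy, sz = (float(s) for s in spacing)
    return int(mask.sum()) * (sx * sy * sz) / 1000.0


def compute_suv_stats(volume: PETVolume, mask: np.ndarray) -> tuple[float, float]:
    """(SUVmax, SUVmean) over the mask voxels."""
    mask = _validated_mask(mask)
    if mask.shape != volume.shape:
        raise InvalidArgumentError("mask shape does not match volume shape")
    inside = volume.values[mask]
    return float(inside.max()), float(inside.mean())


def compute_tlg(suv_mean: float, mtv_ml: float) -> float:
    """Total lesion glycolysis: SUVmean times MTV."""
    if suv_mean < 0 or mtv_ml < 0:
        raise InvalidArgumentError("suv_mean and mtv_ml must be non-negative")
    return float(suv_mean) * float(mtv_ml)


def compute_centroid(
    mask: np.ndarray,
    spacing: Sequence[float],
    weights: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Centroid of mask voxel centers in mm.

    Unweighted geometric centroid by default; pass ``weights`` (same shape as
    the mask) for an intensity-weighted variant.
    """
    mask = _validated_mask(mask)
    coords = np.argwhere(mask).astype(np.float64)
    if weights is None:
        center = coords.mean(axis=0)
    else:
        w = np.asarray(weights, dtype=np.float64)[mask]
        total = w.sum()
        if total <= 0:
            raise InvalidArgumentError("weights must have positive total mass")
        center = (coords * w[:, None]).sum(axis=0) / total
    return center * np.asarray([float(s) for s in spacing])


def equivalent_sphere_radius(mtv_ml: float) -> float:
    """Radius (mm) of a sphere whose volume equals ``mtv_ml``."""
    if not mtv_ml > 0:
        raise InvalidArgumentError(f"volume must be positive, got {mtv_ml}")
    volume_mm3 = 1000.0 * float(mtv_ml)
    return (3.0 * volume_mm3 / (4.0 * math.pi)) ** (1.0 / 3.0)


def compute_nhoc(
    hotspot: Sequence[int],
    centroid_mm: Sequence[float],
    r_equiv_mm: float,
    spacing: Sequence[float],
) -> float:
    """Normalized hotspot-to-centroid distance."""
    if not r_equiv_mm > 0:
        raise InvalidArgumentError("equivalent radius must be positive")
    hotspot_mm = np.asarray(hotspot, dtype=np.float64) * np.asarray(
        [float(s) for s in spacing]
    )
    distance = float(np.linalg.norm(hotspot_mm - np.asarray(centroid_mm, dtype=np.float64)))
    return distance / float(r_equiv_mm)


def compute_nhop(
    hotspot: Sequence[int],
    perimeter: Iterable[Sequence[int]],
    r_equiv_mm: float,
    spacing: Sequence[float],
) -> float:
    """Normalized minimum hotspot-to-perimeter distance.

    The distance is taken between voxel centers; a hotspot lying on the
    perimeter therefore yields exactly 0.
    """
    if not r_equiv_mm > 0:
        raise InvalidArgumentError("equivalent radius must be positive")
    coords = np.asarray(
        perimeter if isinstance(perimeter, np.ndarray) else sorted(tuple(p) for p in perimeter),
        dtype=np.float64,
    )
    if coords.size == 0:
        raise InvalidInputError("perimeter is empty")
    scale = np.asarray([float(s) for s in spacing])
    deltas = (coords - np.asarray(hotspot, dtype=np.float64)) * scale
    distance = float(np.sqrt((deltas**2).sum(axis=1).min()))
    return distance / float(r_equiv_mm)


def extract_metrics(
    volume: PETVolume,
    *,
    target_spacing_mm: Optional[float] = 3.0,
    threshold_fraction: float = 0.40,
    suv_weighted_centroid: bool = False,
    search_mask: Optional[np.ndarray] = None,
) -> TumorMetrics:
    """Run the full preprocessing chain and return every per-lesion metric.

    Steps: resample to an isotropic grid (skipped when ``target_spacing_mm``
    is None), locate the hotspot, segment at ``threshold_fraction`` of the
    hotspot SUV, then compute SUV statistics, MTV, TLG, centroid,
    equivalent-sphere radius, NHOCmax and NHOPmax.

    A degenerate single-voxel lesion yields ``nhoc_max = nhop_max = 0`` with a
    ``"degenerate_lesion"`` flag instead of an error, so batch extraction
    never aborts.
    """
    flags: list[str] = []
    if target_spacing_mm is not None:
        working = resample_isotropic(volume, target_spacing_mm)
        if search_mask is not None and working.shape != volume.shape:
            raise InvalidArgumentError(
                "search_mask requires target_spacing_mm=None or an input volume "
                "already on the target grid"
            )
    else:
        working = volume

    hotspot = find_hotspot(working, search_mask)
    seg: SegmentationResult = segment_tumor(working, hotspot, threshold_fraction)

    mtv_ml = compute_mtv(seg.mask, working.spacing)
    suv_max, suv_mean = compute_suv_stats(working, seg.mask)
    tlg = compute_tlg(suv_mean, mtv_ml)
    weights = working.values if suv_weighted_centroid else None
    centroid = compute_centroid(seg.mask, working.spacing, weights=weights)
    r_equiv = equivalent_sphere_radius(mtv_ml)

    if seg.voxel_count <= 1:
        flags.append("degenerate_lesion")
        nhoc = 0.0
        nhop = 0.0
    else:
        nhoc = compute_nhoc(hotspot, centroid, r_equiv, working.spacing)
        nhop = compute_nhop(hotspot, seg.perimeter_array, r_equiv, working.spacing)

    provenance = {
        "input_shape": tuple(volume.shape),
        "input_spacing_mm": tuple(volume.spacing),
        "working_spacing_mm": tuple(working.spacing),
        "target_spacing_mm": target_spacing_mm,
        "threshold_fraction": threshold_fraction,
        "threshold_suv": seg.threshold_suv,
        "centroid_weighting": "suv_weighted" if suv_weighted_centroid else "geometric",
        "mask_voxels": seg.voxel_count,
        "perimeter_voxels": len(seg.perimeter),
    }
    return TumorMetrics(
        suv_max=suv_max,
        suv_mean=suv_mean,
        mtv_ml=mtv_ml,
        tlg=tlg,
        centroid_mm=tuple(float(c) for c in centroid),
        r_equiv_mm=r_equiv,
        nhoc_max=nhoc,
        nhop_max=nhop,
        hotspot=hotspot,
        flags=tuple(flags),
        provenance=provenance,
    )
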
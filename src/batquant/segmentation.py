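"""Supraclavicular adipose tissue (scAT) and active-BAT segmentation.

The MR-path workflow composes four primitives: a manual anatomical outline
(an input, not an algorithm), a fat-fraction window (default 400–1000‰), a
body mask from the in-phase volume, and a one-voxel erosion against partial
volume effects. Intersecting the result with an SUV >= 1.5 g/ml PET
segmentation isolates the metabolically active portion of the depot. The
PET/CT path swaps the FF window for a −190…−10 HU adipose radiodensity
window. A paired-sphere comparison places one sphere at the hottest PET
voxel and one in a quiet region of the depot to contrast the fat fraction of
active versus inactive tissue within an individual.

All threshold intervals are closed at both ends, so a voxel exactly at a
bound is included.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .dixon import FatFractionMap
from .volumes import Grid, SegmentationMask, Volume3D

__all__ = [
    "SegmentationParams",
    "threshold_mask",
    "intersect",
    "shrink",
    "body_mask",
    "segment_scat_mr",
    "segment_bat_active",
    "segment_scat_ct",
    "place_paired_spheres",
    "sphere_mask",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Thresholds and geometry knobs for the segmentation workflow.

    ff_window: closed FF interval in per mille defining adipose tissue.
    suv_threshold: g/ml; voxels at or above count as metabolically active.
    hu_window: closed CT interval in HU defining adipose tissue.
    body_mask_quantile: fraction of the in-phase robust maximum (99th
        percentile) used as the body threshold.
    shrink_voxels: erosion repetitions applied to final segmentations.
    sphere_diameter_fraction: paired-sphere diameter as a fraction of the
        largest in-plane world extent of the volume.
    """

    ff_window: tuple[float, float] = (400.0, 1000.0)
    suv_threshold: float = 1.5
    hu_window: tuple[float, float] = (-190.0, -10.0)
    body_mask_quantile: float = 0.2
    shrink_voxels: int = 1
    sphere_diameter_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.ff_window[0] > self.ff_window[1]:
            raise ValueError("ff_window is empty")
        if self.hu_window[0] > self.hu_window[1]:
            raise ValueError("hu_window is empty")
        if self.suv_threshold <= 0:
            raise ValueError("suv_threshold must be positive")
        if self.shrink_voxels < 0:
            raise ValueError("shrink_voxels must be >= 0")


# 6-connected (face-adjacent) structuring element; one application is the
# closest integer analog of a one-voxel margin shrink on near-isotropic grids.
_CROSS = ndimage.generate_binary_structure(3, 1)


def threshold_mask(volume: Volume3D, lo: float, hi: float = math.inf) -> SegmentationMask:
    """Mask of voxels with lo <= value <= hi (closed interval)."""
    if lo > hi:
        raise ValueError("lower threshold exceeds upper threshold")
    vals = volume.values
    return SegmentationMask(values=(vals >= lo) & (vals <= hi), grid=volume.grid)


def intersect(masks: list[SegmentationMask]) -> SegmentationMask:
    """Voxelwise logical AND of masks sharing one grid."""
    if not masks:
        raise ValueError("need at least one mask")
    grid = masks[0].grid
    out = masks[0].values.copy()
    for m in masks[1:]:
        grid.require_match(m.grid, "masks to intersect")
        out &= m.values
    return SegmentationMask(values=out, grid=grid)


def shrink(mask: SegmentationMask, voxels: int = 1) -> SegmentationMask:
    """Erode by ``voxels`` applications of the 6-connected cross."""
    if voxels < 0:
        raise ValueError("erosion count must be >= 0")
    if voxels == 0:
        return SegmentationMask(values=mask.values.copy(), grid=mask.grid)
    eroded = ndimage.binary_erosion(mask.values, structure=_CROSS,
                                    iterations=voxels, border_value=0)
    return SegmentationMask(values=eroded, grid=mask.grid)


def body_mask(in_phase: Volume3D, quantile: float = 0.2) -> SegmentationMask:
    """Threshold the in-phase volume and keep the largest component.

    The threshold is ``quantile`` times the 99th percentile of the in-phase
    intensities — a robust fraction-of-maximum rule that separates the body
    from air background regardless of how much of the field of view the
    subject fills.
    """
    vals = in_phase.values
    if np.any(vals < 0):
        raise ValueError("in-phase volume must be nonnegative")
    thr = quantile * np.percentile(vals, 99)
    if thr <= 0:
        raise ValueError("body mask is empty: no signal above threshold")
    fg = vals >= thr
    labels, n = ndimage.label(fg)
    if n == 0:
        raise ValueError("body mask is empty: no signal above threshold")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    keep = 1 + int(np.argmax(sizes))
    return SegmentationMask(values=labels == keep, grid=in_phase.grid)


def segment_scat_mr(anatomical: SegmentationMask, ff: FatFractionMap,
                    in_phase: Volume3D,
                    params: SegmentationParams = SegmentationParams()
                    ) -> SegmentationMask:
    """MR-path depot segmentation: anatomy ∩ FF window ∩ body, then shrink."""
    if anatomical.is_empty():
        raise ValueError("anatomical delineation is empty")
    anatomical.grid.require_match(ff.ff.grid, "anatomical mask and FF map")
    ff_mask = intersect([threshold_mask(ff.ff, *params.ff_window), ff.valid_mask])
    body = body_mask(in_phase, params.body_mask_quantile)
    result = shrink(intersect([anatomical, ff_mask, body]), params.shrink_voxels)
    if result.is_empty():
        raise ValueError("no supraclavicular adipose tissue after filtering")
    return result


def segment_bat_active(scat: SegmentationMask, suv: Volume3D,
                       params: SegmentationParams = SegmentationParams()
                       ) -> SegmentationMask:
    """Metabolically active depot: scat ∩ {SUV >= threshold}.

    May legitimately be empty — a BAT-negative subject.
    """
    if suv.units != "g_per_ml":
        raise ValueError("SUV map must be tagged g_per_ml")
    return intersect([scat, threshold_mask(suv, params.suv_threshold)])


def segment_scat_ct(anatomical: SegmentationMask, ct: Volume3D, suv: Volume3D,
                    params: SegmentationParams = SegmentationParams()
                    ) -> SegmentationMask:
    """PET/CT-path segmentation: anatomy ∩ HU window ∩ SUV window, shrunk."""
    if ct.units != "HU":
        raise ValueError("CT volume must be tagged HU")
    hu_mask = threshold_mask(ct, *params.hu_window)
    pet_mask = threshold_mask(suv, params.suv_threshold)
    result = shrink(intersect([anatomical, hu_mask, pet_mask]),
                    params.shrink_voxels)
    if result.is_empty():
        raise ValueError("no metabolically active adipose tissue after filtering")
    return result


# ---------------------------------------------------------------------------
# Paired spheres

def _sphere_offsets(grid: Grid, radius_mm: float) -> np.ndarray:
    """Boolean kernel of voxels whose world distance to center <= radius."""
    half = [int(radius_mm // s) for s in grid.spacing]
    axes = [np.arange(-h, h + 1) * s for h, s in zip(half, grid.spacing)]
    dx, dy, dz = np.meshgrid(*axes, indexing="ij")
    return (dx ** 2 + dy ** 2 + dz ** 2) <= radius_mm ** 2 + 1e-9


def sphere_mask(grid: Grid, center_index: tuple[int, int, int],
                radius_mm: float) -> SegmentationMask:
    """Sphere of world radius ``radius_mm`` centered on a voxel index."""
    kern = _sphere_offsets(grid, radius_mm)
    out = np.zeros(grid.shape, dtype=bool)
    kc = [k // 2 for k in kern.shape]
    src = []
    dst = []
    for ax in range(3):
        lo = center_index[ax] - kc[ax]
        hi = lo + kern.shape[ax]
        s_lo = max(0, -lo)
        s_hi = kern.shape[ax] - max(0, hi - grid.shape[ax])
        src.append(slice(s_lo, s_hi))
        dst.append(slice(lo + s_lo, lo + s_hi))
    out[tuple(dst)] = kern[tuple(src)]
    return SegmentationMask(values=out, grid=grid)


def sphere_radius_mm(grid: Grid, diameter_fraction: float) -> float:
    """World radius: fraction of the largest in-plane (first two axes) extent."""
    extents = [sh * sp for sh, sp in zip(grid.shape[:2], grid.spacing[:2])]
    return 0.5 * diameter_fraction * max(extents)


def place_paired_spheres(suv: Volume3D, scat: SegmentationMask,
                         active: SegmentationMask,
                         params: SegmentationParams = SegmentationParams()
                         ) -> tuple[SegmentationMask, SegmentationMask]:
    """PET-positive and PET-negative sphere ROIs within the depot.

    The positive sphere sits on the maximal-SUV voxel inside ``scat`` and is
    intersected with ``active``. The negative sphere is centered on the scat
    voxel (at least one radius away from the positive center and with zero
    sphere overlap with ``active``) whose sphere has minimal mean SUV; ties
    break toward the lowest voxel index. It is intersected with ``scat``.
    """
    suv.grid.require_match(scat.grid, "SUV map and depot mask")
    suv.grid.require_match(active.grid, "SUV map and active mask")
    if scat.is_empty():
        raise ValueError("depot segmentation is empty")
    if active.is_empty():
        raise ValueError("no metabolically active tissue: cannot place the "
                         "PET-positive sphere")
    grid = suv.grid
    radius = sphere_radius_mm(grid, params.sphere_diameter_fraction)

    masked_suv = np.where(scat.values, suv.values, -np.inf)
    pos_center = np.unravel_index(int(np.argmax(masked_suv)), grid.shape)
    pos_sphere = sphere_mask(grid, pos_center, radius)
    positive = intersect([pos_sphere, active])

    kern = _sphere_offsets(grid, radius).astype(float)
    ksum = kern.sum()
    # sphere-mean SUV and sphere overlap with `active` for every center
    mean_suv = ndimage.convolve(suv.values.astype(float), kern,
                                mode="constant", cval=0.0) / ksum
    active_overlap = ndimage.convolve(active.values.astype(float), kern,
                                      mode="constant", cval=0.0)

    idx = np.indices(grid.shape)
    world_sq = sum(((idx[a] - pos_center[a]) * grid.spacing[a]) ** 2
                   for a in range(3))
    candidates = scat.values & (world_sq >= radius ** 2) & (active_overlap < 0.5)
    if not candidates.any():
        raise ValueError("no PET-negative region: depot has no quiet zone "
                         "clear of the active segmentation")
    cand_scores = np.where(candidates, mean_suv, np.inf)
    neg_center = np.unravel_index(int(np.argmin(cand_scores)), grid.shape)
    neg_sphere = sphere_mask(grid, neg_center, radius)
    negative = intersect([neg_sphere, scat])
    return positive, negative
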
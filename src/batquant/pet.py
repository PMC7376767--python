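"""FDG-PET quantification: decay correction, SUV maps, ROI summaries.

SUV (standardized uptake value, g/ml) normalises a tissue activity
concentration (Bq/ml) by the injected activity per gram of body weight, so a
uniform distribution of tracer over the whole body gives SUV = 1 everywhere.
Normalisation uses total body weight, and the injected dose is referenced to
scan start: vendor images are usually already decay-corrected there, so the
dose is used as-is by default, with explicit half-life correction available
for raw doses.
"""

from __future__ import annotations

from dataclasses import dataclass

from .volumes import SegmentationMask, Volume3D

__all__ = [
    "F18_HALF_LIFE_MIN",
    "PetAcquisition",
    "RoiSummary",
    "decay_correct",
    "suv_map",
    "summarize",
]

#: Physical half-life of fluorine-18 in minutes.
F18_HALF_LIFE_MIN = 109.77


@dataclass(frozen=True)
class PetAcquisition:
    """Injection and timing metadata needed to compute SUV."""

    injected_dose_mbq: float
    body_weight_kg: float
    uptake_interval_min: float = 30.0
    half_life_min: float = F18_HALF_LIFE_MIN

    def __post_init__(self) -> None:
        for name in ("injected_dose_mbq", "body_weight_kg",
                     "uptake_interval_min", "half_life_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class RoiSummary:
    """Mean/SD of a map over a mask plus the region's size."""

    mean: float
    sd: float
    voxel_count: int
    volume_ml: float


def decay_correct(dose_mbq: float, elapsed_min: float,
                  half_life_min: float = F18_HALF_LIFE_MIN) -> float:
    """Activity remaining after ``elapsed_min``: dose * 2^(-t / T_half)."""
    if half_life_min <= 0:
        raise ValueError("half-life must be positive")
    if elapsed_min < 0:
        raise ValueError("elapsed time must be nonnegative")
    return dose_mbq * 2.0 ** (-elapsed_min / half_life_min)


def suv_map(activity: Volume3D, acq: PetAcquisition,
            decay_corrected_input: bool = True) -> Volume3D:
    """Convert an activity-concentration volume (Bq/ml) to SUV (g/ml)."""
    if activity.units != "Bq_per_ml":
        raise ValueError(
            f"activity map must be tagged Bq_per_ml, got {activity.units!r}")
    dose_mbq = acq.injected_dose_mbq
    if not decay_corrected_input:
        dose_mbq = decay_correct(dose_mbq, acq.uptake_interval_min,
                                 acq.half_life_min)
    dose_bq = dose_mbq * 1e6
    weight_g = acq.body_weight_kg * 1000.0
    suv = activity.values / (dose_bq / weight_g)
    return activity.with_values(suv, units="g_per_ml")


def summarize(volume: Volume3D, mask: SegmentationMask) -> RoiSummary:
    """Mean and population SD of ``volume`` over the masked voxels.

    Voxels inside an ROI are the whole population of interest, hence the
    ``ddof=0`` SD; subject-level statistics elsewhere use the sample SD.
    """
    volume.grid.require_match(mask.grid, "map and mask")
    if mask.is_empty():
        raise ValueError("empty segmentation")
    vals = volume.values[mask.values]
    return RoiSummary(
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=0)),
        voxel_count=int(vals.size),
        volume_ml=mask.volume_ml,
    )
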
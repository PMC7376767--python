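"""3D volumes, masks, and grid-aware resampling.

Everything downstream (fat-fraction maps, SUV maps, segmentations) lives on
a :class:`Volume3D`. A volume carries its voxel grid explicitly — spacing in
mm, world origin, and a direction matrix — using the RAS world convention
with 0-based voxel indices. Masks are bound to the grid of the volume they
index; operations that mix grids raise instead of resampling silently.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Units",
    "Grid",
    "Volume3D",
    "SegmentationMask",
    "GridMismatchError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "resample_to_grid",
]

#: Recognised unit tags for Volume3D.
Units = ("arbitrary", "per_mille", "Bq_per_ml", "g_per_ml", "HU")


class GridMismatchError(ValueError):
    """Two objects that must share a voxel grid do not."""


@dataclass(frozen=True)
class Grid:
    """Voxel lattice in world (RAS) coordinates.

    ``world = origin + orientation @ (spacing * index)`` for 0-based indices.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: tuple[tuple[float, ...], ...] = (
        (1.0, 0.0, 0.0),
        (0.0, 1.0, 0.0),
        (0.0, 0.0, 1.0),
    )

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError("grid must have three axes, each of size >= 1")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be strictly positive")
        R = np.asarray(self.orientation, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise ValueError("orientation matrix must be orthonormal (3x3)")

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-to-world affine."""
        A = np.eye(4)
        R = np.asarray(self.orientation, dtype=float)
        A[:3, :3] = R * np.asarray(self.spacing)
        A[:3, 3] = self.origin
        return A

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def matches(self, other: "Grid", atol: float = 1e-5) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def require_match(self, other: "Grid", what: str = "volumes") -> None:
        if not self.matches(other):
            raise GridMismatchError(f"{what} are not on the same voxel grid")

    @classmethod
    def from_affine(cls, shape, affine: np.ndarray) -> "Grid":
        A = np.asarray(affine, dtype=float)
        M = A[:3, :3]
        spacing = np.linalg.norm(M, axis=0)
        R = M / spacing
        return cls(
            shape=tuple(int(s) for s in shape),
            spacing=tuple(float(s) for s in spacing),
            origin=tuple(float(o) for o in A[:3, 3]),
            orientation=tuple(tuple(float(v) for v in row) for row in R),
        )


@dataclass
class Volume3D:
    """A 3D scalar field on an explicit world grid with a units tag."""

    values: np.ndarray
    grid: Grid
    units: str = "arbitrary"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("Volume3D requires a 3D array")
        if tuple(self.values.shape) != self.grid.shape:
            raise ValueError("array shape does not match grid shape")
        if self.units not in Units:
            raise ValueError(f"unknown units tag {self.units!r}; expected one of {Units}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.grid.spacing

    def with_values(self, values: np.ndarray, units: str | None = None) -> "Volume3D":
        return Volume3D(values=values, grid=self.grid, units=units or self.units)


@dataclass
class SegmentationMask:
    """Boolean mask bound to the grid of the volume it indexes."""

    values: np.ndarray
    grid: Grid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError("mask requires a 3D array")
        if tuple(self.values.shape) != self.grid.shape:
            raise ValueError("mask shape does not match its reference grid")

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    @property
    def volume_ml(self) -> float:
        return self.voxel_count * self.grid.voxel_volume_ml

    def is_empty(self) -> bool:
        return not self.values.any()


def uniform_grid(shape, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> Grid:
    """Axis-aligned grid helper used throughout the phantoms and tests."""
    return Grid(shape=tuple(int(s) for s in shape),
                spacing=tuple(float(s) for s in spacing),
                origin=tuple(float(o) for o in origin))


# ---------------------------------------------------------------------------
# NIfTI I/O

def read_volume(path, units: str = "arbitrary") -> Volume3D:
    """Read a 3D NIfTI-1/NIfTI-2 image into a :class:`Volume3D`.

    Raises FileNotFoundError for a missing file, ValueError for a non-3D
    image, and nibabel's errors for an unreadable header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path.name}: not a 3D volume (ndim={data.ndim})")
    grid = Grid.from_affine(data.shape, img.affine)
    dtype = np.complex128 if np.iscomplexobj(data) else np.float64
    return Volume3D(values=data.astype(dtype), grid=grid, units=units)


def write_volume(volume: Volume3D, path) -> None:
    vals = np.asarray(volume.values)
    dtype = np.complex64 if np.iscomplexobj(vals) else np.float32
    img = nib.Nifti1Image(vals.astype(dtype), volume.grid.affine)
    nib.save(img, str(path))


def read_mask(path, expected_grid: Grid | None = None) -> SegmentationMask:
    """Read a uint8 {0,1} NIfTI mask; optionally enforce a reference grid."""
    vol = read_volume(path)
    mask = SegmentationMask(values=vol.values > 0.5, grid=vol.grid)
    if expected_grid is not None:
        expected_grid.require_match(mask.grid, "mask and expected reference")
    return mask


def write_mask(mask: SegmentationMask, path) -> None:
    img = nib.Nifti1Image(mask.values.astype(np.uint8), mask.grid.affine)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Resampling

def resample_to_grid(moving: Volume3D, reference: Volume3D | Grid,
                     mode: str = "trilinear", fill: float = 0.0) -> Volume3D:
    """Resample ``moving`` onto the grid of ``reference`` in world space.

    ``mode`` is ``trilinear`` or ``nearest``; nearest preserves the value set
    of the input. Values requested outside the moving volume get ``fill``.
    """
    if mode not in ("trilinear", "nearest"):
        raise ValueError("mode must be 'trilinear' or 'nearest'")
    ref_grid = reference.grid if isinstance(reference, Volume3D) else reference
    if moving.grid.matches(ref_grid):
        return Volume3D(values=moving.values.copy(), grid=ref_grid,
                        units=moving.units)

    A_mov = moving.grid.affine
    try:
        inv_mov = np.linalg.inv(A_mov)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - orthonormality guards this
        raise ValueError("moving volume orientation is not invertible") from exc
    # index_ref -> world -> index_mov, one combined affine
    T = inv_mov @ ref_grid.affine
    idx = np.indices(ref_grid.shape, dtype=float)
    coords = np.tensordot(T[:3, :3], idx, axes=1) + T[:3, 3][:, None, None, None]
    order = 1 if mode == "trilinear" else 0
    out = ndimage.map_coordinates(moving.values.astype(float), coords,
                                  order=order, mode="constant", cval=fill)
    return Volume3D(values=out, grid=ref_grid, units=moving.units)
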
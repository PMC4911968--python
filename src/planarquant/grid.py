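"""Core voxel/pixel data containers.

Axis convention (fixed throughout the package):

* axis 0 — left-right (x)
* axis 1 — anterior-posterior (y, anterior at index 0)
* axis 2 — caudal-cranial (z)

All planar projections are taken along axis 1, producing images on the
(x, z) plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

AXIS_X = 0
AXIS_AP = 1
AXIS_Z = 2

ANTERIOR = "anterior"
POSTERIOR = "posterior"


class GridMismatchError(ValueError):
    """Two grids that must share shape/spacing do not."""


@dataclass(frozen=True)
class VoxelGrid:
    """A 3D scalar field with voxel spacing in millimetres.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar values (counts, HU, or attenuation coefficient).
    spacing : tuple of float
        Voxel spacing in mm per axis, all strictly positive.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={data.ndim}")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (1 ml = 1000 mm^3)."""
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    def with_data(self, data: np.ndarray) -> "VoxelGrid":
        return replace(self, data=data)

    def same_grid(self, other: "VoxelGrid") -> bool:
        return self.shape == other.shape and np.allclose(
            self.spacing, other.spacing, rtol=0, atol=1e-9
        )

    def require_same_grid(self, other: "VoxelGrid") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"grid mismatch: {self.shape}@{self.spacing} vs "
                f"{other.shape}@{other.spacing}"
            )


@dataclass(frozen=True)
class Mask3D:
    """A binary volume of interest on the same grid as its source volume."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    label: str = ""

    def __post_init__(self) -> None:
        voxels = np.asarray(self.voxels)
        if voxels.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={voxels.ndim}")
        if voxels.dtype != bool:
            uniq = np.unique(voxels)
            if not np.isin(uniq, (0, 1)).all():
                raise ValueError("mask must be binary valued")
            voxels = voxels.astype(bool)
        object.__setattr__(self, "voxels", voxels)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_count(self) -> int:
        return int(self.voxels.sum())

    @property
    def voxel_volume_ml(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    @property
    def volume_ml(self) -> float:
        return self.voxel_count * self.voxel_volume_ml

    def is_subset_of(self, other: "Mask3D") -> bool:
        return bool((self.voxels & ~other.voxels).sum() == 0)


@dataclass(frozen=True)
class ROI2D:
    """A binary region on the (x, z) projection plane."""

    pixels: np.ndarray
    pixel_spacing: tuple[float, float]
    label: str = ""

    def __post_init__(self) -> None:
        pixels = np.asarray(self.pixels)
        if pixels.ndim != 2:
            raise ValueError(f"expected a 2D ROI, got ndim={pixels.ndim}")
        if pixels.dtype != bool:
            pixels = pixels.astype(bool)
        object.__setattr__(self, "pixels", pixels)
        object.__setattr__(
            self, "pixel_spacing", tuple(float(s) for s in self.pixel_spacing)
        )

    @property
    def pixel_count(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class PlanarImage:
    """A 2D planar count image on the (x, z) plane."""

    counts: np.ndarray
    pixel_spacing: tuple[float, float]
    view: str = ANTERIOR

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.float64)
        if counts.ndim != 2:
            raise ValueError(f"expected a 2D image, got ndim={counts.ndim}")
        if self.view not in (ANTERIOR, POSTERIOR):
            raise ValueError(f"view must be '{ANTERIOR}' or '{POSTERIOR}'")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(
            self, "pixel_spacing", tuple(float(s) for s in self.pixel_spacing)
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape
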
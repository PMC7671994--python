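"""Core spatial containers: volumes, masks, displacement fields, landmarks.

All containers share one world-coordinate convention: the world position of
voxel index ``i`` (0-based, numpy axis order == file axis order) is

    world(i) = origin + direction @ (spacing * i)

where ``direction`` is a 3x3 orthonormal matrix taken from the file header
and honored as stored -- no implicit RAS/LPS flip is ever performed.
Displacements are expressed in millimetres along the world axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["Volume3D", "BinaryMask", "DeformationField", "LandmarkSet"]

_EYE = np.eye(3)


def _as_direction(direction) -> np.ndarray:
    d = np.asarray(direction, dtype=float).reshape(3, 3)
    if not np.allclose(d @ d.T, _EYE, atol=1e-6):
        raise ValueError("direction matrix is not orthonormal within 1e-6")
    return d


@dataclass
class Volume3D:
    """A scalar 3D image with its sampling grid.

    Parameters
    ----------
    data : (nx, ny, nz) array
        Intensities; stored as float32 regardless of on-disk type.
    spacing : (3,) array, mm/voxel, all components > 0.
    origin : (3,) array, mm.
    direction : (3, 3) orthonormal matrix mapping index axes to world axes.
    """

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got {self.data.ndim}D")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("all spacing components must be > 0")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.direction = _as_direction(self.direction)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def index_to_world(self) -> np.ndarray:
        """3x3 matrix A with world(i) = origin + A @ i."""
        return self.direction * self.spacing[None, :]

    @property
    def world_to_index(self) -> np.ndarray:
        return np.linalg.inv(self.index_to_world)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def index_to_world_points(self, indices: np.ndarray) -> np.ndarray:
        """Map (N, 3) voxel indices (may be fractional) to world mm."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return self.origin + idx @ self.index_to_world.T

    def world_to_index_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.origin) @ self.world_to_index.T

    def same_grid(self, other: "Volume3D | BinaryMask | DeformationField",
                  atol: float = 1e-5) -> bool:
        return (
            self.shape == tuple(other.shape)
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.direction, other.direction, atol=atol)
        )

    def with_data(self, data: np.ndarray) -> "Volume3D":
        """New volume on this grid with different intensities."""
        return Volume3D(data, self.spacing.copy(), self.origin.copy(),
                        self.direction.copy())


@dataclass
class BinaryMask:
    """A Boolean volume on the same grid as its parent :class:`Volume3D`."""

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D array, got {data.ndim}D")
        if data.dtype != bool:
            vals = np.unique(data)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("mask values must be strictly in {0, 1}")
        self.data = data.astype(bool)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("all spacing components must be > 0")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.direction = _as_direction(self.direction)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @classmethod
    def on_grid(cls, grid: "Volume3D", data: np.ndarray) -> "BinaryMask":
        return cls(data, grid.spacing.copy(), grid.origin.copy(),
                   grid.direction.copy())

    def to_volume(self) -> Volume3D:
        return Volume3D(self.data.astype(np.float32), self.spacing,
                        self.origin, self.direction)

    def count(self) -> int:
        return int(self.data.sum())


@dataclass
class DeformationField:
    """Per-voxel world displacement (mm) defined on a fixed-volume grid.

    ``displacements`` has shape (3, nx, ny, nz); component c is the
    displacement along world axis c. The field maps a fixed-grid world
    point x to the moving image's world point x + u(x) (pull-back
    convention: the warped image samples the source at x + u(x)).
    """

    displacements: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        u = np.asarray(self.displacements, dtype=np.float64)
        if u.ndim != 4 or u.shape[0] != 3:
            raise ValueError("displacements must have shape (3, nx, ny, nz)")
        if not np.all(np.isfinite(u)):
            raise ValueError("displacement field contains non-finite values")
        self.displacements = u
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.direction = _as_direction(self.direction)

    @property
    def shape(self) -> tuple:
        return self.displacements.shape[1:]

    @classmethod
    def on_grid(cls, grid: Volume3D, displacements: np.ndarray) -> "DeformationField":
        return cls(displacements, grid.spacing.copy(), grid.origin.copy(),
                   grid.direction.copy())

    @classmethod
    def zeros_like(cls, grid: Volume3D) -> "DeformationField":
        return cls.on_grid(grid, np.zeros((3,) + tuple(grid.shape)))

    def max_magnitude(self) -> float:
        return float(np.sqrt((self.displacements ** 2).sum(axis=0)).max())


@dataclass
class LandmarkSet:
    """Paired anatomical landmarks in mm world coordinates.

    Row k of ``points_fixed`` and ``points_moving`` is one corresponding
    pair; pairing is positional.
    """

    points_fixed: np.ndarray
    points_moving: np.ndarray
    labels: Sequence[str] | None = None

    def __post_init__(self):
        self.points_fixed = np.atleast_2d(
            np.asarray(self.points_fixed, dtype=float))
        self.points_moving = np.atleast_2d(
            np.asarray(self.points_moving, dtype=float))
        if self.points_fixed.shape != self.points_moving.shape:
            raise ValueError("fixed and moving point lists differ in shape")
        if self.points_fixed.ndim != 2 or self.points_fixed.shape[1] != 3:
            raise ValueError("points must be N x 3")
        if len(self.points_fixed) < 1:
            raise ValueError("a LandmarkSet needs at least one pair")
        if self.labels is None:
            self.labels = [f"L{k + 1}" for k in range(len(self.points_fixed))]
        self.labels = list(self.labels)
        if len(self.labels) != len(self.points_fixed):
            raise ValueError("labels length does not match point count")

    def __len__(self) -> int:
        return len(self.points_fixed)

    def distances(self) -> np.ndarray:
        """Euclidean fixed-to-moving distance per pair, mm."""
        d = self.points_fixed - self.points_moving
        return np.sqrt((d ** 2).sum(axis=1))
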
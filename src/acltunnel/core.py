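"""Shared containers for tunnel morphometry: planes, volumes, masks, point sets.

All geometry is expressed in world millimetres.  A voxel index ``(i, j, k)``
maps to the world position of its *centre*, ``origin + index * spacing``, so
anisotropic CT grids (typically fine in-plane resolution with a coarse slice
thickness) are handled once, here, and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np


class AclTunnelError(Exception):
    """Base class for errors raised by this package."""


class GeometryError(AclTunnelError):
    """Degenerate or unfit-table geometry (coplanar clouds, sphere-like masks...)."""


class SegmentationError(AclTunnelError):
    """Thresholding or mask-processing failure."""


def unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = float(np.linalg.norm(v))
    if n == 0.0:
        raise GeometryError("zero-length direction vector")
    return v / n


@dataclass(frozen=True)
class Plane:
    """A plane in world mm, used for the joint line.

    By convention the normal points *into the bone*, i.e. positive signed
    distance means deeper inside the bone, negative means joint side.
    """

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        object.__setattr__(self, "normal", unit(self.normal))

    def signed_distance(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return (pts - self.point) @ self.normal


def _check_grid(data: np.ndarray, spacing, origin):
    if data.ndim != 3:
        raise ValueError(f"expected a 3D grid, got ndim={data.ndim}")
    if any(s < 2 for s in data.shape):
        raise ValueError(f"grid too small on some axis: shape={data.shape}")
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    if spacing.shape != (3,) or np.any(spacing <= 0):
        raise ValueError(f"spacing must be 3 strictly positive mm values, got {spacing}")
    if origin.shape != (3,):
        raise ValueError("origin must be a 3-vector (mm)")
    return spacing, origin


@dataclass
class ImageVolume:
    """A 3D scalar grid with anisotropic voxel spacing (mm) and world origin."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.spacing, self.origin = _check_grid(self.data, self.spacing, self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[:3, :3] = np.diag(self.spacing)
        a[:3, 3] = self.origin
        return a

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape ``(*grid, 3)``."""
        idx = np.stack(
            np.meshgrid(*[np.arange(n) for n in self.shape], indexing="ij"), axis=-1
        ).astype(float)
        return self.origin + idx * self.spacing

    def world_to_index(self, pt) -> tuple[int, int, int]:
        idx = np.round((np.asarray(pt, dtype=float) - self.origin) / self.spacing)
        idx = idx.astype(int)
        if np.any(idx < 0) or np.any(idx >= np.asarray(self.shape)):
            raise ValueError(f"point {pt} lies outside the volume grid")
        return tuple(int(i) for i in idx)


@dataclass
class TunnelMask:
    """One tunnel's binary voxel set, aligned to an :class:`ImageVolume` grid."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    side: Optional[str] = None    # femur | tibia
    bundle: Optional[str] = None  # SB | AM | PL

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        self.spacing, self.origin = _check_grid(self.data, self.spacing, self.origin)
        if self.side not in (None, "femur", "tibia"):
            raise ValueError(f"unknown side {self.side!r}")
        if self.bundle not in (None, "SB", "AM", "PL"):
            raise ValueError(f"unknown bundle {self.bundle!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.voxel_volume

    def world_coords(self) -> np.ndarray:
        """World coordinates of the centres of all mask voxels, ``(N, 3)``."""
        idx = np.argwhere(self.data).astype(float)
        return self.origin + idx * self.spacing

    def copy(self) -> "TunnelMask":
        return replace(self, data=self.data.copy())

    def same_grid(self, other: "TunnelMask", atol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


@dataclass
class PointSet:
    """Boundary sample of a tunnel surface in world mm.

    ``normals`` (optional, unit vectors, orientation not guaranteed) let the
    measurement stage separate the drilled lateral wall from aperture/end caps.
    """

    points: np.ndarray
    provenance: str = ""
    normals: Optional[np.ndarray] = None

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (N, 3) array of mm coordinates")
        if self.normals is not None:
            self.normals = np.atleast_2d(np.asarray(self.normals, dtype=float))
            if self.normals.shape != self.points.shape:
                raise ValueError("normals must match points in shape")

    def __len__(self) -> int:
        return self.points.shape[0]

    def select(self, keep: np.ndarray, provenance_suffix: str = "") -> "PointSet":
        return PointSet(
            self.points[keep],
            provenance=self.provenance + provenance_suffix,
            normals=None if self.normals is None else self.normals[keep],
        )


def as_point_array(points) -> np.ndarray:
    if isinstance(points, PointSet):
        return points.points
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 3:
        raise ValueError("expected (N, 3) point coordinates")
    return pts
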
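"""Volume / mask IO, threshold segmentation, surface extraction and point filtering.

The reproducible counterpart of an interactive segmentation workflow: a
threshold grows a connected tunnel region from a seed, the mask boundary is
sampled into a point cloud, tunnel ends are trimmed to the graft region, and
interference-screw protrusions are rejected by a robust residual scheme
instead of a hand-drawn cut line.
"""

from __future__ import annotations

import os
from typing import Optional

import nibabel as nib
import numpy as np
from scipy import ndimage

from .core import (
    ImageVolume,
    Plane,
    PointSet,
    SegmentationError,
    TunnelMask,
    as_point_array,
    unit,
)
from . import geometry

#: Robust screw-filter defaults: MAD multiplier and maximum refit iterations.
K_MAD_DEFAULT = 3.5
MAX_ITER_DEFAULT = 5
#: Abort the screw filter when it would discard more than this fraction.
MAX_REMOVED_FRACTION = 0.4

_CONN26 = np.ones((3, 3, 3), dtype=bool)


# ---------------------------------------------------------------------------
# NIfTI IO


def _affine_to_grid(affine: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    rot = affine[:3, :3]
    spacing = np.linalg.norm(rot, axis=0)
    if np.any(spacing <= 0):
        raise SegmentationError("NIfTI affine has a zero-length axis")
    if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6 * spacing.max()):
        raise SegmentationError("only axis-aligned NIfTI affines are supported")
    return spacing.astype(float), affine[:3, 3].astype(float)


def write_volume(vol: ImageVolume, path: str) -> None:
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), vol.affine)
    nib.save(img, path)


def read_volume(path: str) -> ImageVolume:
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise SegmentationError(f"expected a 3D volume, got ndim={data.ndim} in {path}")
    spacing, origin = _affine_to_grid(img.affine)
    return ImageVolume(np.asarray(data, dtype=float), spacing, origin)


def write_mask(mask: TunnelMask, path: str) -> None:
    """Write a binary tunnel mask as an integer-label NIfTI volume."""
    vol = ImageVolume(mask.data.astype(np.uint8), mask.spacing, mask.origin)
    img = nib.Nifti1Image(mask.data.astype(np.uint8), vol.affine)
    img.header.set_data_dtype(np.uint8)
    nib.save(img, path)


def read_mask(path: str, side: Optional[str] = None, bundle: Optional[str] = None,
              label: int = 1) -> TunnelMask:
    """Read one tunnel mask (``voxels == label``) from an integer NIfTI volume.

    The round trip through :func:`write_mask` reproduces voxels, spacing and
    origin exactly.  Non-integer data or non-3D images are rejected.
    """
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise SegmentationError(f"expected a 3D label volume, got ndim={data.ndim}")
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.round(data)):
            raise SegmentationError(f"{path} does not contain integer labels")
        data = np.round(data).astype(np.int32)
    spacing, origin = _affine_to_grid(img.affine)
    sel = data == label
    if not sel.any():
        raise SegmentationError(f"label {label} not present in {path}")
    return TunnelMask(sel, spacing, origin, side=side, bundle=bundle)


def write_points_csv(points: PointSet, path: str) -> None:
    np.savetxt(path, points.points, delimiter=",", header="x_mm,y_mm,z_mm", comments="")


# ---------------------------------------------------------------------------
# threshold segmentation


def threshold_segment(
    vol: ImageVolume, lo: float, hi: float, seed_point, fill_holes: bool = True,
) -> TunnelMask:
    """Segment the tunnel as the thresholded component containing a seed.

    Selects ``lo <= intensity <= hi``, keeps the 26-connected component that
    contains ``seed_point`` (world mm), and fills holes slice-wise.  A
    component touching the grid boundary is rejected — the seed most likely
    landed outside the tunnel (in bone or air).
    """
    if not lo < hi:
        raise ValueError(f"threshold window requires lo < hi, got [{lo}, {hi}]")
    idx = vol.world_to_index(seed_point)
    sel = (vol.data >= lo) & (vol.data <= hi)
    if not sel.any():
        raise SegmentationError(f"no voxels in threshold window [{lo}, {hi}]")
    if not sel[idx]:
        raise SegmentationError(
            f"seed {tuple(np.round(seed_point, 2))} (intensity "
            f"{vol.data[idx]:.1f}) is outside the window [{lo}, {hi}]"
        )
    labels, _ = ndimage.label(sel, structure=_CONN26)
    comp = labels == labels[idx]
    if fill_holes:
        for k in range(comp.shape[2]):
            comp[:, :, k] = ndimage.binary_fill_holes(comp[:, :, k])
    border = np.zeros_like(comp)
    border[[0, -1], :, :] = True
    border[:, [0, -1], :] = True
    border[:, :, [0, -1]] = True
    if (comp & border).any():
        raise SegmentationError(
            "segmented component touches the grid boundary; the seed is "
            "probably not inside a tunnel"
        )
    return TunnelMask(comp, vol.spacing, vol.origin)


def dice(mask_a: TunnelMask, mask_b: TunnelMask) -> float:
    """Dice overlap between two masks on the same grid."""
    if not mask_a.same_grid(mask_b):
        raise ValueError("masks must share a grid")
    a, b = mask_a.data, mask_b.data
    denom = a.sum() + b.sum()
    return float(2.0 * (a & b).sum() / denom) if denom else 1.0


# ---------------------------------------------------------------------------
# surface extraction


def mask_to_points(mask: TunnelMask, method: str = "isosurface") -> PointSet:
    """Sample the mask boundary into a world-mm point set.

    ``voxel_faces``: centres of voxel faces exposed to the background, with
    axis-aligned face normals.  ``isosurface``: vertices of a marching-cubes
    surface at the 0.5 level (sub-voxel positions between inside and outside
    voxel centres), with gradient normals.
    """
    if mask.n_voxels == 0:
        raise SegmentationError("empty mask has no surface")
    if mask.n_voxels < 2:
        raise SegmentationError("single-voxel mask has no fittable surface")
    if method == "voxel_faces":
        pts, nrm = [], []
        m = mask.data
        for axis in range(3):
            for sign in (+1, -1):
                shifted = np.roll(m, -sign, axis=axis)
                # voxels rolled in from the edge are background
                edge = [slice(None)] * 3
                edge[axis] = -1 if sign > 0 else 0
                shifted[tuple(edge)] = False
                exposed = m & ~shifted
                idx = np.argwhere(exposed).astype(float)
                if idx.size == 0:
                    continue
                centers = mask.origin + idx * mask.spacing
                offset = np.zeros(3)
                offset[axis] = sign * mask.spacing[axis] / 2.0
                pts.append(centers + offset)
                n = np.zeros(3)
                n[axis] = float(sign)
                nrm.append(np.tile(n, (idx.shape[0], 1)))
        return PointSet(np.vstack(pts), provenance="voxel_faces", normals=np.vstack(nrm))
    if method == "isosurface":
        from skimage.measure import marching_cubes

        padded = np.pad(mask.data, 1).astype(np.float32)
        verts, faces, normals, _ = marching_cubes(
            padded, level=0.5, spacing=tuple(mask.spacing)
        )
        verts = verts - mask.spacing + mask.origin
        norms = np.linalg.norm(normals, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return PointSet(verts, provenance="isosurface", normals=normals / norms)
    raise ValueError(f"unknown surface method {method!r}")


# ---------------------------------------------------------------------------
# trimming and screw filtering


def trim_tunnel(
    points: PointSet,
    axis_hint,
    keep_range: tuple[float, float],
    joint_plane: Plane,
    min_points: int = 50,
) -> PointSet:
    """Keep points whose axial coordinate lies in ``[a, b]``.

    The axial coordinate is 0 where the line through the cloud centroid along
    ``axis_hint`` crosses the joint plane, increasing into the bone.  Used to
    isolate the graft region and discard the suspension-device track.
    """
    a, b = keep_range
    if not a < b:
        raise ValueError(f"keep_range must satisfy a < b, got [{a}, {b}]")
    d = unit(axis_hint)
    if d @ joint_plane.normal < 0:
        d = -d
    pts = points.points
    centroid = pts.mean(axis=0)
    denom = d @ joint_plane.normal
    if abs(denom) < 1e-6:
        raise ValueError("axis_hint is parallel to the joint plane")
    t = ((joint_plane.point - centroid) @ joint_plane.normal) / denom
    origin = centroid + t * d
    s = (pts - origin) @ d
    keep = (s >= a) & (s <= b)
    if keep.sum() < min_points:
        raise SegmentationError(
            f"only {int(keep.sum())} points survive trimming to [{a}, {b}] mm "
            f"(need >= {min_points})"
        )
    return points.select(keep, provenance_suffix="+trim")


def filter_screw_outliers(
    points: PointSet,
    max_iter: int = MAX_ITER_DEFAULT,
    k_mad: float = K_MAD_DEFAULT,
    joint_plane: Optional[Plane] = None,
) -> tuple[PointSet, int]:
    """Iteratively reject screw-tip protrusions by robust radial residuals.

    Repeats: fit a cylinder, compute radial residuals, drop points whose
    residual exceeds ``median + k_mad * MAD``, refit — until convergence or
    ``max_iter``.  Only outward outliers are dropped, matching the physical
    artifact (a screw tip bulging off the tunnel wall).  Returns the filtered
    set and the number of points removed; aborts if more than 40 % of points
    would be discarded (the mask is probably not a tunnel).
    """
    if not np.isfinite(k_mad):
        return points, 0
    current = points
    n0 = len(points)
    removed = 0
    for _ in range(max_iter):
        cyl = geometry.fit_cylinder(current, joint_plane=joint_plane)
        res = cyl.radial_distances(current) - cyl.radius
        med = float(np.median(res))
        mad = float(np.median(np.abs(res - med)))
        if mad == 0.0:
            break
        keep = res <= med + k_mad * mad
        n_drop = int((~keep).sum())
        if n_drop == 0:
            break
        removed += n_drop
        if removed > MAX_REMOVED_FRACTION * n0:
            raise SegmentationError(
                f"screw filter would remove {removed}/{n0} points "
                f"(> {MAX_REMOVED_FRACTION:.0%}); mask is likely not a tunnel"
            )
        current = current.select(keep, provenance_suffix="")
    if removed:
        current = PointSet(
            current.points, provenance=points.provenance + "+screwfilter",
            normals=current.normals,
        )
    return current, removed
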
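"""Best-fit cylinder / circle measurement of bone tunnels, and tunnel communication.

This is the measurement core of the package.  A segmented tunnel is summarised
by three primitives, mirroring the semi-automated 3D-CT workflow used to
quantify tunnel widening after ACL reconstruction:

* a least-squares **cylinder** fitted to the whole (trimmed, screw-filtered)
  tunnel surface — its diameter is the length-averaged tunnel size and its
  axis defines the measurement direction;
* a least-squares **circle** in the plane perpendicular to that axis at the
  tunnel *aperture* (where the axis crosses the joint-line plane); and
* a second circle **10.0 mm** deeper along the axis.

Cross-sections are taken perpendicular to the fitted cylinder axis, not
parallel to the anatomical joint surface; the 10.0 mm offset is measured along
the axis.  This keeps the aperture and 10-mm measures directly comparable.

Communication between two tunnels of a double-bundle reconstruction is
declared when no cortical bone separates the two masks at the level of the
joint line; the ridge distance is the depth at which a separating bridge
first (and persistently) appears.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

from .core import (
    GeometryError,
    Plane,
    PointSet,
    TunnelMask,
    as_point_array,
    unit,
)

#: Default axial half-width (mm) of the point slab used for circle fits.
DEFAULT_SLAB_HALFWIDTH = 1.0
#: Depth (mm) of the second cross-sectional measurement below the aperture.
CIRCLE_DEPTH_MM = 10.0
#: |cos| threshold between a point normal and the tunnel axis above which a
#: boundary point is treated as belonging to an end cap, not the drilled wall.
CAP_NORMAL_COS = 0.7
#: Sanity window (mm) for any measured tunnel diameter.
DIAMETER_SANITY_MM = (2.0, 20.0)


def _orthonormal_complement(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = unit(d)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(d[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = unit(np.cross(d, helper))
    e2 = np.cross(d, e1)
    return e1, e2


@dataclass(frozen=True)
class CylinderFit:
    """A least-squares cylinder: point on axis, unit direction, radius.

    ``axis_point`` is the axial origin used for axial coordinates; after
    :func:`measure_tunnel` it is rebased to the joint-plane intersection so
    that axial coordinate 0 is the aperture.
    """

    axis_point: np.ndarray
    axis_dir: np.ndarray
    radius: float
    length: float
    rms_residual: float
    n_points: int

    def __post_init__(self):
        object.__setattr__(self, "axis_point", np.asarray(self.axis_point, dtype=float))
        object.__setattr__(self, "axis_dir", unit(self.axis_dir))
        if self.radius <= 0:
            raise GeometryError(f"non-positive cylinder radius {self.radius}")

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius

    @property
    def csa(self) -> float:
        """Cross-sectional area, pi * r^2 (mm^2)."""
        return float(np.pi * self.radius**2)

    def axial_coordinates(self, points) -> np.ndarray:
        pts = as_point_array(points)
        return (pts - self.axis_point) @ self.axis_dir

    def radial_distances(self, points) -> np.ndarray:
        pts = as_point_array(points)
        w = pts - self.axis_point
        s = w @ self.axis_dir
        return np.linalg.norm(w - s[:, None] * self.axis_dir, axis=1)

    def rebased(self, axis_point: np.ndarray) -> "CylinderFit":
        """Return the same cylinder with a new axial origin on the axis."""
        p = np.asarray(axis_point, dtype=float)
        # project onto the axis so the origin really lies on it
        s = (p - self.axis_point) @ self.axis_dir
        return replace(self, axis_point=self.axis_point + s * self.axis_dir)


@dataclass(frozen=True)
class CircleFit:
    """A least-squares circle in a plane perpendicular to the tunnel axis."""

    center: np.ndarray
    plane_normal: np.ndarray
    radius: float
    slab_halfwidth: float
    n_points: int
    rms_residual: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        object.__setattr__(self, "plane_normal", unit(self.plane_normal))
        if self.radius <= 0:
            raise GeometryError(f"non-positive circle radius {self.radius}")
        if self.n_points < 8:
            raise GeometryError(f"circle fit needs >= 8 points, got {self.n_points}")

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius

    @property
    def csa(self) -> float:
        return float(np.pi * self.radius**2)


@dataclass(frozen=True)
class TunnelMeasurement:
    """The six numbers reported per tunnel per timepoint.

    Diameter and cross-sectional area of the best-fit cylinder, of the
    aperture circle, and of the circle 10.0 mm from the joint line.
    """

    cylinder: CylinderFit
    aperture: CircleFit
    at10mm: CircleFit
    side: Optional[str] = None
    bundle: Optional[str] = None
    timepoint: Optional[str] = None

    def __post_init__(self):
        lo, hi = DIAMETER_SANITY_MM
        for name in ("cylinder", "aperture", "at10mm"):
            d = getattr(self, name).diameter
            if not (lo <= d <= hi):
                raise GeometryError(
                    f"{name} diameter {d:.2f} mm outside sanity window [{lo}, {hi}] mm"
                )

    def as_dict(self) -> dict:
        return {
            "side": self.side,
            "bundle": self.bundle,
            "timepoint": self.timepoint,
            "cylinder_diameter_mm": self.cylinder.diameter,
            "cylinder_csa_mm2": self.cylinder.csa,
            "aperture_diameter_mm": self.aperture.diameter,
            "aperture_csa_mm2": self.aperture.csa,
            "at10mm_diameter_mm": self.at10mm.diameter,
            "at10mm_csa_mm2": self.at10mm.csa,
            "cylinder_rms_mm": self.cylinder.rms_residual,
            "cylinder_length_mm": self.cylinder.length,
        }


@dataclass(frozen=True)
class CommunicationResult:
    """Outcome of the converging-tunnel check.

    ``communicating`` means the two tunnels share their opening at the joint
    line (no cortical ridge at depth 0); ``ridge_distance`` is the depth in mm
    from the joint line at which separating bone first persistently appears
    (``None`` when not communicating, ``nan`` when no ridge is found within
    ``max_depth``).  ``gap_profile`` lists (depth-bin centre, minimum bone gap)
    pairs; a gap of 0 means the masks are in contact in that bin.
    """

    communicating: bool
    ridge_distance: Optional[float]
    gap_profile: tuple


# ---------------------------------------------------------------------------
# cylinder fit


def _principal_axis(pts: np.ndarray) -> np.ndarray:
    c = pts.mean(axis=0)
    u, s, vt = np.linalg.svd(pts - c, full_matrices=False)
    if s[0] <= 0 or s[-1] / s[0] < 1e-12:
        raise GeometryError("degenerate (coplanar or collinear) point cloud")
    return vt[0]


def fit_cylinder(
    points,
    joint_plane: Optional[Plane] = None,
    min_points: int = 50,
    xtol: float = 1e-12,
    max_nfev: int = 2000,
    degenerate_rms_fraction: float = 0.25,
) -> CylinderFit:
    """Least-squares cylinder fit to a tunnel-boundary point cloud.

    Minimises ``sum((dist(p_i, axis) - r)^2)``.  The axis is initialised from
    the principal direction of the cloud and refined together with the radius
    by nonlinear least squares.  When ``joint_plane`` is given the axis
    direction is canonicalised to point away from the joint into the bone.

    Raises :class:`GeometryError` for too few / coplanar points, for
    non-convergence, and for sphere-like clouds whose residual exceeds a
    quarter of the fitted radius (clean tunnel surfaces stay below a tenth).
    """
    pts = as_point_array(points)
    if pts.shape[0] < min_points:
        raise GeometryError(
            f"cylinder fit needs >= {min_points} points, got {pts.shape[0]}"
        )
    centroid = pts.mean(axis=0)
    d0 = _principal_axis(pts)
    e1, e2 = _orthonormal_complement(d0)
    w0 = pts - centroid
    r0 = float(np.mean(np.linalg.norm(w0 - (w0 @ d0)[:, None] * d0, axis=1)))
    if r0 <= 0:
        raise GeometryError("collinear point cloud")

    def residuals(p):
        u, v, a, b, r = p
        d = d0 + a * e1 + b * e2
        d = d / np.linalg.norm(d)
        q = centroid + u * e1 + v * e2
        w = pts - q
        s = w @ d
        rad = np.linalg.norm(w - s[:, None] * d, axis=1)
        return rad - r

    sol = least_squares(
        residuals,
        x0=np.array([0.0, 0.0, 0.0, 0.0, r0]),
        method="lm",
        xtol=xtol,
        ftol=xtol,
        gtol=xtol,
        max_nfev=max_nfev,
    )
    if not sol.success:
        raise GeometryError(
            f"cylinder fit did not converge (status {sol.status}): {sol.message}; "
            f"final rms {float(np.sqrt(np.mean(sol.fun**2))):.4g} mm"
        )
    u, v, a, b, r = sol.x
    if r <= 0:
        raise GeometryError(f"cylinder fit collapsed to non-positive radius {r}")
    d = unit(d0 + a * e1 + b * e2)
    q = centroid + u * e1 + v * e2

    # canonical direction: away from the joint plane (into bone), otherwise a
    # deterministic sign convention on the dominant component
    if joint_plane is not None:
        if d @ joint_plane.normal < 0:
            d = -d
    elif d[np.argmax(np.abs(d))] < 0:
        d = -d

    s = (pts - q) @ d
    length = float(s.max() - s.min())
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    fit = CylinderFit(
        axis_point=q, axis_dir=d, radius=float(r), length=length,
        rms_residual=rms, n_points=pts.shape[0],
    )
    if rms > degenerate_rms_fraction * fit.radius:
        raise GeometryError(
            f"cloud is not cylinder-like: rms residual {rms:.3g} mm exceeds "
            f"{degenerate_rms_fraction:.0%} of fitted radius {fit.radius:.3g} mm"
        )
    return fit


def known_axis_radius(points, axis_point, axis_dir) -> float:
    """Closed-form radius estimate when the axis is known: mean radial distance.

    This is the independent oracle for :func:`fit_cylinder` on exact data.
    """
    pts = as_point_array(points)
    d = unit(axis_dir)
    w = pts - np.asarray(axis_point, dtype=float)
    s = w @ d
    return float(np.mean(np.linalg.norm(w - s[:, None] * d, axis=1)))


# ---------------------------------------------------------------------------
# circle fit


def _kasa_circle(u: np.ndarray, v: np.ndarray) -> tuple[float, float, float]:
    # algebraic (Kasa) fit: || [2u 2v 1] [a b c]^T - (u^2+v^2) || minimised
    A = np.column_stack([2 * u, 2 * v, np.ones_like(u)])
    y = u**2 + v**2
    (a, b, c), *_ = np.linalg.lstsq(A, y, rcond=None)
    r2 = c + a**2 + b**2
    if r2 <= 0:
        raise GeometryError("algebraic circle fit collapsed (degenerate slab)")
    return float(a), float(b), float(np.sqrt(r2))


def fit_circle_at(
    points,
    cyl: CylinderFit,
    axial_position: float,
    slab_halfwidth: float = DEFAULT_SLAB_HALFWIDTH,
) -> CircleFit:
    """Best-fit circle to the tunnel wall in a thin slab along the axis.

    Points with axial coordinate within ``axial_position +/- slab_halfwidth``
    (relative to ``cyl.axis_point``) are projected onto the plane through
    ``axial_position`` perpendicular to the cylinder axis and fitted with an
    algebraic (Kasa) circle refined by geometric Gauss-Newton.
    """
    pts = as_point_array(points)
    s = cyl.axial_coordinates(pts)
    sel = np.abs(s - axial_position) <= slab_halfwidth
    n = int(sel.sum())
    if n < 8:
        raise GeometryError(
            f"only {n} points in slab {axial_position:+.1f} +/- {slab_halfwidth:.1f} mm "
            f"(need >= 8)"
        )
    e1, e2 = _orthonormal_complement(cyl.axis_dir)
    plane_origin = cyl.axis_point + axial_position * cyl.axis_dir
    w = pts[sel] - plane_origin
    u, v = w @ e1, w @ e2
    a, b, r = _kasa_circle(u, v)

    def residuals(p):
        return np.hypot(u - p[0], v - p[1]) - p[2]

    sol = least_squares(residuals, x0=np.array([a, b, r]), method="lm", xtol=1e-12)
    a, b, r = sol.x
    if r <= 0:
        raise GeometryError("geometric circle refinement collapsed")
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    return CircleFit(
        center=plane_origin + a * e1 + b * e2,
        plane_normal=cyl.axis_dir,
        radius=float(r),
        slab_halfwidth=slab_halfwidth,
        n_points=n,
        rms_residual=rms,
    )


# ---------------------------------------------------------------------------
# full tunnel measurement


def drop_cap_points(points: PointSet, axis_dir, cos_threshold: float = CAP_NORMAL_COS) -> PointSet:
    """Remove end-cap boundary points using their surface normals.

    Points whose normal is closer than ``acos(cos_threshold)`` to the tunnel
    axis belong to the flat aperture/end caps of a binary mask, not to the
    drilled wall, and would bias radius estimates low.  No-op when the point
    set carries no normals.
    """
    if points.normals is None:
        return points
    d = unit(axis_dir)
    keep = np.abs(points.normals @ d) < cos_threshold
    if keep.sum() < 8:
        return points
    return points.select(keep, provenance_suffix="+capfilter")


def measure_tunnel(
    points: PointSet,
    joint_plane: Plane,
    slab_halfwidth: float = DEFAULT_SLAB_HALFWIDTH,
    circle_depth: float = CIRCLE_DEPTH_MM,
    cap_normal_cos: float = CAP_NORMAL_COS,
    side: Optional[str] = None,
    bundle: Optional[str] = None,
    timepoint: Optional[str] = None,
) -> TunnelMeasurement:
    """Run the full measurement pipeline on a trimmed, filtered point set.

    Fits the cylinder, rebases its axial origin to the joint-plane
    intersection (axial coordinate 0 = aperture), then fits circles at 0 and
    ``circle_depth`` mm.  End-cap points are removed via surface normals when
    available.
    """
    if not isinstance(points, PointSet):
        points = PointSet(as_point_array(points))
    prelim_axis = _principal_axis(points.points)
    wall = drop_cap_points(points, prelim_axis, cap_normal_cos)
    cyl = fit_cylinder(wall, joint_plane=joint_plane)

    denom = cyl.axis_dir @ joint_plane.normal
    if abs(denom) < 1e-6:
        raise GeometryError("tunnel axis is parallel to the joint plane")
    t = ((joint_plane.point - cyl.axis_point) @ joint_plane.normal) / denom
    aperture_origin = cyl.axis_point + t * cyl.axis_dir
    cyl = cyl.rebased(aperture_origin)

    aperture = fit_circle_at(wall, cyl, 0.0, slab_halfwidth)
    at10 = fit_circle_at(wall, cyl, circle_depth, slab_halfwidth)
    return TunnelMeasurement(
        cylinder=cyl, aperture=aperture, at10mm=at10,
        side=side, bundle=bundle, timepoint=timepoint,
    )


# ---------------------------------------------------------------------------
# tunnel communication


def _surface_voxels(mask: TunnelMask) -> np.ndarray:
    from scipy import ndimage

    eroded = ndimage.binary_erosion(mask.data, structure=np.ones((3, 3, 3)))
    surf = mask.data & ~eroded
    idx = np.argwhere(surf).astype(float)
    return mask.origin + idx * mask.spacing


def detect_communication(
    mask_a: TunnelMask,
    mask_b: TunnelMask,
    joint_plane: Plane,
    max_depth: float = 20.0,
    depth_bin: Optional[float] = None,
) -> CommunicationResult:
    """Detect a missing cortical ridge between two converging tunnels.

    The depth axis is the joint-plane normal, binned at the slice thickness
    (or ``depth_bin``).  In each bin the minimum distance between the two
    tunnels' surface voxel centres, minus one in-plane voxel diagonal (the
    centre-to-centre distance of adjacent voxels across a vanishing bone
    wall), is the bone gap; a gap <= 0 counts as contact.  The tunnels
    communicate when they are in contact in the bin at the joint line; the
    ridge distance is the lower edge of the first bin after which the gap
    stays positive.
    """
    if not mask_a.same_grid(mask_b):
        raise ValueError("masks must live on the same voxel grid")
    pa, pb = _surface_voxels(mask_a), _surface_voxels(mask_b)
    if pa.size == 0 or pb.size == 0:
        raise ValueError("empty tunnel mask")
    da, db = joint_plane.signed_distance(pa), joint_plane.signed_distance(pb)
    if np.median(da) * np.median(db) < 0:
        raise ValueError("masks lie on opposite sides of the joint plane")

    if depth_bin is None:
        # slice thickness along the depth axis: dominant-axis voxel extent
        depth_bin = float(np.max(np.abs(joint_plane.normal) * mask_a.spacing))
        depth_bin = max(depth_bin, float(np.min(mask_a.spacing)))
    # contact scale: diagonal of the voxel footprint transverse to the depth
    # axis — surface voxels closer than this have no bone voxel between them
    transverse = (1.0 - np.abs(joint_plane.normal)) * mask_a.spacing
    diag = float(max(np.linalg.norm(transverse), np.min(mask_a.spacing)))
    n_bins = int(np.ceil(max_depth / depth_bin))

    # distance from every A-surface voxel to the nearest B-surface voxel
    dist = cKDTree(pb).query(pa, k=1)[0]
    in_range = da <= max_depth
    contact = (dist <= diag) & in_range

    profile = []
    gaps = np.full(n_bins, np.inf)
    for k in range(n_bins):
        lo, hi = k * depth_bin, (k + 1) * depth_bin
        ia = (da >= lo) & (da < hi)
        if ia.any():
            gaps[k] = max(float(dist[ia].min()) - diag, 0.0)
        profile.append((lo + depth_bin / 2.0, float(gaps[k])))

    communicating = bool(np.isfinite(gaps[0]) and gaps[0] <= 0.0)
    ridge: Optional[float] = None
    if communicating:
        # smallest depth beyond which the masks are never again in contact:
        # the depth of the deepest voxel-level contact (quantised to slices)
        ridge = float(da[contact].max()) if contact.any() else float("nan")
    return CommunicationResult(
        communicating=communicating,
        ridge_distance=ridge,
        gap_profile=tuple(profile),
    )
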
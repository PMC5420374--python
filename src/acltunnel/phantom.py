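"""Ground-truthed CT-like knee phantoms for tunnel-widening analysis.

Real post-operative CT scans of ACL-reconstructed knees are not publicly
available, so every analysis stage in this package is exercised on synthetic
phantoms with analytically known truth: a solid bone block on an anisotropic
voxel grid (fine in-plane, 1.5 mm slice thickness, mirroring a 16-row scanner
protocol at desk scale), with near-cylindrical drilled tunnels entering at a
joint-line plane.  The generator covers the phenomena the measurement layer
must be robust to: widening between timepoints (uniform, or stronger at the
aperture as expected from the windshield-wiper effect), interference-screw
tips protruding from the tibial tunnel wall, stochastic rater segmentation
noise, and pairs of converging double-bundle tunnels with or without a
separating cortical ridge.

Cohort-level defaults reproduce the published study conditions: 22 subjects
with single-bundle (SB) and 20 with double-bundle (DB) reconstructions, with
per-tunnel Year-0 diameters and 1-year widening drawn from the reported
means and SDs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .core import (
    AclTunnelError,
    ImageVolume,
    Plane,
    TunnelMask,
    unit,
)

#: Depth (mm) over which aperture-weighted widening decays, and the fraction
#: of the aperture widening that remains at / beyond that depth.
APERTURE_DECAY_DEPTH_MM = 10.0
APERTURE_FAR_FRACTION = 0.5

#: Physical floors used when drawing cohorts: drilled diameters below 4 mm or
#: widening below -0.5 mm are rejected and redrawn (drill sizes are >= 5 mm
#: by the graft-size inclusion criteria, so the diameter floor is essentially
#: never hit).
MIN_DIAMETER_MM = 4.0
MIN_WIDENING_MM = -0.5

#: Minimal drilled graft-bundle diameters (mm): PL 5.0, AM 6.0.
MIN_DRILL_DIAMETER = {"PL": 5.0, "AM": 6.0, "SB": 5.0}


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity model of one phantom bone block.

    Defaults use a 96 x 96 x 40 grid at (0.4, 0.4, 1.5) mm — the published
    slice thickness and in-plane/slice anisotropy at desk scale; a full
    512 x 512 grid is available by overriding ``grid_shape``/``spacing``.
    Intensities are HU-like: solid bone everywhere except inside tunnels.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 40)
    spacing: tuple[float, float, float] = (0.4, 0.4, 1.5)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    joint_plane: Plane = field(
        default_factory=lambda: Plane(point=(19.2, 19.2, 9.0), normal=(0.0, 0.0, 1.0))
    )
    bone_intensity: float = 700.0
    background_intensity: float = 0.0
    noise_sd: float = 20.0

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive on all axes")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def volume_extent(self) -> np.ndarray:
        """World coordinates of the last voxel centre."""
        return np.asarray(self.origin) + (np.asarray(self.grid_shape) - 1) * np.asarray(
            self.spacing
        )

    def empty_volume_coords(self) -> np.ndarray:
        idx = np.stack(
            np.meshgrid(*[np.arange(n) for n in self.grid_shape], indexing="ij"),
            axis=-1,
        ).astype(float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)


@dataclass(frozen=True)
class RadiusProfile:
    """Radius (mm) as a function of axial depth s (mm) below the aperture.

    Year-0 drilled tunnels are constant-radius; widening adds either a
    uniform diameter increment or an aperture-weighted one that decays
    linearly from the full increment at s = 0 to ``far_fraction`` of it at
    ``decay_depth`` and beyond.
    """

    base_radius: float
    delta_diameter: float = 0.0
    mode: str = "uniform"  # uniform | aperture_weighted
    decay_depth: float = APERTURE_DECAY_DEPTH_MM
    far_fraction: float = APERTURE_FAR_FRACTION

    def __post_init__(self):
        if self.base_radius <= 0:
            raise ValueError("base radius must be positive")
        if self.mode not in ("uniform", "aperture_weighted"):
            raise ValueError(f"unknown widening mode {self.mode!r}")

    def radius(self, s):
        s = np.asarray(s, dtype=float)
        if self.mode == "uniform" or self.delta_diameter == 0.0:
            return np.broadcast_to(
                self.base_radius + self.delta_diameter / 2.0, s.shape
            ).copy()
        frac = np.clip(s / self.decay_depth, 0.0, 1.0)
        dia_add = self.delta_diameter * (1.0 - (1.0 - self.far_fraction) * frac)
        return self.base_radius + dia_add / 2.0

    def diameter(self, s):
        return 2.0 * self.radius(s)

    def min_radius(self, length: float) -> float:
        return float(np.min(self.radius(np.linspace(0.0, length, 201))))

    def mean_diameter(self, length: float) -> float:
        """Length-averaged diameter over [0, length] (exact for this profile)."""
        if self.mode == "uniform" or self.delta_diameter == 0.0:
            return 2.0 * self.base_radius + self.delta_diameter
        d, dd, ff = self.delta_diameter, self.decay_depth, self.far_fraction
        if length <= dd:
            mean_add = d * (1.0 - (1.0 - ff) * length / (2.0 * dd))
        else:
            near = d * (1.0 - (1.0 - ff) / 2.0) * dd
            far = d * ff * (length - dd)
            mean_add = (near + far) / length
        return 2.0 * self.base_radius + mean_add


@dataclass(frozen=True)
class TunnelSpec:
    """One drilled tunnel: entry on the joint plane, axis into the bone."""

    entry_point: np.ndarray
    axis_direction: np.ndarray
    length: float
    profile: RadiusProfile
    side: str = "femur"
    bundle: str = "SB"

    def __post_init__(self):
        object.__setattr__(self, "entry_point", np.asarray(self.entry_point, float))
        object.__setattr__(self, "axis_direction", unit(self.axis_direction))
        if self.length <= 0:
            raise ValueError("tunnel length must be positive")
        if self.profile.min_radius(self.length) <= 0:
            raise ValueError("radius profile reaches zero inside the tunnel")
        if self.side not in ("femur", "tibia"):
            raise ValueError(f"unknown side {self.side!r}")
        if self.bundle not in ("SB", "AM", "PL"):
            raise ValueError(f"unknown bundle {self.bundle!r}")

    @classmethod
    def drilled(
        cls, entry_point, axis_direction, diameter_mm: float, length: float,
        side: str = "femur", bundle: str = "SB", enforce_min_drill: bool = False,
    ) -> "TunnelSpec":
        if enforce_min_drill and diameter_mm < MIN_DRILL_DIAMETER[bundle]:
            raise ValueError(
                f"{bundle} drill diameter {diameter_mm} mm below the "
                f"{MIN_DRILL_DIAMETER[bundle]} mm graft minimum"
            )
        return cls(
            entry_point, axis_direction, length,
            RadiusProfile(base_radius=diameter_mm / 2.0),
            side=side, bundle=bundle,
        )

    def truth(self, timepoint: str = "year0") -> "TunnelTruth":
        return TunnelTruth(
            side=self.side,
            bundle=self.bundle,
            timepoint=timepoint,
            diameter_aperture=float(self.profile.diameter(0.0)),
            diameter_at10mm=float(
                self.profile.diameter(min(APERTURE_DECAY_DEPTH_MM, self.length))
            ),
            diameter_mean=self.profile.mean_diameter(self.length),
            entry_point=tuple(self.entry_point),
            axis_direction=tuple(self.axis_direction),
            length=self.length,
        )


def widen_tunnel(t: TunnelSpec, delta_mm: float, profile: str = "uniform") -> TunnelSpec:
    """Year-1 version of a drilled tunnel after ``delta_mm`` diameter widening.

    ``uniform`` widens the whole tunnel equally; ``aperture_weighted`` applies
    the full increment at the aperture, decaying to half of it at 10 mm and
    beyond — the pattern expected when widening concentrates at the joint.
    ``delta_mm`` may be mildly negative but must not close the tunnel.
    """
    if t.profile.delta_diameter != 0.0:
        raise ValueError("widen_tunnel expects an unwidened (Year-0) tunnel")
    if delta_mm == 0.0:
        return t
    new_profile = replace(t.profile, delta_diameter=float(delta_mm), mode=profile)
    if new_profile.min_radius(t.length) <= 0:
        raise ValueError(
            f"widening {delta_mm} mm would close the tunnel "
            f"(base diameter {t.profile.diameter(0.0):.2f} mm)"
        )
    return replace(t, profile=new_profile)


# ---------------------------------------------------------------------------
# ground truth


@dataclass(frozen=True)
class TunnelTruth:
    side: str
    bundle: str
    timepoint: str
    diameter_aperture: float
    diameter_at10mm: float
    diameter_mean: float
    entry_point: tuple
    axis_direction: tuple
    length: float

    def as_dict(self) -> dict:
        return {
            "side": self.side, "bundle": self.bundle, "timepoint": self.timepoint,
            "diameter_aperture_mm": self.diameter_aperture,
            "diameter_at10mm_mm": self.diameter_at10mm,
            "diameter_mean_mm": self.diameter_mean,
            "entry_point_mm": list(self.entry_point),
            "axis_direction": list(self.axis_direction),
            "length_mm": self.length,
        }


@dataclass
class GroundTruth:
    """Analytic truth for a phantom: per-tunnel diameters and pair topology."""

    tunnels: list
    ridge_distance_mm: Optional[float] = None
    communicating: Optional[bool] = None

    def tunnel(self, side: str, bundle: str, timepoint: str) -> TunnelTruth:
        for t in self.tunnels:
            if (t.side, t.bundle, t.timepoint) == (side, bundle, timepoint):
                return t
        raise KeyError((side, bundle, timepoint))

    def widening(self, side: str, bundle: str, level: str = "mean") -> tuple[float, float]:
        """(delta mm, delta %) between year0 and year1 at a measurement level."""
        attr = {
            "mean": "diameter_mean", "cylinder": "diameter_mean",
            "aperture": "diameter_aperture", "10mm": "diameter_at10mm",
        }[level]
        d0 = getattr(self.tunnel(side, bundle, "year0"), attr)
        d1 = getattr(self.tunnel(side, bundle, "year1"), attr)
        delta = d1 - d0
        return delta, 100.0 * delta / d0

    def as_dict(self) -> dict:
        return {
            "tunnels": [t.as_dict() for t in self.tunnels],
            "ridge_distance_mm": self.ridge_distance_mm,
            "communicating": self.communicating,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# voxelization


def _voxelize(coords: np.ndarray, t: TunnelSpec, joint_plane: Plane) -> np.ndarray:
    """Boolean grid of voxel centres inside the tunnel and on the bone side.

    The drilled void is the (profile-radius) cylinder around the axis, cut by
    the joint plane at the top and by the drilled depth at the bottom; for an
    oblique axis the aperture is therefore a complete ellipse in the joint
    plane, as a real drill leaves it.
    """
    flat = coords.reshape(-1, 3)
    w = flat - t.entry_point
    s = w @ t.axis_direction
    radial2 = np.einsum("ij,ij->i", w, w) - s**2
    r = t.profile.radius(np.clip(s, 0.0, t.length))
    depth = (flat - joint_plane.point) @ joint_plane.normal
    inside = (s <= t.length) & (radial2 <= r**2) & (depth >= 0.0)
    return inside.reshape(coords.shape[:3])


def _check_tunnel_fits(spec: PhantomSpec, t: TunnelSpec) -> None:
    lo = np.asarray(spec.origin, float)
    hi = spec.volume_extent()
    ss = np.linspace(0.0, t.length, 41)
    centers = t.entry_point + ss[:, None] * t.axis_direction
    radii = t.profile.radius(ss)
    if np.any(centers - radii[:, None] < lo) or np.any(centers + radii[:, None] > hi):
        raise ValueError(
            f"tunnel ({t.side} {t.bundle}) exits the phantom grid; enlarge the "
            f"grid or shorten/reposition the tunnel"
        )
    if abs(t.axis_direction @ spec.joint_plane.normal) < 0.17:  # > ~80 deg tilt
        raise ValueError("tunnel axis is (nearly) parallel to the joint plane")


def generate_phantom(
    spec: PhantomSpec,
    tunnels: list,
    seed: int,
    timepoint: str = "year0",
    expect_overlap: bool = False,
) -> tuple[ImageVolume, list, GroundTruth]:
    """Voxelize tunnels into a bone block and return volume, masks and truth.

    A voxel belongs to a tunnel when its centre lies within the radius profile
    of the tunnel axis, within the drilled span, and on the bone side of the
    joint plane.  Intensities are ``background`` inside tunnels and ``bone``
    elsewhere, plus seeded Gaussian noise; the noise never affects the
    geometry, so masks and ground truth are bit-identical across seeds.
    """
    for t in tunnels:
        _check_tunnel_fits(spec, t)
    coords = spec.empty_volume_coords()
    masks = []
    for t in tunnels:
        m = _voxelize(coords, t, spec.joint_plane)
        masks.append(TunnelMask(m, spec.spacing, spec.origin, side=t.side, bundle=t.bundle))
    if not expect_overlap:
        for i in range(len(masks)):
            for j in range(i + 1, len(masks)):
                if (masks[i].data & masks[j].data).any():
                    warnings.warn(
                        f"tunnels {i} and {j} overlap but were not generated as a "
                        f"communicating pair", stacklevel=2,
                    )
    any_tunnel = np.zeros(spec.grid_shape, dtype=bool)
    for m in masks:
        any_tunnel |= m.data
    data = np.where(any_tunnel, spec.background_intensity, spec.bone_intensity).astype(float)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)
    vol = ImageVolume(data, spec.spacing, spec.origin)
    truth = GroundTruth(tunnels=[t.truth(timepoint) for t in tunnels])
    return vol, masks, truth


# ---------------------------------------------------------------------------
# artifacts and rater perturbation


def add_screw_artifact(mask: TunnelMask, tip_offset, tip_radius: float) -> TunnelMask:
    """Union a spherical interference-screw tip lobe onto a tibial tunnel mask.

    The lobe centre sits at the distal end of the tunnel (found from the
    mask's principal axis) displaced by ``tip_offset`` (mm).  A zero-radius or
    fully interior lobe leaves the mask unchanged; a lobe that does not touch
    the tunnel wall is an error — a real screw tip protrudes *from* the wall.
    """
    if mask.side == "femur":
        raise ValueError("screw-tip artifacts are a tibial-tunnel phenomenon")
    if tip_radius < 0:
        raise ValueError("tip_radius must be >= 0")
    if tip_radius == 0:
        return mask.copy()
    coords = mask.world_coords()
    c = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - c, full_matrices=False)
    d = vt[0]
    # deterministic sign: dominant component positive, so "distal" is the
    # end of the tunnel away from the joint under the drilling convention
    if d[np.argmax(np.abs(d))] < 0:
        d = -d
    s = (coords - c) @ d
    distal = c + s.max() * d
    center = distal + np.asarray(tip_offset, dtype=float)

    lo = mask.origin
    hi = mask.origin + (np.asarray(mask.shape) - 1) * mask.spacing
    if np.any(center - tip_radius < lo) or np.any(center + tip_radius > hi):
        raise ValueError("screw tip lobe exits the phantom grid")

    idx = np.stack(
        np.meshgrid(*[np.arange(n) for n in mask.shape], indexing="ij"), axis=-1
    ).astype(float)
    world = mask.origin + idx * mask.spacing
    sphere = np.einsum("...i,...i->...", world - center, world - center) <= tip_radius**2
    if not (sphere & ~mask.data).any():
        return mask.copy()  # lobe fully inside the tunnel: union is a no-op
    union = mask.data | sphere
    from scipy import ndimage

    _, n_comp = ndimage.label(union, structure=np.ones((3, 3, 3)))
    if n_comp != 1:
        raise ValueError("screw tip lobe is disconnected from the tunnel wall")
    return replace(mask.copy(), data=union)


def perturb_segmentation(
    mask: TunnelMask,
    rater_bias_mm: float,
    boundary_noise_sd_mm: float,
    seed: int,
    min_component_voxels: int = 5,
) -> TunnelMask:
    """Emulate manual rater edits: a systematic boundary offset plus jitter.

    The mask boundary is moved outward by ``rater_bias_mm`` on average (sub-
    voxel shifts included) with voxel-wise Gaussian jitter of SD
    ``boundary_noise_sd_mm``.  A continuous signed distance to the boundary
    is estimated from the Gaussian-smoothed (partial-volume) mask indicator,
    ``x = -sigma * Phi^{-1}(u)``, and voxels in a band around the surface are
    re-classified by ``x <= bias + jitter``; the smoothed estimate is what
    lets a 0.2 mm bias move the *average* boundary by 0.2 mm on a 0.4 mm
    grid, where any voxel-quantised distance would respond in half-voxel
    steps.  Deterministic in ``seed``.
    """
    if rater_bias_mm == 0.0 and boundary_noise_sd_mm == 0.0:
        return mask.copy()
    if boundary_noise_sd_mm < 0:
        raise ValueError("boundary_noise_sd_mm must be >= 0")
    from scipy import ndimage
    from scipy.stats import norm as _norm

    spacing = mask.spacing
    sigma_mm = 0.5  # smoothing scale; small vs tunnel radii, > in-plane voxel
    u = ndimage.gaussian_filter(mask.data.astype(float), sigma=sigma_mm / spacing)
    eps = 1e-12
    sdf = -sigma_mm * _norm.ppf(np.clip(u, eps, 1.0 - eps))

    d_in = ndimage.distance_transform_edt(mask.data, sampling=spacing)
    d_out = ndimage.distance_transform_edt(~mask.data, sampling=spacing)
    coarse = d_out - d_in  # positive outside, negative inside
    band_halfwidth = (
        2.0 * float(spacing.max()) + abs(rater_bias_mm) + 4.0 * boundary_noise_sd_mm
    )
    band = np.abs(coarse) <= band_halfwidth

    rng = np.random.default_rng(seed)
    noise = (
        rng.normal(0.0, boundary_noise_sd_mm, size=int(band.sum()))
        if boundary_noise_sd_mm > 0 else 0.0
    )
    new = mask.data.copy()
    new[band] = sdf[band] <= rater_bias_mm + noise

    labels, n_comp = ndimage.label(new, structure=np.ones((3, 3, 3)))
    if n_comp > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n_comp + 1))
        keep_label = int(np.argmax(sizes)) + 1
        if (sizes < min_component_voxels).sum() != n_comp - 1:
            raise AclTunnelError(
                "rater perturbation destroyed mask connectivity "
                f"({n_comp} components)"
            )
        new = labels == keep_label  # drop isolated noise specks
    if not new.any():
        raise AclTunnelError("rater perturbation erased the mask")
    return replace(mask.copy(), data=new)


# ---------------------------------------------------------------------------
# communicating pairs


def generate_communicating_pair(
    ridge_distance_mm: Optional[float],
    spec: PhantomSpec,
    diameters: tuple[float, float] = (7.1, 5.8),
    length: float = 25.0,
    half_angle_deg: float = 10.0,
    side: str = "femur",
    seed: int = 0,
) -> tuple[TunnelMask, TunnelMask, GroundTruth]:
    """Two converging AM/PL tunnels sharing (or not) their joint-line opening.

    With a requested ridge distance ``d`` the entry points are placed so the
    tunnel surfaces touch for depths below ``d`` and separate beyond; with
    ``None`` the tunnels are parallel and separated at all depths.  Default
    diameters are the reported Year-0 femoral AM/PL drill sizes.
    """
    r1, r2 = diameters[0] / 2.0, diameters[1] / 2.0
    n = spec.joint_plane.normal
    # in-plane direction along which the tunnels separate
    lateral = unit(np.cross(n, [0.0, 1.0, 0.0] if abs(n[1]) < 0.9 else [1.0, 0.0, 0.0]))
    mid = np.asarray(spec.joint_plane.point, dtype=float)
    tan = np.tan(np.radians(half_angle_deg))

    if ridge_distance_mm is None:
        e0 = r1 + r2 + 3.0
        axis1 = axis2 = n
        truth_comm = False
        ridge = None
    else:
        if ridge_distance_mm <= 0 or ridge_distance_mm >= length:
            raise ValueError("ridge distance must lie within the tunnel length")
        e0 = (r1 + r2) - 2.0 * ridge_distance_mm * tan
        if e0 <= 0.2:
            raise ValueError(
                f"cannot realise a {ridge_distance_mm} mm ridge with radii "
                f"({r1:.2f}, {r2:.2f}) mm at half-angle {half_angle_deg} deg"
            )
        axis1 = unit(n - tan * lateral)
        axis2 = unit(n + tan * lateral)
        truth_comm = True
        ridge = float(ridge_distance_mm)

    t1 = TunnelSpec(mid - (e0 / 2.0) * lateral, axis1, length,
                    RadiusProfile(r1), side=side, bundle="AM")
    t2 = TunnelSpec(mid + (e0 / 2.0) * lateral, axis2, length,
                    RadiusProfile(r2), side=side, bundle="PL")
    _, masks, truth = generate_phantom(spec, [t1, t2], seed=seed, expect_overlap=True)
    truth.ridge_distance_mm = ridge
    truth.communicating = truth_comm
    return masks[0], masks[1], truth


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class TunnelTypeParams:
    """Distributional parameters (mm) for one tunnel type in one group."""

    d0_mean: float
    d0_sd: float
    widen_mean: float
    widen_sd: float


#: Published Year-0 diameters (best-fit cylinder) and 1-year widening,
#: mean +/- SD in mm, per group and tunnel type.
DEFAULT_TUNNEL_PARAMS: dict = {
    "SB": {
        "femur": TunnelTypeParams(8.3, 0.6, 1.4, 0.9),
        "tibia": TunnelTypeParams(10.0, 1.0, 1.0, 1.0),
    },
    "DB": {
        "femur_AM": TunnelTypeParams(7.1, 0.7, 0.5, 0.6),
        "femur_PL": TunnelTypeParams(5.8, 0.4, 0.8, 1.0),
        "tibia_AM": TunnelTypeParams(9.1, 0.8, 0.7, 0.8),
        "tibia_PL": TunnelTypeParams(7.0, 0.6, 0.5, 0.6),
    },
}

DEFAULT_N_SB = 22
DEFAULT_N_DB = 20

MEASUREMENT_LEVELS = ("cylinder", "aperture", "10mm")

#: Canonical tunnel placements (entry offsets in mm from the joint-plane
#: centre, axis tilt deg) used when cohorts are voxelized.
_PLACEMENTS = {
    "femur": (np.array([0.0, 0.0]), 10.0),
    "tibia": (np.array([0.0, 0.0]), 15.0),
    "femur_AM": (np.array([-5.5, 0.0]), 8.0),
    "femur_PL": (np.array([5.5, 0.0]), 14.0),
    "tibia_AM": (np.array([-6.0, 0.0]), 10.0),
    "tibia_PL": (np.array([6.0, 0.0]), 16.0),
}


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition parameters for a simulated two-group cohort."""

    n_sb: int = DEFAULT_N_SB
    n_db: int = DEFAULT_N_DB
    params: dict = field(default_factory=lambda: DEFAULT_TUNNEL_PARAMS)
    rng_seed: int = 0
    widening_profile: str = "uniform"
    tunnel_length: float = 25.0
    min_diameter: float = MIN_DIAMETER_MM
    min_widening: float = MIN_WIDENING_MM

    def __post_init__(self):
        if self.n_sb < 2 or self.n_db < 2:
            raise ValueError("need at least 2 subjects per group")
        for group in self.params.values():
            for p in group.values():
                if p.d0_sd < 0 or p.widen_sd < 0:
                    raise ValueError("SDs must be >= 0")


@dataclass
class CohortDataset:
    """Paired Year-0/Year-1 measurements plus ground truth for a cohort.

    ``table`` is long format: subject, group, tunnel, level, timepoint,
    diameter_mm (and true_diameter_mm).  ``specs`` holds the analytic
    TunnelSpec pairs per subject/tunnel for voxel-mode phantom building.
    """

    table: pd.DataFrame
    specs: list  # (subject_id, group, tunnel, year0 TunnelSpec, year1 TunnelSpec)
    spec: CohortSpec

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path, index=False)


def _truncated_normal(rng, mean, sd, lower, size):
    if sd == 0:
        out = np.full(size, float(mean))
        if np.any(out < lower):
            raise ValueError("degenerate draw below truncation bound")
        return out
    out = rng.normal(mean, sd, size)
    bad = out < lower
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out < lower
    return out


def _tunnel_spec_for(tunnel: str, diameter: float, length: float,
                     joint_plane: Plane) -> TunnelSpec:
    offset, tilt = _PLACEMENTS[tunnel]
    side = "femur" if tunnel.startswith("femur") else "tibia"
    bundle = tunnel.split("_")[1] if "_" in tunnel else "SB"
    n = joint_plane.normal
    lateral = unit(np.cross(n, [0.0, 1.0, 0.0] if abs(n[1]) < 0.9 else [1.0, 0.0, 0.0]))
    transverse = np.cross(n, lateral)
    entry = joint_plane.point + offset[0] * lateral + offset[1] * transverse
    tr = np.radians(tilt)
    axis = unit(np.cos(tr) * n + np.sin(tr) * lateral)
    return TunnelSpec(entry, axis, length, RadiusProfile(diameter / 2.0),
                      side=side, bundle=bundle)


def generate_cohort(cs: CohortSpec = CohortSpec(),
                    joint_plane: Optional[Plane] = None) -> CohortDataset:
    """Draw a paired two-timepoint cohort at the configured study conditions.

    Per subject and tunnel type, the Year-0 diameter is Normal(mu0, sd0)
    truncated above 4 mm and the subject-level widening Normal(muD, sdD)
    truncated above -0.5 mm; the widening is applied uniformly, so in this
    fast (analytic) mode all three measurement levels carry the same value.
    Phantom voxelization is deferred to the TunnelSpecs in ``specs``.
    """
    rng = np.random.default_rng(cs.rng_seed)
    if joint_plane is None:
        joint_plane = PhantomSpec().joint_plane
    rows = []
    specs = []
    group_sizes = {"SB": cs.n_sb, "DB": cs.n_db}
    subject_counter = 0
    for group in ("SB", "DB"):
        tunnels = cs.params[group]
        for _ in range(group_sizes[group]):
            subject_counter += 1
            sid = f"{group}{subject_counter:03d}"
            for tunnel, p in tunnels.items():
                d0 = float(_truncated_normal(rng, p.d0_mean, p.d0_sd,
                                             cs.min_diameter, 1)[0])
                delta = float(_truncated_normal(rng, p.widen_mean, p.widen_sd,
                                                cs.min_widening, 1)[0])
                t0 = _tunnel_spec_for(tunnel, d0, cs.tunnel_length, joint_plane)
                t1 = widen_tunnel(t0, delta, cs.widening_profile)
                specs.append((sid, group, tunnel, t0, t1))
                for timepoint, ts in (("year0", t0), ("year1", t1)):
                    tr = ts.truth(timepoint)
                    level_values = {
                        "cylinder": tr.diameter_mean,
                        "aperture": tr.diameter_aperture,
                        "10mm": tr.diameter_at10mm,
                    }
                    for level in MEASUREMENT_LEVELS:
                        rows.append({
                            "subject": sid, "group": group, "tunnel": tunnel,
                            "level": level, "timepoint": timepoint,
                            "diameter_mm": level_values[level],
                            "true_diameter_mm": level_values[level],
                        })
    return CohortDataset(table=pd.DataFrame(rows), specs=specs, spec=cs)
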
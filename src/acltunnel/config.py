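"""Run configuration for the command-line pipeline.

A single declarative mapping (YAML or dict) validated up front; its SHA-256
hash and the seed are embedded in every output for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .core import AclTunnelError


@dataclass
class RunConfig:
    # phantom geometry
    grid_shape: tuple = (96, 96, 40)
    spacing: tuple = (0.4, 0.4, 1.5)
    joint_plane_point: tuple = (19.2, 19.2, 9.0)
    joint_plane_normal: tuple = (0.0, 0.0, 1.0)
    noise_sd: float = 20.0
    # measurement
    slab_halfwidth: float = 1.0
    circle_depth: float = 10.0
    trim_range: tuple = (0.0, 23.0)
    k_mad: float = 3.5
    filter_max_iter: int = 5
    surface_method: str = "isosurface"
    # cohort
    n_sb: int = 22
    n_db: int = 20
    widening_profile: str = "uniform"
    tunnel_length: float = 25.0
    # statistics
    bootstrap_b: int = 2000
    alpha: float = 0.05
    power_delta: float = 0.5
    power_sd: float = 0.74
    power_target: float = 0.80
    seed: int = 0

    def validate(self) -> "RunConfig":
        if len(self.grid_shape) != 3 or any(int(n) < 2 for n in self.grid_shape):
            raise AclTunnelError(f"invalid grid_shape {self.grid_shape}")
        if len(self.spacing) != 3 or any(float(s) <= 0 for s in self.spacing):
            raise AclTunnelError(f"invalid spacing {self.spacing}: must be positive mm")
        a, b = self.trim_range
        if not a < b:
            raise AclTunnelError(f"trim_range must be increasing, got {self.trim_range}")
        if self.slab_halfwidth <= 0 or self.circle_depth <= 0:
            raise AclTunnelError("slab_halfwidth and circle_depth must be positive")
        if self.n_sb < 2 or self.n_db < 2:
            raise AclTunnelError("need at least 2 subjects per group")
        if self.bootstrap_b < 200:
            raise AclTunnelError("bootstrap_b must be >= 200")
        if not 0 < self.alpha < 1:
            raise AclTunnelError("alpha must lie in (0, 1)")
        if self.surface_method not in ("isosurface", "voxel_faces"):
            raise AclTunnelError(f"unknown surface_method {self.surface_method!r}")
        if self.widening_profile not in ("uniform", "aperture_weighted"):
            raise AclTunnelError(f"unknown widening_profile {self.widening_profile!r}")
        return self

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise AclTunnelError(f"unknown config keys: {sorted(unknown)}")
        for key in ("grid_shape", "spacing", "joint_plane_point",
                    "joint_plane_normal", "trim_range"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw).validate()

    def as_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        canon = json.dumps(self.as_dict(), sort_keys=True, default=list)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def phantom_spec(self):
        from .core import Plane
        from .phantom import PhantomSpec

        return PhantomSpec(
            grid_shape=tuple(int(n) for n in self.grid_shape),
            spacing=tuple(float(s) for s in self.spacing),
            joint_plane=Plane(self.joint_plane_point, self.joint_plane_normal),
            noise_sd=self.noise_sd,
        )

    def joint_plane(self):
        from .core import Plane

        return Plane(self.joint_plane_point, self.joint_plane_normal)
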
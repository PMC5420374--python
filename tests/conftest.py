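"""Shared fixtures: phantoms, point clouds, and the measurement pipeline."""

import numpy as np
import pytest

from acltunnel import phantom as ph
from acltunnel import volumes as vio
from acltunnel import geometry as geo


@pytest.fixture(scope="session")
def spec():
    return ph.PhantomSpec()


@pytest.fixture(scope="session")
def plane(spec):
    return spec.joint_plane


@pytest.fixture(scope="session")
def axial_tunnel_8mm(spec, plane):
    """A clean 8 mm tunnel perpendicular to the joint plane, plus its mask."""
    t = ph.TunnelSpec.drilled(plane.point, (0, 0, 1), 8.0, 25.0, side="tibia")
    vol, masks, truth = ph.generate_phantom(spec, [t], seed=1)
    return t, vol, masks[0], truth


def exact_cylinder_points(radius=4.0, length=30.0, n=2000, seed=0,
                          axis_point=(0.0, 0.0, 0.0), axis_dir=(0.0, 0.0, 1.0)):
    """Exact (noise-free) points on a cylinder surface, for oracle tests."""
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0, 2 * np.pi, n)
    s = rng.uniform(0, length, n)
    d = np.asarray(axis_dir, dtype=float)
    d = d / np.linalg.norm(d)
    helper = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return (
        np.asarray(axis_point)
        + s[:, None] * d
        + radius * (np.cos(theta)[:, None] * e1 + np.sin(theta)[:, None] * e2)
    )


def measure_phantom_tunnel(tunnel, spec, plane, method="isosurface",
                           trim=(0.0, 23.0), screw_filter=False):
    """mask -> points -> trim -> (filter) -> measurement, as the CLI does."""
    _, masks, truth = ph.generate_phantom(spec, [tunnel], seed=1,
                                          expect_overlap=True)
    pts = vio.mask_to_points(masks[0], method)
    pts = vio.trim_tunnel(pts, np.asarray(plane.normal), trim, plane)
    if screw_filter:
        pts, _ = vio.filter_screw_outliers(pts, joint_plane=plane)
    return geo.measure_tunnel(pts, plane), truth


def random_oblique_tunnel(rng, plane, diameter=None, max_tilt_deg=30.0,
                          length=25.0):
    """A random drilled tunnel whose mid-axis stays near the grid centre."""
    dia = diameter if diameter is not None else rng.uniform(5.0, 10.0)
    tilt = np.radians(rng.uniform(0.0, max_tilt_deg))
    az = rng.uniform(0, 2 * np.pi)
    d = np.array([np.sin(tilt) * np.cos(az), np.sin(tilt) * np.sin(az), np.cos(tilt)])
    inplane = np.array([d[0], d[1], 0.0])
    nrm = np.linalg.norm(inplane)
    entry = np.asarray(plane.point, dtype=float)
    if nrm > 1e-9:
        entry = entry - (length / 2.0) * np.sin(tilt) * inplane / nrm
    return ph.TunnelSpec.drilled(entry, d, dia, length)
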
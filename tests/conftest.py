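"""Shared fixtures: expensive geometry built once per session."""

import numpy as np
import pytest
import trimesh

from ufiberlab.laplace import gradient_field, solve_laplace
from ufiberlab.phantom import Phantom, make_phantom
from ufiberlab.streamlines import trace_streamlines


@pytest.fixture(scope="session")
def sphere_phantom():
    """Default concentric-sphere phantom (outer 20, inner 10, 1 mm, order 3)."""
    return make_phantom(outer_radius=20.0, inner_radius=10.0, voxel_size=1.0,
                        mesh_order=3, seed=0)


@pytest.fixture(scope="session")
def sphere_potential(sphere_phantom):
    return solve_laplace(sphere_phantom, tol=1e-7)


@pytest.fixture(scope="session")
def sphere_gradient(sphere_phantom, sphere_potential):
    g, _ = gradient_field(sphere_potential)
    return g


@pytest.fixture(scope="session")
def sphere_streamlines(sphere_phantom, sphere_gradient):
    return trace_streamlines(sphere_phantom, sphere_gradient)


def make_slab_phantom(thickness=10.0, width=20.0, voxel_size=1.0):
    """Plane-parallel phantom: phi=0 at z=thickness (top), phi=1 at z=0.

    White matter fills 0 < z < thickness; the "ventricle" is the half-space
    z <= 0.  The seeding surface is a flat triangulated sheet at the top.
    """
    nz = int(thickness / voxel_size) + 5
    nxy = int(width / voxel_size) + 1
    shape = (nxy, nxy, nz)
    origin = np.array([0.0, 0.0, -2.0 * voxel_size])
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    z = grids[2] * voxel_size + origin[2]
    vent = z <= 0
    outer_dist = thickness - z       # positive below the top plane
    inner_dist = z                   # positive above the ventricle plane
    wm = (outer_dist > 0) & (inner_dist > 0)

    # flat sheet mesh at z = thickness (interior seeds only, away from edges)
    n = 9
    xs = np.linspace(width * 0.25, width * 0.75, n)
    vv, uu = np.meshgrid(xs, xs, indexing="ij")
    verts = np.column_stack([uu.ravel(), vv.ravel(),
                             np.full(n * n, thickness)])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            faces += [[a, a + 1, a + n], [a + 1, a + n + 1, a + n]]
    surf = trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False)

    return Phantom(
        voxel_size=voxel_size, origin=origin, wm_mask=wm,
        ventricle_mask=vent, surface=surf,
        roi_labels=np.ones(len(verts), dtype=int),
        outer_dist=outer_dist, inner_dist=inner_dist,
        centers=np.zeros((1, 3)), outer_radius=np.inf,
        inner_radius=thickness,
    )


@pytest.fixture(scope="session")
def slab_phantom():
    return make_slab_phantom()


@pytest.fixture(scope="session")
def slab_potential(slab_phantom):
    return solve_laplace(slab_phantom, tol=1e-7)
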
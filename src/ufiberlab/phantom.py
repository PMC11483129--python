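"""Synthetic phantom geometry: concentric-sphere white matter shells.

The phantom stands in for a segmented brain: an outer gray/white boundary
surface (a recursively subdivided icosahedron, optionally radially perturbed
to mimic gyrification), an inner "ventricle" sphere, and the white-matter
shell between them.  The unperturbed sphere admits closed-form solutions of
the Laplace problem, which makes every downstream stage testable against
analytic oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

__all__ = ["Phantom", "make_phantom", "roi_directions", "voxel_roi_sector"]


@dataclass
class Phantom:
    """Voxelized two-boundary geometry plus its boundary surface mesh.

    Attributes
    ----------
    voxel_size : float
        Isotropic voxel edge length in mm.
    origin : (3,) ndarray
        World coordinate (mm) of the center of voxel (0, 0, 0).
    wm_mask : (X, Y, Z) bool ndarray
        White matter: voxels strictly between the two boundaries.
    ventricle_mask : (X, Y, Z) bool ndarray
        Inner (high-potential) boundary region.
    surface : trimesh.Trimesh
        Gray/white boundary mesh in world mm with outward normals.
    roi_labels : (V,) int ndarray
        Per-vertex region label, 1..n_rois (0 would mean background).
    outer_dist : (X, Y, Z) float ndarray
        Signed distance to the outer boundary, positive inside (mm).
        Radial approximation; exact for zero gyrification.
    inner_dist : (X, Y, Z) float ndarray
        Signed distance to the ventricle boundary, positive in white matter.
    centers : (H, 3) ndarray
        Hemisphere center(s) in world mm.
    outer_radius, inner_radius : float
        Nominal sphere radii (mm).
    gyrification_amplitude : float
        Relative radial perturbation scale of the outer boundary.
    """

    voxel_size: float
    origin: np.ndarray
    wm_mask: np.ndarray
    ventricle_mask: np.ndarray
    surface: trimesh.Trimesh
    roi_labels: np.ndarray
    outer_dist: np.ndarray
    inner_dist: np.ndarray
    centers: np.ndarray
    outer_radius: float
    inner_radius: float
    gyrification_amplitude: float = 0.0
    n_rois: int = 12
    _perturb: object = field(default=None, repr=False)

    @property
    def shape(self) -> tuple:
        return self.wm_mask.shape

    def affine(self) -> np.ndarray:
        """Index -> world (mm) affine, voxel-center convention."""
        A = np.eye(4)
        A[:3, :3] = np.eye(3) * self.voxel_size
        A[:3, 3] = self.origin
        return A

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, float) - self.origin) / self.voxel_size

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(idx, float) * self.voxel_size + self.origin

    def voxel_centers(self) -> np.ndarray:
        """(X, Y, Z, 3) world coordinates of all voxel centers."""
        grids = np.meshgrid(*[np.arange(s) for s in self.shape], indexing="ij")
        idx = np.stack(grids, axis=-1).astype(float)
        return idx * self.voxel_size + self.origin

    def nearest_center(self, points: np.ndarray) -> np.ndarray:
        """Index of the closest hemisphere center for each point."""
        pts = np.atleast_2d(np.asarray(points, float))
        d2 = ((pts[:, None, :] - self.centers[None, :, :]) ** 2).sum(-1)
        return np.argmin(d2, axis=1)

    def radial_frame(self, points: np.ndarray):
        """Radial and tangential (azimuthal) unit vectors at world points.

        The tangential direction is the azimuthal unit vector of the
        spherical frame around the nearest hemisphere center; at the poles
        (where the azimuth is undefined) a fixed fallback axis x-hat is used.
        """
        pts = np.atleast_2d(np.asarray(points, float))
        ci = self.nearest_center(pts)
        rel = pts - self.centers[ci]
        r = np.linalg.norm(rel, axis=1)
        r_safe = np.where(r > 1e-12, r, 1.0)
        radial = rel / r_safe[:, None]
        rho = np.hypot(rel[:, 0], rel[:, 1])
        az = np.zeros_like(radial)
        ok = rho > 1e-8 * np.maximum(r, 1e-12)
        az[ok, 0] = -rel[ok, 1] / rho[ok]
        az[ok, 1] = rel[ok, 0] / rho[ok]
        az[~ok] = [1.0, 0.0, 0.0]  # pole fallback, orthogonal to z
        return radial, az


def _perturbation(seed: int, bands=(3, 4, 5)):
    """Smooth random angular function s(u) with max|s| normalized to 1.

    Built from a fixed set of low-order direction lobes so the outer
    boundary undulates like coarse gyri.  Deterministic in ``seed``.
    """
    rng = np.random.default_rng(seed)
    axes = rng.normal(size=(8, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    degs = rng.choice(bands, size=8)
    amps = rng.normal(size=8)

    def s(units: np.ndarray) -> np.ndarray:
        u = np.atleast_2d(units)
        out = np.zeros(len(u))
        for ax, l, a in zip(axes, degs, amps):
            out += a * np.cos(l * np.arccos(np.clip(u @ ax, -1, 1)))
        return out

    # normalize on a probe set so max |s| == 1
    probe = trimesh.creation.icosphere(subdivisions=3).vertices
    scale = np.abs(s(probe)).max()
    if scale == 0:
        return lambda u: np.zeros(len(np.atleast_2d(u)))
    return lambda u: s(u) / scale


def roi_directions(n_rois: int = 12, seed: int = 7) -> np.ndarray:
    """Unit directions defining ROI sectors (spherical Voronoi seeds)."""
    if n_rois == 12:
        return trimesh.creation.icosphere(subdivisions=0).vertices.copy()
    rng = np.random.default_rng(seed)
    d = rng.normal(size=(n_rois, 3))
    return d / np.linalg.norm(d, axis=1, keepdims=True)


def _label_by_sector(units: np.ndarray, dirs: np.ndarray) -> np.ndarray:
    return np.argmax(units @ dirs.T, axis=1) + 1


def voxel_roi_sector(phantom: Phantom, roi_id: int,
                     margin_deg: float = 0.0) -> np.ndarray:
    """Boolean volume: white-matter voxels lying in a ROI's radial sector.

    ``margin_deg`` widens the sector: a voxel is included when its angular
    distance to the ROI seed direction is within that of its best seed
    plus the margin.  A margin of 0 gives the exact spherical Voronoi
    cell; a few degrees absorbs the half-voxel quantization of voxel
    centers relative to surface vertices at the sector boundary.
    """
    ctr = phantom.voxel_centers().reshape(-1, 3)
    ci = phantom.nearest_center(ctr)
    rel = ctr - phantom.centers[ci]
    r = np.linalg.norm(rel, axis=1)
    units = rel / np.where(r > 1e-12, r, 1.0)[:, None]
    dirs = roi_directions(phantom.n_rois)
    cos_all = np.clip(units @ dirs.T, -1.0, 1.0)
    ang = np.degrees(np.arccos(cos_all))
    theta_roi = ang[:, roi_id - 1]
    theta_best = ang.min(axis=1)
    inside = (theta_roi <= theta_best + margin_deg).reshape(phantom.shape)
    return inside & phantom.wm_mask


def make_phantom(
    outer_radius: float = 20.0,
    inner_radius: float = 10.0,
    voxel_size: float = 1.0,
    gyrification_amplitude: float = 0.0,
    mesh_order: int = 3,
    seed: int = 0,
    hemispheres: int = 1,
    n_rois: int = 12,
    grid_shape: tuple | None = None,
) -> Phantom:
    """Build a concentric-shell phantom with an icosphere boundary mesh.

    Parameters
    ----------
    outer_radius, inner_radius : float
        Radii (mm) of the gray/white boundary and the ventricle sphere.
    voxel_size : float
        Isotropic voxel size in mm.
    gyrification_amplitude : float
        Relative amplitude of a smooth angular perturbation of the outer
        radius (0 gives a perfect sphere with analytic Laplace solution).
    mesh_order : int
        Icosphere subdivision order; vertex count is 10 * 4**order + 2.
    hemispheres : int
        1 or 2; two hemispheres duplicate the mesh with a lateral offset.
    grid_shape : tuple, optional
        Explicit voxel grid shape.  Must contain the outer surface plus a
        2-voxel margin, else a sizing error is raised.
    """
    if inner_radius <= 0:
        raise ValueError("inner_radius must be positive")
    if inner_radius >= outer_radius:
        raise ValueError("inner_radius must be smaller than outer_radius")
    if hemispheres not in (1, 2):
        raise ValueError("hemispheres must be 1 or 2")

    g = float(gyrification_amplitude)
    r_max = outer_radius * (1.0 + abs(g))
    gap = 5.0  # lateral gap between hemispheres, mm
    if hemispheres == 2:
        off = r_max + gap / 2.0
        centers = np.array([[-off, 0.0, 0.0], [off, 0.0, 0.0]])
    else:
        centers = np.zeros((1, 3))

    half_extent = np.abs(centers).max(axis=0) + r_max + 2 * voxel_size
    need = np.ceil(2 * half_extent / voxel_size).astype(int) + 1
    if grid_shape is None:
        shape = tuple(int(n) for n in need)
    else:
        shape = tuple(grid_shape)
        if any(s < n for s, n in zip(shape, need)):
            raise ValueError(
                f"grid_shape {shape} too small: need at least {tuple(need)} "
                "to contain the outer surface plus a 2-voxel margin"
            )
    origin = -(np.array(shape) - 1) / 2.0 * voxel_size

    perturb = _perturbation(seed) if g != 0 else None

    def outer_r_of(units):
        if perturb is None:
            return np.full(len(np.atleast_2d(units)), outer_radius)
        return outer_radius * (1.0 + g * perturb(units))

    # ---- surface mesh --------------------------------------------------
    base = trimesh.creation.icosphere(subdivisions=mesh_order, radius=1.0)
    units = base.vertices / np.linalg.norm(base.vertices, axis=1, keepdims=True)
    verts = units * outer_r_of(units)[:, None]
    meshes, labels = [], []
    dirs = roi_directions(n_rois)
    for c in centers:
        m = trimesh.Trimesh(vertices=verts + c, faces=base.faces.copy(), process=False)
        meshes.append(m)
        labels.append(_label_by_sector(units, dirs))
    surface = trimesh.util.concatenate(meshes) if len(meshes) > 1 else meshes[0]
    roi_labels = np.concatenate(labels)

    # ---- voxel masks and signed distances ------------------------------
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    ctr = np.stack(grids, axis=-1) * voxel_size + origin
    flat = ctr.reshape(-1, 3)
    d2 = ((flat[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
    ci = np.argmin(d2, axis=1)
    rel = flat - centers[ci]
    r = np.linalg.norm(rel, axis=1)
    u = rel / np.where(r > 1e-12, r, 1.0)[:, None]
    r_out = outer_r_of(u)
    outer_dist = (r_out - r).reshape(shape)
    inner_dist = (r - inner_radius).reshape(shape)
    # boundaries inclusive: a voxel center exactly on an interface belongs
    # to the Dirichlet region, so it keeps the boundary value exactly
    ventricle = (inner_dist <= 0)
    wm = (outer_dist > 0) & ~ventricle

    return Phantom(
        voxel_size=float(voxel_size),
        origin=origin,
        wm_mask=wm,
        ventricle_mask=ventricle,
        surface=surface,
        roi_labels=roi_labels,
        outer_dist=outer_dist,
        inner_dist=inner_dist,
        centers=centers,
        outer_radius=float(outer_radius),
        inner_radius=float(inner_radius),
        gyrification_amplitude=g,
        n_rois=n_rois,
        _perturb=perturb,
    )
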
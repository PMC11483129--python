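"""Laplacian streamlines: laminar trajectories from cortex to ventricles.

One trajectory is seeded at every vertex of the gray/white boundary mesh
and propagated along the normalized Laplace-potential gradient with a
fixed 0.1 mm Euler step, truncated at 5 mm of arc length.  These are
geometric constructs (not diffusion tractography): their sole purpose is
to sample white matter at controlled depths below the cortex, so the
first segment leaves the surface perpendicularly and subsequent segments
bend smoothly toward the ventricles without crossing each other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .phantom import Phantom

__all__ = ["LaplacianStreamline", "trace_streamlines", "depth_points",
           "depth_tangent"]

TERMINATIONS = ("max_length", "reached_ventricle", "left_mask", "stalled",
                "seed_outside_grid")


@dataclass
class LaplacianStreamline:
    """Ordered world-mm points of one seeded trajectory."""

    seed_vertex_id: int
    points: np.ndarray        # (n_points, 3) world mm
    step: float               # mm
    arc_length: float         # mm, n_full_steps * step + final partial step
    termination: str

    def arc_lengths(self) -> np.ndarray:
        """Cumulative arc length at each point."""
        if len(self.points) < 2:
            return np.zeros(len(self.points))
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])


def _interp_vec(vol4, idx):
    """Trilinear interpolation of a vector volume at fractional indices."""
    out = np.empty((len(idx), vol4.shape[-1]))
    for c in range(vol4.shape[-1]):
        out[:, c] = map_coordinates(vol4[..., c], idx.T, order=1, mode="nearest")
    return out


def _interp_scal(vol, idx):
    return map_coordinates(vol.astype(float), idx.T, order=1, mode="nearest")


def trace_streamlines(
    phantom: Phantom,
    gradient: np.ndarray,
    step: float = 0.1,
    max_length: float = 5.0,
) -> list:
    """Propagate one streamline per surface vertex along the gradient.

    Fixed-step Euler integration of the trilinearly interpolated,
    renormalized gradient.  A streamline stops when it reaches
    ``max_length``, enters the ventricle mask, leaves the white-matter
    mask, or the interpolated gradient magnitude falls below 1e-8
    (stalled; one retry nudges the seed 0.05 mm inward along the vertex
    normal).  Streamlines are returned in vertex order, one per vertex.
    """
    seeds = np.asarray(phantom.surface.vertices, float)
    normals = np.asarray(phantom.surface.vertex_normals, float)
    n = len(seeds)
    shape = np.array(phantom.shape)

    max_steps = int(np.floor(max_length / step + 1e-9))
    wm_or_vent = (phantom.wm_mask | phantom.ventricle_mask).astype(float)
    vent = phantom.ventricle_mask.astype(float)

    # Within one voxel of the gray/white boundary the discrete potential
    # gradient is corrupted by the staircase representation of the Dirichlet
    # surface, while the equipotential there parallels the boundary by
    # construction; blend toward the boundary's inward normal (from the
    # signed distance) in that shell.
    sdf_dir = None
    if phantom.outer_dist is not None:
        h = phantom.voxel_size
        sg = np.stack(np.gradient(phantom.outer_dist, h), axis=-1)
        smag = np.linalg.norm(sg, axis=-1)
        okm = smag > 1e-12
        sg[okm] /= smag[okm][..., None]
        sg[~okm] = 0.0
        sdf_dir = sg  # points toward increasing inside-distance (inward)

    pos = seeds.copy()
    idx0 = phantom.world_to_index(pos)
    in_grid = np.all((idx0 >= 0) & (idx0 <= shape - 1), axis=1)

    alive = in_grid.copy()
    term = np.array(["seed_outside_grid"] * n, dtype=object)
    term[in_grid] = ""
    paths = [[p.copy()] for p in pos]
    nudged = np.zeros(n, bool)
    arc = np.zeros(n)

    if max_length <= 0:
        for i in range(n):
            if term[i] == "":
                term[i] = "max_length"
        return [LaplacianStreamline(i, np.array(paths[i]), step, 0.0, term[i])
                for i in range(n)]

    for _ in range(max_steps):
        if not alive.any():
            break
        ai = np.flatnonzero(alive)
        idx = phantom.world_to_index(pos[ai])
        g = _interp_vec(gradient, idx)
        if sdf_dir is not None:
            dist = _interp_scal(phantom.outer_dist, idx)
            w = np.clip(dist / phantom.voxel_size, 0.0, 1.0)[:, None]
            nrm_in = _interp_vec(sdf_dir, idx)
            g = w * g + (1.0 - w) * nrm_in
        mag = np.linalg.norm(g, axis=1)

        # stalled seeds get one retry: nudge inward along the vertex normal
        stall = mag < 1e-8
        retry = stall & ~nudged[ai] & (arc[ai] == 0.0)
        if retry.any():
            ri = ai[retry]
            pos[ri] -= 0.05 * normals[ri]
            nudged[ri] = True
            idx_r = phantom.world_to_index(pos[ri])
            g_r = _interp_vec(gradient, idx_r)
            mag_r = np.linalg.norm(g_r, axis=1)
            g[retry] = g_r
            mag[retry] = mag_r
            stall = mag < 1e-8
        if stall.any():
            for i in ai[stall]:
                term[i] = "stalled"
            alive[ai[stall]] = False
            ai = ai[~stall]
            g, mag = g[~stall], mag[~stall]
        if len(ai) == 0:
            continue

        new = pos[ai] + step * (g / mag[:, None])
        pos[ai] = new
        arc[ai] += step
        for j, i in enumerate(ai):
            paths[i].append(new[j].copy())

        idx_new = phantom.world_to_index(new)
        off = ~np.all((idx_new >= 0) & (idx_new <= shape - 1), axis=1)
        inside = _interp_scal(wm_or_vent, np.clip(idx_new, 0, shape - 1))
        in_vent = _interp_scal(vent, np.clip(idx_new, 0, shape - 1))
        done_vent = in_vent >= 0.5
        done_left = (off | (inside <= 1e-6)) & ~done_vent
        for j, i in enumerate(ai):
            if done_vent[j]:
                term[i] = "reached_ventricle"
                alive[i] = False
            elif done_left[j]:
                term[i] = "left_mask"
                alive[i] = False

    for i in np.flatnonzero(alive):
        term[i] = "max_length"

    return [
        LaplacianStreamline(i, np.array(paths[i]), step, float(arc[i]),
                            str(term[i]))
        for i in range(n)
    ]


def depth_points(streamline: LaplacianStreamline,
                 depths=(0.0, 0.5, 1.0, 1.5, 2.0)) -> np.ndarray:
    """Points at the requested arc lengths along the trajectory.

    Linear interpolation along the polyline; depths beyond the
    streamline's arc length return NaN rows (missing marker).
    """
    depths = np.asarray(depths, float)
    if np.any(depths < 0):
        raise ValueError("depths must be nonnegative")
    if np.any(np.diff(depths) < 0):
        raise ValueError("depths must be sorted ascending")
    s = streamline.arc_lengths()
    out = np.full((len(depths), 3), np.nan)
    ok = depths <= s[-1] + 1e-12
    if ok.any() and len(streamline.points) >= 1:
        for c in range(3):
            out[ok, c] = np.interp(depths[ok], s, streamline.points[:, c])
    return out


def depth_tangent(streamline: LaplacianStreamline, depth: float) -> np.ndarray:
    """Unit tangent at a given arc length (central difference of the
    bracketing polyline points); NaN vector when the depth is missing."""
    s = streamline.arc_lengths()
    if depth > s[-1] + 1e-12 or len(streamline.points) < 2:
        return np.full(3, np.nan)
    j = int(np.clip(np.searchsorted(s, depth, side="right"), 1, len(s) - 1))
    lo, hi = j - 1, j
    if abs(s[lo] - depth) < 1e-9 and lo > 0:  # exactly on a point: centered
        lo -= 1
    d = streamline.points[hi] - streamline.points[lo]
    nrm = np.linalg.norm(d)
    return d / nrm if nrm > 0 else np.full(3, np.nan)
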
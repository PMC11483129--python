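"""Per-voxel fiber populations (fixels) and the planted two-system field.

A fixel is one fiber population within a voxel: an axial unit direction
(v and -v equivalent) plus a nonnegative apparent fiber density (AFD).
Storage follows the on-disk fixel-directory convention: an index volume
(count, offset) into flat direction/AFD tables, so empty voxels cost
nothing and the field round-trips exactly through files.

The planted field realizes the two fiber systems that coexist in
superficial white matter: long-range fibers radial to the cortex and
U-fibers running tangentially, the latter peaking near 1.5 mm depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import Phantom, voxel_roi_sector
from .tapping_sim import SubjectSpec

__all__ = [
    "FixelField",
    "plant_fixel_field",
    "default_radial_profile",
    "default_tangential_profile",
]


def default_radial_profile(d):
    """AFD of the radial (long-range) population vs depth: constant 0.5."""
    d = np.asarray(d, float)
    return np.full(d.shape, 0.5)


def default_tangential_profile(d, peak: float = 0.5, depth0: float = 1.5,
                               width: float = 1.0):
    """Gaussian U-fiber density profile peaking at 1.5 mm below the cortex."""
    d = np.asarray(d, float)
    return peak * np.exp(-0.5 * ((d - depth0) / width) ** 2)


@dataclass
class FixelField:
    """Sparse per-voxel fixel lists over a voxel grid.

    index : (X, Y, Z, 2) int ndarray -- per voxel [count, offset]
    directions : (N, 3) float ndarray -- axial unit vectors
    afd : (N,) float ndarray -- nonnegative densities
    """

    index: np.ndarray
    directions: np.ndarray
    afd: np.ndarray
    voxel_size: float
    origin: np.ndarray

    def __post_init__(self):
        if len(self.directions):
            norms = np.linalg.norm(self.directions, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise ValueError("fixel directions must be unit length")
        if np.any(self.afd < 0):
            raise ValueError("fixel AFD must be nonnegative")

    @property
    def shape(self):
        return self.index.shape[:3]

    @property
    def n_fixels(self) -> int:
        return len(self.afd)

    def fixels_at(self, i: int, j: int, k: int):
        """(directions, afd) arrays of the fixels in one voxel."""
        cnt, off = self.index[i, j, k]
        return self.directions[off:off + cnt], self.afd[off:off + cnt]

    def copy_with_afd(self, afd: np.ndarray) -> "FixelField":
        return FixelField(self.index, self.directions, np.asarray(afd, float),
                          self.voxel_size, self.origin)


def plant_fixel_field(
    phantom: Phantom,
    radial_profile=default_radial_profile,
    tangential_profile=default_tangential_profile,
    subject: SubjectSpec | None = None,
    roi_id: int = 1,
    noise_sd: float = 0.0,
    sector_margin_deg: float = 3.0,
) -> FixelField:
    """Plant radial + tangential fixels across the white-matter shell.

    Each white-matter voxel at depth ``d`` below the gray/white boundary
    receives a radial fixel with AFD ``radial_profile(d)`` and, where the
    tangential profile is nonzero, a tangential fixel (azimuthal direction,
    orthogonal to the local radial direction) with AFD
    ``tangential_profile(d)`` scaled by ``subject.tan_amplitude`` inside the
    radial sector of ``roi_id``.

    ``noise_sd`` adds independent zero-mean Gaussian AFD noise (clipped at
    zero) to every planted fixel, seeded from ``subject.seed``; the default
    of 0 keeps the field an exact realization of the profiles.
    ``sector_margin_deg`` widens the planted sector slightly beyond the
    ROI's Voronoi cell so every ROI-labeled vertex samples planted voxels
    despite voxel-center quantization at the sector boundary.
    """
    subject = subject if subject is not None else SubjectSpec()
    wm = phantom.wm_mask
    ijk = np.argwhere(wm)
    pts = phantom.index_to_world(ijk)
    depth = phantom.outer_dist[wm]

    r_afd = np.asarray(radial_profile(depth), float)
    t_afd = np.asarray(tangential_profile(depth), float)
    if np.any(r_afd < 0) or np.any(t_afd < 0):
        raise ValueError("fiber density profiles must be nonnegative")

    in_roi = voxel_roi_sector(phantom, roi_id, sector_margin_deg)[wm]
    t_afd = t_afd * np.where(in_roi, subject.tan_amplitude, 1.0)

    radial, tangential = phantom.radial_frame(pts)

    if noise_sd > 0:
        rng = np.random.default_rng(subject.seed)
        r_afd = np.where(r_afd > 0,
                         np.clip(r_afd + rng.normal(0, noise_sd, r_afd.shape), 0, None),
                         r_afd)
        t_afd = np.where(t_afd > 0,
                         np.clip(t_afd + rng.normal(0, noise_sd, t_afd.shape), 0, None),
                         t_afd)

    nvox = len(ijk)
    keep_r = r_afd > 0
    keep_t = t_afd > 0
    counts = keep_r.astype(int) + keep_t.astype(int)

    index = np.zeros(phantom.shape + (2,), dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(counts)[:-1]])
    index[ijk[:, 0], ijk[:, 1], ijk[:, 2], 0] = counts
    index[ijk[:, 0], ijk[:, 1], ijk[:, 2], 1] = offsets

    total = int(counts.sum())
    directions = np.zeros((total, 3))
    afd = np.zeros(total)
    # radial fixel first in each voxel where present
    pos_r = offsets[keep_r]
    directions[pos_r] = radial[keep_r]
    afd[pos_r] = r_afd[keep_r]
    pos_t = offsets[keep_t] + keep_r[keep_t].astype(int)
    directions[pos_t] = tangential[keep_t]
    afd[pos_t] = t_afd[keep_t]

    return FixelField(index=index, directions=directions, afd=afd,
                      voxel_size=phantom.voxel_size, origin=phantom.origin.copy())
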
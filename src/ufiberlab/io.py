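"""File-format plumbing: NIfTI, GIFTI, TCK, fixel directories, CSV.

Conventions enforced at every boundary: world coordinates in mm, voxel
indices 0-based with the voxel-center convention, affine maps index to
world, streamline points in world mm.  NIfTI volumes are written
uncompressed so that identical runs produce bitwise-identical files.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import trimesh

from .fixelfield import FixelField
from .tapping_sim import TappingSession, Trial

__all__ = [
    "save_nifti", "load_nifti", "save_surface_gifti", "load_surface_gifti",
    "save_streamlines_tck", "load_streamlines_tck",
    "streamlines_to_frame", "save_fixel_dir", "load_fixel_dir",
    "save_sessions_csv", "load_sessions_csv",
    "save_vertex_table", "load_vertex_table",
]


def save_nifti(path, data: np.ndarray, affine: np.ndarray,
               dtype=None) -> Path:
    path = Path(path)
    arr = np.asarray(data)
    if dtype is not None:
        arr = arr.astype(dtype)
    elif arr.dtype == bool:
        arr = arr.astype(np.int8)
    img = nib.Nifti1Image(arr, np.asarray(affine, float))
    nib.save(img, str(path))
    return path


def load_nifti(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def save_surface_gifti(path, surface: trimesh.Trimesh) -> Path:
    path = Path(path)
    coords = nib.gifti.GiftiDataArray(
        np.asarray(surface.vertices, np.float32), intent="NIFTI_INTENT_POINTSET")
    faces = nib.gifti.GiftiDataArray(
        np.asarray(surface.faces, np.int32), intent="NIFTI_INTENT_TRIANGLE")
    nib.save(nib.gifti.GiftiImage(darrays=[coords, faces]), str(path))
    return path


def load_surface_gifti(path) -> trimesh.Trimesh:
    img = nib.load(str(path))
    coords = img.get_arrays_from_intent("NIFTI_INTENT_POINTSET")[0].data
    faces = img.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")[0].data
    return trimesh.Trimesh(vertices=coords.astype(float),
                           faces=faces.astype(int), process=False)


def save_streamlines_tck(path, streamlines) -> Path:
    path = Path(path)
    tract = nib.streamlines.Tractogram(
        [np.asarray(s.points, np.float32) for s in streamlines],
        affine_to_rasmm=np.eye(4))
    nib.streamlines.save(tract, str(path))
    return path


def load_streamlines_tck(path):
    """Streamline point lists (world mm); metadata beyond points is not
    reconstructed."""
    t = nib.streamlines.load(str(path))
    return [np.asarray(s, float) for s in t.streamlines]


def streamlines_to_frame(streamlines) -> pd.DataFrame:
    rows = []
    for s in streamlines:
        for k, p in enumerate(np.asarray(s.points)):
            rows.append((s.seed_vertex_id, k, p[0], p[1], p[2]))
    return pd.DataFrame(rows, columns=["vertex_id", "point_index",
                                       "x", "y", "z"])


def save_fixel_dir(path, field: FixelField) -> Path:
    """Write a fixel directory: index volume plus per-fixel tables.

    Mirrors the conventional on-disk layout: ``index.nii`` is
    (X, Y, Z, 2) with per-voxel count and offset into ``directions.csv``
    (N x 3 unit vectors) and ``afd.csv`` (N densities); the text tables
    use %.17g and round-trip float64 exactly.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    affine[:3, :3] *= field.voxel_size
    affine[:3, 3] = field.origin
    save_nifti(path / "index.nii", field.index.astype(np.int32), affine)
    # per-fixel tables as text (%.17g round-trips float64 exactly)
    pd.DataFrame(field.directions, columns=["x", "y", "z"]).to_csv(
        path / "directions.csv", index=False, float_format="%.17g")
    pd.DataFrame({"afd": field.afd}).to_csv(
        path / "afd.csv", index=False, float_format="%.17g")
    return path


def load_fixel_dir(path) -> FixelField:
    path = Path(path)
    index, affine = load_nifti(path / "index.nii")
    directions = pd.read_csv(path / "directions.csv",
                             float_precision="round_trip").to_numpy(float)
    afd = pd.read_csv(path / "afd.csv",
                      float_precision="round_trip")["afd"].to_numpy(float)
    return FixelField(
        index=np.asarray(index, np.int64),
        directions=directions.reshape(-1, 3),
        afd=afd,
        voxel_size=float(affine[0, 0]),
        origin=np.asarray(affine[:3, 3], float),
    )


def save_sessions_csv(path, sessions) -> Path:
    """Event-stream CSV: trial_id, modality, target_ms, epoch, event_type,
    onset_ms (plus subject and n_sync for exact reconstruction)."""
    rows = []
    for sess in sessions:
        for ti, t in enumerate(sess.trials):
            for o in t.stimulus_onsets:
                rows.append((sess.subject_id, ti, t.modality, t.target_ms,
                             "sync", "stimulus", o, t.n_sync))
            for k, o in enumerate(t.tap_onsets):
                epoch = "sync" if k <= t.n_sync else "cont"
                rows.append((sess.subject_id, ti, t.modality, t.target_ms,
                             epoch, "tap", o, t.n_sync))
    df = pd.DataFrame(rows, columns=["subject", "trial_id", "modality",
                                     "target_ms", "epoch", "event_type",
                                     "onset_ms", "n_sync"])
    df.to_csv(path, index=False, float_format="%.10g")
    return Path(path)


def load_sessions_csv(path):
    df = pd.read_csv(path)
    sessions = []
    for sid, sdf in df.groupby("subject", sort=True):
        sess = TappingSession(subject_id=int(sid))
        for tid, tdf in sdf.groupby("trial_id", sort=True):
            stim = np.sort(tdf.loc[tdf.event_type == "stimulus",
                                   "onset_ms"].to_numpy(float))
            taps = np.sort(tdf.loc[tdf.event_type == "tap",
                                   "onset_ms"].to_numpy(float))
            sess.trials.append(Trial(
                modality=str(tdf.modality.iloc[0]),
                target_ms=float(tdf.target_ms.iloc[0]),
                stimulus_onsets=stim,
                tap_onsets=taps,
                n_sync=int(tdf.n_sync.iloc[0]),
            ))
        sessions.append(sess)
    return sessions


def save_vertex_table(path, values: np.ndarray, columns) -> Path:
    """Per-vertex CSV keyed by vertex_id."""
    df = pd.DataFrame(np.atleast_2d(values.T).T, columns=list(columns))
    df.insert(0, "vertex_id", np.arange(len(df)))
    df.to_csv(path, index=False, float_format="%.10g")
    return Path(path)


def load_vertex_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
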
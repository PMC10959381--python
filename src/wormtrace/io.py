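"""Reading and writing recordings, tracks and ground truth.

Volumes travel as multi-page TIFF stacks (pages ordered t-major, then z);
tracks and ground truth as plain CSV so every stage can be resumed from
disk.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import GroundTruth, Recording, Spot, Track

TRACK_COLUMNS = ["track_id", "t", "x_um", "y_um", "z_um", "intensity", "source"]


def read_recording(
    path,
    voxel_size: tuple[float, float, float],
    n_z: int,
    frame_interval: float = 1.0,
) -> Recording:
    """Read a multi-page TIFF into a Recording.

    Pages are interpreted in acquisition order: ``n_z`` consecutive pages
    form one volume. The page count must be divisible by ``n_z``.
    """
    if n_z < 1:
        raise ValueError("n_z must be >= 1")
    pages = tifffile.imread(str(path))
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise ValueError(
            f"expected a stack of 2D pages in {path}; got array of shape {pages.shape}"
        )
    n_pages = pages.shape[0]
    if n_pages % n_z != 0:
        raise ValueError(
            f"page count {n_pages} not divisible by n_z={n_z}: "
            "cannot reshape into complete volumes"
        )
    frames = pages.reshape(n_pages // n_z, n_z, *pages.shape[1:])
    return Recording(frames=frames, voxel_size=voxel_size, frame_interval=frame_interval)


def write_recording(rec: Recording, path) -> None:
    """Write a Recording as a multi-page TIFF, t-major then z; inverse of
    :func:`read_recording`."""
    t, z, y, x = rec.frames.shape
    tifffile.imwrite(str(path), rec.frames.reshape(t * z, y, x))


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    rows = [
        (tr.track_id, s.t, s.position[0], s.position[1], s.position[2], s.intensity, s.source)
        for tr in tracks
        for s in tr.spots
    ]
    return pd.DataFrame(rows, columns=TRACK_COLUMNS)


def write_tracks(tracks: list[Track], path) -> None:
    tracks_to_frame(tracks).to_csv(path, index=False)


def read_tracks(path) -> list[Track]:
    df = pd.read_csv(path)
    out = []
    for tid, sub in df.groupby("track_id", sort=True):
        spots = [
            Spot(
                t=int(r.t),
                position=np.array([r.x_um, r.y_um, r.z_um]),
                intensity=float(r.intensity),
                source=str(r.source),
            )
            for r in sub.itertuples()
        ]
        out.append(Track(track_id=int(tid), spots=spots))
    return out


def write_ground_truth(truth: GroundTruth, path) -> None:
    truth.table.to_csv(path, index=False)


def read_ground_truth(path) -> GroundTruth:
    return GroundTruth(pd.read_csv(path))


def write_detections(spots_by_frame: list[list[Spot]], path) -> None:
    rows = [
        (s.t, s.position[0], s.position[1], s.position[2], s.intensity)
        for frame in spots_by_frame
        for s in frame
    ]
    pd.DataFrame(rows, columns=["t", "x_um", "y_um", "z_um", "intensity"]).to_csv(
        path, index=False
    )


def read_detections(path) -> list[list[Spot]]:
    df = pd.read_csv(path)
    n_frames = int(df["t"].max()) + 1 if len(df) else 0
    frames: list[list[Spot]] = [[] for _ in range(n_frames)]
    for r in df.itertuples():
        frames[int(r.t)].append(
            Spot(t=int(r.t), position=np.array([r.x_um, r.y_um, r.z_um]), intensity=float(r.intensity))
        )
    return frames


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
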
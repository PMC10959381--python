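"""Fluorescence trace extraction from tracked, segmented neurons.

Per frame, the ROI is the consolidated ellipsoid placed at the track's
position; the signal is the mean of the brightest 90% of ROI voxels
(voxels at or above the 10th intensity percentile), and a local background
— the mean of the 1-voxel-thick corona just outside the ROI — is
subtracted. Values may be negative and are not clamped; normalization
(e.g. dF/F) is left to downstream analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import Recording, Track
from .roi import RoiShape

log = logging.getLogger(__name__)


@dataclass
class Trace:
    """Per-frame fluorescence for one track."""

    track_id: int
    frames: np.ndarray  # frame indices covered
    values: np.ndarray  # raw background-subtracted signal
    smoothed: np.ndarray | None = None
    frames_inferred: np.ndarray | None = None  # True where position was inferred

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.frames.shape != self.values.shape:
            raise ValueError("frames and values must have equal length")
        if self.smoothed is not None and np.shape(self.smoothed) != self.values.shape:
            raise ValueError("smoothed must match values in length")
        if self.frames_inferred is None:
            self.frames_inferred = np.zeros(self.values.shape, dtype=bool)

    @property
    def series(self) -> np.ndarray:
        """Smoothed values when available, else raw."""
        return self.values if self.smoothed is None else self.smoothed


def extract_trace(rec: Recording, track: Track, shape: RoiShape) -> Trace:
    """Extract the background-corrected signal of one gap-free track."""
    if track.gaps:
        raise ValueError(
            f"track {track.track_id} has gaps {track.gaps}; fill them before extraction"
        )
    dx, dy, dz = rec.voxel_size
    nz, ny, nx = rec.shape_zyx
    pad = float(np.max(shape.semi_axes))
    values, inferred = [], []
    for s in track.spots:
        cx, cy, cz = s.position
        z0 = int(np.floor((cz - pad) / dz)) - 1
        z1 = int(np.ceil((cz + pad) / dz)) + 1
        y0 = int(np.floor((cy - pad) / dy)) - 1
        y1 = int(np.ceil((cy + pad) / dy)) + 1
        x0 = int(np.floor((cx - pad) / dx)) - 1
        x1 = int(np.ceil((cx + pad) / dx)) + 1
        z0c, y0c, x0c = max(0, z0), max(0, y0), max(0, x0)
        z1c, y1c, x1c = min(nz - 1, z1), min(ny - 1, y1), min(nx - 1, x1)
        if z1c < z0c or y1c < y0c or x1c < x0c:
            log.warning("track %d frame %d: ROI outside volume", track.track_id, s.t)
            values.append(np.nan)
            inferred.append(s.source != "detected")
            continue
        crop = rec.frames[s.t, z0c : z1c + 1, y0c : y1c + 1, x0c : x1c + 1]
        zz, yy, xx = np.indices(crop.shape)
        pts = np.column_stack([
            ((xx + x0c) * dx).ravel(), ((yy + y0c) * dy).ravel(), ((zz + z0c) * dz).ravel()
        ])
        placed = RoiShape(
            center=s.position, semi_axes=shape.semi_axes,
            orientation=shape.orientation, quality=shape.quality,
        )
        inside = placed.contains(pts).reshape(crop.shape)
        if not inside.any():
            # ellipsoid thinner than the grid: take the nearest voxel
            d2 = ((pts - s.position) ** 2).sum(axis=1).reshape(crop.shape)
            inside = d2 == d2.min()
        roi_vals = crop[inside].astype(float)
        cutoff = np.percentile(roi_vals, 10)
        signal = roi_vals[roi_vals >= cutoff].mean()
        corona = ndimage.binary_dilation(inside, structure=np.ones((3, 3, 3), bool)) & ~inside
        background = crop[corona].astype(float).mean() if corona.any() else 0.0
        values.append(signal - background)
        inferred.append(s.source != "detected")
    return Trace(
        track_id=track.track_id,
        frames=np.array(track.frames),
        values=np.array(values),
        frames_inferred=np.array(inferred, dtype=bool),
    )


def smooth_trace(trace: Trace, window: int = 5) -> Trace:
    """Centred moving average with the window shrinking at the edges;
    window must be odd, window=1 is the identity."""
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1; got {window}")
    h = window // 2
    v = trace.values
    smoothed = np.array([
        np.nanmean(v[max(0, i - h) : i + h + 1]) for i in range(len(v))
    ])
    return Trace(
        track_id=trace.track_id,
        frames=trace.frames.copy(),
        values=trace.values.copy(),
        smoothed=smoothed,
        frames_inferred=trace.frames_inferred.copy(),
    )


def extract_all_traces(
    rec: Recording, tracks: list[Track], shapes: dict[int, RoiShape], window: int = 5
) -> list[Trace]:
    return [
        smooth_trace(extract_trace(rec, tr, shapes[tr.track_id]), window=window)
        for tr in tracks
    ]


def traces_to_frame(traces: list[Trace]) -> pd.DataFrame:
    """Track x frame matrix of raw values (NaN outside a track's span)."""
    n_frames = max(int(tr.frames.max()) for tr in traces) + 1 if traces else 0
    data = {}
    for tr in traces:
        col = np.full(n_frames, np.nan)
        col[tr.frames] = tr.values
        data[tr.track_id] = col
    return pd.DataFrame(data)


def write_traces(traces: list[Trace], path) -> None:
    traces_to_frame(traces).to_csv(path, index_label="t")
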
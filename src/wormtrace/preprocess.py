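"""Pre-processing applied before blob detection.

Two steps: a per-frame background estimate taken from a dark crop of the
image, and a temporal denoising filter (a one-parameter recursive filter of
the kind usually called an "image Kalman filter" in microscopy, or a
3-frame running median for low-SNR light-sheet data).
"""

from __future__ import annotations

import logging

import numpy as np

from .core import Recording

log = logging.getLogger(__name__)


def find_dark_corner(rec: Recording, size: int = 32) -> tuple[int, int, int, int]:
    """Pick the (y0, y1, x0, x1) corner crop with the lowest mean in frame 0.

    Used as the default dark crop when none is configured.
    """
    _, _, ny, nx = rec.frames.shape
    sy, sx = min(size, ny), min(size, nx)
    corners = [
        (0, sy, 0, sx),
        (0, sy, nx - sx, nx),
        (ny - sy, ny, 0, sx),
        (ny - sy, ny, nx - sx, nx),
    ]
    means = [rec.frames[0][:, y0:y1, x0:x1].mean() for (y0, y1, x0, x1) in corners]
    return corners[int(np.argmin(means))]


def subtract_background(rec: Recording, dark_crop: tuple[int, int, int, int] | None = None) -> Recording:
    """Subtract a frame-specific scalar background.

    For each frame t the mean intensity of the dark crop (over all z planes
    of that frame) is subtracted from every voxel of the frame; negative
    results are clamped to 0 so detection sees non-negative intensities.

    Parameters
    ----------
    dark_crop : (y0, y1, x0, x1), half-open voxel box
        A region of the field of view containing no sample. Defaults to the
        32x32 corner with the lowest mean intensity in frame 0.
    """
    if dark_crop is None:
        dark_crop = find_dark_corner(rec)
    y0, y1, x0, x1 = (int(v) for v in dark_crop)
    _, _, ny, nx = rec.frames.shape
    if not (0 <= y0 < y1 <= ny and 0 <= x0 < x1 <= nx):
        raise ValueError(f"dark crop {dark_crop} outside image of shape (y={ny}, x={nx})")
    if (y1 - y0) * (x1 - x0) < 4:
        raise ValueError("dark crop must cover at least 4 voxels")
    frames = rec.frames.astype(np.float32, copy=True)
    b = frames[:, :, y0:y1, x0:x1].mean(axis=(1, 2, 3))
    frames -= b[:, None, None, None]
    np.clip(frames, 0, None, out=frames)
    return Recording(frames, rec.voxel_size, rec.frame_interval)


def temporal_denoise(rec: Recording, gain: float = 0.5, mode: str = "kalman") -> Recording:
    """Denoise along time, per voxel.

    ``kalman``: recursive filter est_t = est_{t-1} + gain * (obs_t - est_{t-1})
    with est_0 = obs_0; ``gain`` in (0, 1], gain=1 is the identity.
    ``median``: running median over a 3-frame window, shrinking at the edges.
    """
    if mode not in ("kalman", "median"):
        raise ValueError(f"unknown denoise mode {mode!r}")
    frames = rec.frames.astype(np.float32, copy=False)
    if mode == "kalman":
        if not 0 < gain <= 1:
            raise ValueError(f"gain must be in (0, 1]; got {gain}")
        if gain == 1.0:  # exact pass-through limit
            return Recording(frames.copy(), rec.voxel_size, rec.frame_interval)
        out = np.empty_like(frames, dtype=np.float32)
        out[0] = frames[0]
        for t in range(1, frames.shape[0]):
            out[t] = out[t - 1] + gain * (frames[t] - out[t - 1])
    else:
        T = frames.shape[0]
        out = np.empty_like(frames, dtype=np.float32)
        for t in range(T):
            lo, hi = max(0, t - 1), min(T, t + 2)
            out[t] = np.median(frames[lo:hi], axis=0)
    return Recording(out, rec.voxel_size, rec.frame_interval)
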
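"""Nucleus detection by 3D Laplacian-of-Gaussian filtering.

Each volume is convolved with a 3D LoG kernel built in physical units (so
the strongly anisotropic z spacing of plane-scanning stacks is handled),
the sign is flipped so bright blobs give positive peaks, and candidate
centres are the strict 26-connected local maxima of the response. A
candidate is kept when the element-wise product of the response and the
original image at that voxel exceeds a user threshold; the threshold, the
kernel size and the Gaussian sigma are the user-tunable detection
parameters, usually dialled in on a preview frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import Recording, Spot

log = logging.getLogger(__name__)

MERGE_RADIUS_UM = 1.5  # duplicate maxima closer than this are merged


@dataclass
class DetectionParams:
    """User-set detection parameters.

    filter_size : odd kernel support in voxels per axis (>= 3)
    sigma : Gaussian scale in micrometres (isotropic in physical units);
        for ~2 um nuclei a sigma of 1 um is the natural choice
    threshold : cutoff on the response x intensity product image
    """

    filter_size: int = 9
    sigma: float = 1.0
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.filter_size < 3 or self.filter_size % 2 == 0:
            raise ValueError(f"filter_size must be odd and >= 3; got {self.filter_size}")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")


def log_filter_3d(
    volume: np.ndarray,
    params: DetectionParams,
    voxel_size: tuple[float, float, float],
) -> np.ndarray:
    """Negated LoG response of one volume, same shape as the input.

    The Laplacian is the sum of physical-unit second derivatives, each
    computed as a Gaussian-derivative filter with per-axis sigma
    ``sigma_um / voxel_size_axis`` and support radius ``filter_size // 2``;
    boundaries are handled by reflection.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError("volume must be 3D (z, y, x)")
    if not np.all(np.isfinite(volume)):
        raise ValueError("volume contains non-finite values")
    dx, dy, dz = voxel_size
    if params.sigma < max(voxel_size) / 2:
        log.warning(
            "sigma %.3g um is under-resolved for voxel size %s", params.sigma, voxel_size
        )
    radius = params.filter_size // 2
    if volume.shape[0] < params.filter_size:
        log.warning(
            "z extent %d smaller than filter support %d; kernel truncated",
            volume.shape[0],
            params.filter_size,
        )
    sig_vox = (params.sigma / dz, params.sigma / dy, params.sigma / dx)
    spacing = (dz, dy, dx)
    vol = volume.astype(np.float32, copy=False)
    resp = np.zeros(volume.shape, dtype=np.float32)
    for axis in range(3):
        order = [0, 0, 0]
        order[axis] = 2
        d2 = ndimage.gaussian_filter(
            vol, sigma=sig_vox, order=order, mode="reflect", radius=radius
        )
        resp += d2 / spacing[axis] ** 2
    return -resp


def detect_spots(
    volume: np.ndarray,
    params: DetectionParams,
    voxel_size: tuple[float, float, float],
    t: int = 0,
) -> list[Spot]:
    """Detect nuclei in one volume.

    Strict local maxima of the LoG response over the 26-connected
    neighbourhood are kept when ``response * intensity`` at the maximum
    voxel exceeds ``params.threshold``; surviving maxima closer than 1.5 um
    are merged keeping the brighter. Spots are returned sorted by
    descending product intensity, positions at voxel centres in um.
    """
    response = log_filter_3d(volume, params, voxel_size)
    footprint = np.ones((3, 3, 3), dtype=bool)
    footprint[1, 1, 1] = False
    neigh_max = ndimage.maximum_filter(
        response, footprint=footprint, mode="constant", cval=-np.inf
    )
    maxima = response > neigh_max
    product = response * np.asarray(volume, dtype=np.float32)
    keep = maxima & (product > params.threshold)
    zz, yy, xx = np.nonzero(keep)
    if zz.size == 0:
        return []
    dx, dy, dz = voxel_size
    order = np.argsort(product[zz, yy, xx])[::-1]
    spots: list[Spot] = []
    kept_pos: list[np.ndarray] = []
    for i in order:
        pos = np.array([xx[i] * dx, yy[i] * dy, zz[i] * dz])
        if kept_pos and np.min(np.linalg.norm(np.array(kept_pos) - pos, axis=1)) < MERGE_RADIUS_UM:
            continue  # duplicate of a brighter maximum
        kept_pos.append(pos)
        spots.append(Spot(t=t, position=pos, intensity=float(product[zz[i], yy[i], xx[i]])))
    return spots


def threshold_from_reference(
    volume: np.ndarray,
    positions: np.ndarray,
    params: DetectionParams,
    voxel_size: tuple[float, float, float],
    fraction: float = 0.5,
) -> float:
    """Set the product threshold from reference nucleus positions.

    Mirrors the human-in-the-loop tuning on a preview frame: the response
    x intensity product is read at each annotated centre and the threshold
    is placed at ``fraction`` of the dimmest one, so all annotated nuclei
    pass with headroom.
    """
    response = log_filter_3d(volume, params, voxel_size)
    dx, dy, dz = voxel_size
    prods = []
    for p in np.atleast_2d(positions):
        iz = int(round(p[2] / dz))
        iy = int(round(p[1] / dy))
        ix = int(round(p[0] / dx))
        prods.append(response[iz, iy, ix] * volume[iz, iy, ix])
    return float(fraction * min(prods))


def detect_all_frames(
    rec: Recording, params: DetectionParams
) -> list[list[Spot]]:
    """Run :func:`detect_spots` on every volume of a recording."""
    return [
        detect_spots(rec.volume(t), params, rec.voxel_size, t=t)
        for t in range(rec.n_frames)
    ]


def preview_detection(
    rec: Recording, t: int, params: DetectionParams, out_path=None
):
    """Maximum-intensity projection of frame ``t`` with detected centres.

    Returns the detections; writes a PNG overlay if ``out_path`` is given.
    Intended for interactive threshold tuning.
    """
    if not 0 <= t < rec.n_frames:
        raise IndexError(f"frame {t} out of range [0, {rec.n_frames})")
    spots = detect_spots(rec.volume(t), params, rec.voxel_size, t=t)
    if out_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        dx, dy, _ = rec.voxel_size
        mip = rec.volume(t).max(axis=0)
        fig, ax = plt.subplots(figsize=(8, 8 * mip.shape[0] / max(1, mip.shape[1])))
        ax.imshow(mip, cmap="gray", interpolation="nearest")
        if spots:
            xs = [s.position[0] / dx for s in spots]
            ys = [s.position[1] / dy for s in spots]
            ax.scatter(xs, ys, s=40, facecolors="none", edgecolors="r", linewidths=0.8)
        ax.set_axis_off()
        fig.savefig(out_path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return spots
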
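"""Core domain types shared by every pipeline stage.

Conventions
-----------
* Image grids are stored ``(t, z, y, x)``, 0-based, matching the page order
  of the multi-page TIFF stacks produced by plane-scanning acquisitions.
* Physical positions are reported ``(x, y, z)`` in micrometres with
  ``x = column_index * dx``; voxel anisotropy (z plane spacing is typically
  an order of magnitude coarser than the in-plane pixel size) is therefore
  absorbed once, here, and all downstream geometry works in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SPOT_SOURCES = ("detected", "inferred", "manual")


@dataclass
class Recording:
    """A 4D fluorescence recording: T volumes of (z, y, x) intensities.

    Parameters
    ----------
    frames : ndarray, shape (t, z, y, x)
        Non-negative intensities.
    voxel_size : (dx, dy, dz)
        Micrometres per voxel along x, y and z.
    frame_interval : float
        Seconds per volume.
    """

    frames: np.ndarray
    voxel_size: tuple[float, float, float]
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4:
            raise ValueError(
                f"frames must be 4D (t, z, y, x); got shape {self.frames.shape}"
            )
        if min(self.frames.shape) < 1:
            raise ValueError(f"all dimensions must be >= 1; got {self.frames.shape}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be positive; got {self.voxel_size}")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.frames.shape[1:]

    def physical_extent(self) -> np.ndarray:
        """Upper bound of voxel-centre coordinates, (x, y, z) in um."""
        nz, ny, nx = self.shape_zyx
        dx, dy, dz = self.voxel_size
        return np.array([(nx - 1) * dx, (ny - 1) * dy, (nz - 1) * dz])

    def volume(self, t: int) -> np.ndarray:
        if not 0 <= t < self.n_frames:
            raise IndexError(f"frame {t} out of range [0, {self.n_frames})")
        return self.frames[t]


@dataclass
class Spot:
    """One nucleus centre at one time point, in physical coordinates."""

    t: int
    position: np.ndarray  # (x, y, z) um
    intensity: float = 0.0
    source: str = "detected"

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be an (x, y, z) triple")
        if self.source not in SPOT_SOURCES:
            raise ValueError(f"source must be one of {SPOT_SOURCES}")
        if self.source == "detected" and self.intensity < 0:
            raise ValueError("detected spots must have non-negative intensity")


@dataclass
class Track:
    """Time-ordered spot sequence for one putative neuron."""

    track_id: int
    spots: list[Spot] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.spots = sorted(self.spots, key=lambda s: s.t)
        ts = [s.t for s in self.spots]
        if len(set(ts)) != len(ts):
            raise ValueError("a track may hold at most one spot per frame")

    @property
    def frames(self) -> list[int]:
        return [s.t for s in self.spots]

    @property
    def start_t(self) -> int:
        return self.spots[0].t

    @property
    def end_t(self) -> int:
        return self.spots[-1].t

    @property
    def gaps(self) -> list[tuple[int, int]]:
        """Inclusive frame ranges inside the span with no spot."""
        out: list[tuple[int, int]] = []
        have = set(self.frames)
        run = None
        for t in range(self.start_t, self.end_t + 1):
            if t not in have:
                run = (run[0], t) if run else (t, t)
            elif run:
                out.append(run)
                run = None
        return out

    def spot_at(self, t: int) -> Spot | None:
        for s in self.spots:
            if s.t == t:
                return s
        return None

    def position_at(self, t: int) -> np.ndarray | None:
        s = self.spot_at(t)
        return None if s is None else s.position

    def mean_position(self) -> np.ndarray:
        return np.mean([s.position for s in self.spots], axis=0)

    def add(self, spot: Spot) -> None:
        if self.spot_at(spot.t) is not None:
            raise ValueError(f"track {self.track_id} already has a spot at t={spot.t}")
        self.spots.append(spot)
        self.spots.sort(key=lambda s: s.t)


class GroundTruth:
    """Per-frame table of true neuron positions and intensities.

    Backed by a DataFrame with columns
    ``neuron_id, t, x_um, y_um, z_um, intensity``; neuron ids are stable
    across frames.
    """

    COLUMNS = ["neuron_id", "t", "x_um", "y_um", "z_um", "intensity"]

    def __init__(self, table: pd.DataFrame):
        missing = set(self.COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"ground-truth table missing columns {sorted(missing)}")
        self.table = table[self.COLUMNS].sort_values(["t", "neuron_id"]).reset_index(drop=True)

    @property
    def neuron_ids(self) -> np.ndarray:
        return np.unique(self.table["neuron_id"].to_numpy())

    @property
    def n_frames(self) -> int:
        return int(self.table["t"].max()) + 1

    def frame(self, t: int) -> tuple[np.ndarray, np.ndarray]:
        """Return (neuron_ids, positions (n, 3) um) for one frame."""
        sub = self.table[self.table["t"] == t]
        ids = sub["neuron_id"].to_numpy()
        pos = sub[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
        return ids, pos

    def positions_of(self, neuron_id) -> pd.DataFrame:
        return self.table[self.table["neuron_id"] == neuron_id].set_index("t")
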
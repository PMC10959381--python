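"""Ground-truth synthetic recordings.

The generator emulates the statistical structure the pipeline assumes:
~100 Gaussian nuclei (soma ~2 um) packed in an elongated head-like region,
slow rigid drift plus per-neuron elastic jitter (relative displacements of
order 2 um over 100 s), calcium-like intensity dynamics with two
anti-correlated neuron groups (backward- and forward-promoting), per-frame
detection dropout, and multiplicative (speckle) noise of variance sigma^2.
Every draw is reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import default_atlas, SEED_CLASSES
from .core import GroundTruth, Recording, Spot, Track
from .traces import Trace

GROUPS = ("backward", "forward", "other")


@dataclass
class SimConfig:
    """Study conditions for one synthetic recording.

    Defaults follow the regime the pipeline is designed for: a
    165 x 440 x 12 voxel head volume at (0.27, 0.27, 2.0) um voxels,
    ~100 nuclei of ~2 um (Gaussian sigma 1 um), drift + elastic jitter
    accumulating to ~1-2 um relative displacement per 100 s, and a 10%
    per-frame chance that a neuron's brightness falls below the detection
    threshold.
    """

    n_neurons: int = 100
    volume_shape: tuple[int, int, int] = (12, 165, 440)  # (z, y, x) voxels
    voxel_size: tuple[float, float, float] = (0.27, 0.27, 2.0)  # (dx, dy, dz) um
    n_frames: int = 200
    frame_interval: float = 1 / 3  # s/volume (3 volumes per second)
    soma_sigma: float = 1.0  # um; renders ~2 um nuclei
    drift_per_frame: tuple[float, float, float] = (0.015, 0.008, 0.004)  # um (x, y, z)
    elastic_jitter_sd: float = 0.05  # um/frame random-walk step per neuron
    dropout_prob: float = 0.1
    dropout_scale: float = 0.05  # dropped frames keep this fraction of brightness
    group_fractions: tuple[float, float] = (0.1, 0.1)  # backward, forward
    noise_variance: float = 0.0  # sigma^2 of multiplicative noise (0 = clean)
    seed: int = 0
    # placement / rendering
    min_separation: float = 4.0  # um between placed nuclei
    baseline_intensity: float = 2.0
    seed_scale_um: float = 20.0  # physical scale of the planted seed-six template
    # activity model
    activity_base: float = 40.0
    activity_amp: float = 60.0
    activity_noise_sd: float = 3.0  # forward / other groups
    backward_noise_sd: float = 1.0  # backward group is the most coherent

    def __post_init__(self) -> None:
        if self.n_neurons < 1 or self.n_frames < 1:
            raise ValueError("n_neurons and n_frames must be >= 1")
        if sum(self.group_fractions) > 1 + 1e-9:
            raise ValueError("group fractions must sum to <= 1")
        if min(self.group_fractions) < 0:
            raise ValueError("group fractions must be >= 0")
        for name in ("elastic_jitter_sd", "dropout_prob", "noise_variance",
                     "activity_noise_sd", "backward_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        margin = 3 * self.soma_sigma
        nz, ny, nx = self.volume_shape
        dx, dy, dz = self.voxel_size
        if (nx - 1) * dx <= 2 * margin or (ny - 1) * dy <= 2 * margin or (nz - 1) * dz <= 2 * margin:
            raise ValueError(
                "volume too small to hold placements with a 3*soma_sigma margin"
            )

    def group_labels(self) -> list[str]:
        nb = int(round(self.group_fractions[0] * self.n_neurons))
        nf = int(round(self.group_fractions[1] * self.n_neurons))
        labels = ["backward"] * nb + ["forward"] * nf
        labels += ["other"] * (self.n_neurons - len(labels))
        return labels[: self.n_neurons]


@dataclass
class ActivityModel:
    """True per-neuron brightness series and activity-group labels.

    The backward group shares one slow latent rise/decay signal, the
    forward group the negated latent, others are independent; pairwise
    within-backward correlation is ~1 and backward-vs-forward ~-1.
    """

    brightness: np.ndarray  # (n_neurons, n_frames)
    groups: list[str]
    latent: np.ndarray = field(default=None)  # (n_frames,)


def _latent_signal(n_frames: int, rng: np.random.Generator,
                   tau: float = 5.0, switch_mean: float = 20.0) -> np.ndarray:
    """Saturating exponential rise/decay segments alternating at random
    intervals — the slow, GCaMP6-like waveform whose exact shape is
    irrelevant downstream; only its correlation structure matters."""
    s, target = 0.0, 1.0
    next_switch = 0
    alpha = 1.0 - np.exp(-1.0 / tau)
    out = np.empty(n_frames)
    for t in range(n_frames):
        if t >= next_switch:
            target = 1.0 - target
            next_switch = t + max(3, int(rng.exponential(switch_mean)))
        s += (target - s) * alpha
        out[t] = s
    return out


def simulate_activity(cfg: SimConfig, rng: np.random.Generator | None = None) -> ActivityModel:
    """Draw the true brightness series for every neuron."""
    if cfg.n_frames < 2:
        raise ValueError("need at least 2 frames for activity simulation")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    groups = cfg.group_labels()
    latent = _latent_signal(cfg.n_frames, rng)
    brightness = np.empty((cfg.n_neurons, cfg.n_frames))
    n_backward_seen = 0
    for i, g in enumerate(groups):
        if g == "backward":
            # the first six backward neurons are the command-interneuron
            # core (AVA/AVE/AIB analogues): they share the latent tightly,
            # while later backward cells follow it more loosely — the
            # coherence hierarchy the seed search relies on
            if n_backward_seen < 6 or cfg.activity_noise_sd == 0:
                sig = latent
            else:
                sig = 0.85 * latent + 0.15 * _latent_signal(cfg.n_frames, rng)
            sd = cfg.backward_noise_sd
            n_backward_seen += 1
        elif g == "forward":
            sig, sd = 1.0 - latent, cfg.activity_noise_sd
        else:
            sig, sd = _latent_signal(cfg.n_frames, rng), cfg.activity_noise_sd
        b = cfg.activity_base + cfg.activity_amp * sig
        if sd > 0:
            b = b + rng.normal(0.0, sd, size=cfg.n_frames)
        brightness[i] = np.maximum(b, 1.0)  # brightness stays >= baseline > 0
    return ActivityModel(brightness=brightness, groups=groups, latent=latent)


def _place_neurons(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Initial (n, 3) positions in um, elongated along x, with the two
    bilateral backward triplets planted roughly collinear along that axis."""
    nz, ny, nx = cfg.volume_shape
    dx, dy, dz = cfg.voxel_size
    margin = 3 * cfg.soma_sigma
    lo = np.array([margin] * 3)
    hi = np.array([(nx - 1) * dx - margin, (ny - 1) * dy - margin, (nz - 1) * dz - margin])
    centre = (lo + hi) / 2

    groups = cfg.group_labels()
    n_backward = groups.count("backward")
    positions: list[np.ndarray] = []
    if n_backward >= 6:
        atlas = {a.class_name: a.position for a in default_atlas()}
        for cls in SEED_CLASSES:
            p = centre + atlas[cls] * cfg.seed_scale_um
            positions.append(np.clip(p, lo, hi))

    # remaining neurons: anisotropic head-like spread, dominant axis = x
    span = hi - lo
    attempts = 0
    while len(positions) < cfg.n_neurons:
        u = rng.uniform(-1, 1, size=3) * np.array([0.5, 0.35, 0.5])
        cand = centre + u * span
        cand = np.clip(cand, lo, hi)
        ok = True
        if positions:
            d = np.linalg.norm(np.asarray(positions) - cand, axis=1)
            ok = d.min() >= cfg.min_separation
        if ok:
            positions.append(cand)
            attempts = 0
        else:
            attempts += 1
            if attempts > 5000:
                raise RuntimeError(
                    f"could not place {cfg.n_neurons} neurons at >= "
                    f"{cfg.min_separation} um separation; reduce density"
                )
    pos = np.asarray(positions)
    d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    if d.min() < 2.0:
        raise RuntimeError("placed neurons closer than 2 um are unresolvable")
    return pos


def _trajectories(cfg: SimConfig, pos0: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """(T, n, 3) positions: initial + cumulative drift + per-neuron
    random-walk elastic jitter."""
    T, n = cfg.n_frames, cfg.n_neurons
    drift = np.arange(T)[:, None] * np.asarray(cfg.drift_per_frame)[None, :]
    traj = pos0[None, :, :] + drift[:, None, :]
    if cfg.elastic_jitter_sd > 0:
        steps = rng.normal(0.0, cfg.elastic_jitter_sd, size=(T, n, 3))
        steps[0] = 0.0
        traj = traj + np.cumsum(steps, axis=0)
    return traj


def render_volume(
    positions: np.ndarray,
    amplitudes: np.ndarray,
    shape_zyx: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
    soma_sigma: float,
    baseline: float = 0.0,
) -> np.ndarray:
    """Render Gaussian nuclei into one (z, y, x) volume.

    Each nucleus is a separable 3D Gaussian of physical sigma
    ``soma_sigma`` with peak value ``amplitudes[i]`` at ``positions[i]``.
    """
    nz, ny, nx = shape_zyx
    dx, dy, dz = voxel_size
    vol = np.full(shape_zyx, baseline, dtype=np.float32)
    r = 3.0 * soma_sigma
    for p, a in zip(positions, amplitudes):
        px, py, pz = p
        z0, z1 = max(0, int(np.floor((pz - r) / dz))), min(nz - 1, int(np.ceil((pz + r) / dz)))
        y0, y1 = max(0, int(np.floor((py - r) / dy))), min(ny - 1, int(np.ceil((py + r) / dy)))
        x0, x1 = max(0, int(np.floor((px - r) / dx))), min(nx - 1, int(np.ceil((px + r) / dx)))
        if z1 < z0 or y1 < y0 or x1 < x0:
            continue
        gz = np.exp(-((np.arange(z0, z1 + 1) * dz - pz) ** 2) / (2 * soma_sigma**2))
        gy = np.exp(-((np.arange(y0, y1 + 1) * dy - py) ** 2) / (2 * soma_sigma**2))
        gx = np.exp(-((np.arange(x0, x1 + 1) * dx - px) ** 2) / (2 * soma_sigma**2))
        vol[z0 : z1 + 1, y0 : y1 + 1, x0 : x1 + 1] += (
            a * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
        ).astype(np.float32)
    return vol


def simulate_recording(cfg: SimConfig) -> tuple[Recording, GroundTruth, ActivityModel]:
    """Generate a recording together with its ground truth.

    Returns the rendered (optionally noisy) Recording, a GroundTruth table
    of per-frame true positions and rendered amplitudes, and the
    ActivityModel holding the underlying brightness series.
    """
    ss = np.random.SeedSequence([cfg.seed, 0])
    rng_place, rng_motion, rng_drop = (np.random.default_rng(s) for s in ss.spawn(3))
    activity = simulate_activity(cfg)
    pos0 = _place_neurons(cfg, rng_place)
    traj = _trajectories(cfg, pos0, rng_motion)

    dropped = rng_drop.random((cfg.n_frames, cfg.n_neurons)) < cfg.dropout_prob
    frames = np.empty((cfg.n_frames, *cfg.volume_shape), dtype=np.float32)
    rows = []
    for t in range(cfg.n_frames):
        amp = activity.brightness[:, t].copy()
        amp[dropped[t]] *= cfg.dropout_scale
        frames[t] = render_volume(
            traj[t], amp, cfg.volume_shape, cfg.voxel_size, cfg.soma_sigma,
            baseline=cfg.baseline_intensity,
        )
        for i in range(cfg.n_neurons):
            rows.append((i, t, traj[t, i, 0], traj[t, i, 1], traj[t, i, 2], amp[i]))

    rec = Recording(frames, cfg.voxel_size, cfg.frame_interval)
    if cfg.noise_variance > 0:
        rec = add_multiplicative_noise(rec, cfg.noise_variance, seed=cfg.seed + 7)
    truth = GroundTruth(pd.DataFrame(rows, columns=GroundTruth.COLUMNS))
    return rec, truth, activity


def add_multiplicative_noise(rec: Recording, variance: float, seed: int) -> Recording:
    """Speckle noise: I' = I * (1 + n), n ~ N(0, sigma^2) i.i.d. per voxel,
    clamped at 0."""
    if variance < 0:
        raise ValueError("variance must be >= 0")
    if variance == 0:
        return Recording(rec.frames.copy(), rec.voxel_size, rec.frame_interval)
    rng = np.random.default_rng(seed)
    out = np.empty_like(rec.frames, dtype=np.float32)
    for t in range(rec.n_frames):  # per-frame chunks keep memory flat
        n = rng.normal(0.0, np.sqrt(variance), size=rec.frames[t].shape)
        out[t] = np.maximum(rec.frames[t] * (1.0 + n), 0.0)
    return Recording(out, rec.voxel_size, rec.frame_interval)


def truth_tracks(truth: GroundTruth) -> list[Track]:
    """Ground truth re-expressed as Track objects (one per neuron)."""
    out = []
    for nid in truth.neuron_ids:
        sub = truth.positions_of(nid)
        spots = [
            Spot(t=int(t), position=np.array([r.x_um, r.y_um, r.z_um]), intensity=float(r.intensity))
            for t, r in sub.iterrows()
        ]
        out.append(Track(track_id=int(nid), spots=spots))
    return out


# ---------------------------------------------------------------------------
# trace-level identification scenes


@dataclass
class IdentificationScene:
    """A synthetic head generated from the shipped atlas, at trace level.

    One track per atlas class, placed at the atlas position mapped through
    a random rigid rotation + translation + uniform scale plus Gaussian
    placement noise, with group-consistent activity. Used to exercise the
    seed search, body-frame construction and atlas assignment without
    rendering images.
    """

    tracks: list[Track]
    traces: list[Trace]
    true_labels: dict[int, str]
    head_direction: np.ndarray
    groups: dict[int, str]
    rotation: np.ndarray
    scale: float
    origin: np.ndarray


def simulate_identification_scene(
    seed: int,
    scale_um: float = 25.0,
    position_noise: float = 0.1,  # normalized atlas units
    n_frames: int = 300,
    activity_noise_sd: float = 3.0,
    backward_noise_sd: float = 1.0,
) -> IdentificationScene:
    from scipy.spatial.transform import Rotation

    atlas = default_atlas()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    R = Rotation.random(random_state=rng).as_matrix()
    trans = rng.uniform(40.0, 120.0, size=3)

    cfg = SimConfig(
        n_neurons=len(atlas), n_frames=n_frames, seed=seed,
        activity_noise_sd=activity_noise_sd, backward_noise_sd=backward_noise_sd,
    )
    order = {"backward": 0, "forward": 1, "other": 2}
    neurons = sorted(atlas, key=lambda a: order[a.group])  # groups match cfg labels
    nb = sum(a.group == "backward" for a in neurons)
    nf = sum(a.group == "forward" for a in neurons)
    cfg = SimConfig(
        n_neurons=len(neurons), n_frames=n_frames, seed=seed,
        group_fractions=(nb / len(neurons), nf / len(neurons)),
        activity_noise_sd=activity_noise_sd, backward_noise_sd=backward_noise_sd,
    )
    activity = simulate_activity(cfg, rng=np.random.default_rng(np.random.SeedSequence([seed, 12])))

    tracks, traces, labels, groups = [], [], {}, {}
    for i, a in enumerate(neurons):
        noisy = a.position + rng.normal(0.0, position_noise, size=3)
        p = R @ (noisy * scale_um) + trans
        spots = [Spot(t=t, position=p, intensity=float(activity.brightness[i, t])) for t in range(n_frames)]
        tracks.append(Track(track_id=i, spots=spots))
        traces.append(
            Trace(
                track_id=i,
                frames=np.arange(n_frames),
                values=activity.brightness[i].copy(),
            )
        )
        labels[i] = a.class_name
        groups[i] = a.group
    head_direction = R @ np.array([1.0, 0.0, 0.0])
    return IdentificationScene(
        tracks=tracks, traces=traces, true_labels=labels,
        head_direction=head_direction, groups=groups, rotation=R,
        scale=scale_um, origin=trans,
    )
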
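"""Correlation- and atlas-based neuron identity assignment.

The head of a constrained worm shows two dominant, mutually anti-correlated
activity groups (backward- vs forward-locomotion promoting). Identification
exploits this: it first finds the "seed six" — two roughly collinear,
bilateral triplets of highly correlated tracks (the AVA/AVE/AIB candidates)
arranged along the axis of largest spatial spread — then anchors a body
coordinate frame on them (x anterior, y dorsal, z left, scaled by the
seed-six mean pairwise distance), and finally assigns atlas classes to
tracks as a linear assignment problem whose cost combines normalized
position distance with an activity-group penalty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from ._lap import solve_assignment
from .atlas import AtlasNeuron, default_atlas
from .traces import Trace

log = logging.getLogger(__name__)


@dataclass
class CorrelationStats:
    """Pairwise Pearson correlations over traces and their summary.

    ``c_mu`` and ``c_sigma`` are the mean and standard deviation of the
    strict upper triangle of C (all off-diagonal pairs).
    """

    track_ids: list[int]
    C: np.ndarray
    c_mu: float
    c_sigma: float
    _index: dict[int, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        n = len(self.track_ids)
        if self.C.shape != (n, n):
            raise ValueError("C must be square over track_ids")
        self._index = {tid: i for i, tid in enumerate(self.track_ids)}

    def corr(self, a: int, b: int) -> float:
        return float(self.C[self._index[a], self._index[b]])

    def row(self, tid: int) -> np.ndarray:
        return self.C[self._index[tid]]


def correlation_stats(traces: list[Trace]) -> CorrelationStats:
    """Pearson correlations of (smoothed) traces, pairwise-complete over
    shared frames; constant traces get zero correlations."""
    if len(traces) < 3:
        raise ValueError("need at least 3 traces")
    for tr in traces:
        if len(tr.frames) < 10:
            raise ValueError(f"trace {tr.track_id} has fewer than 10 frames")
    n_frames = max(int(tr.frames.max()) for tr in traces) + 1
    data = {}
    for tr in traces:
        col = np.full(n_frames, np.nan)
        col[tr.frames] = tr.series
        data[tr.track_id] = col
    df = pd.DataFrame(data)
    C = df.corr(min_periods=3).to_numpy()
    bad = np.isnan(C)
    if bad.any():
        log.warning("constant or non-overlapping traces; setting %d correlations to 0",
                    int(bad.sum()))
        C[bad] = 0.0
    np.fill_diagonal(C, 1.0)
    iu = np.triu_indices_from(C, k=1)
    return CorrelationStats(
        track_ids=list(df.columns), C=C,
        c_mu=float(C[iu].mean()), c_sigma=float(C[iu].std()),
    )


def _principal_axis(points: np.ndarray) -> np.ndarray:
    centred = points - points.mean(axis=0)
    _, _, Vt = np.linalg.svd(centred, full_matrices=False)
    return Vt[0]


def _triplet_geometry(pts: np.ndarray, axis: np.ndarray,
                      collinearity_tol: float, cos_min: float) -> bool:
    c = pts.mean(axis=0)
    M = pts - c
    _, _, Vt = np.linalg.svd(M, full_matrices=False)
    direction = Vt[0]
    proj = M @ direction
    perp = np.linalg.norm(M - proj[:, None] * direction, axis=1)
    length = proj.max() - proj.min()
    if length <= 0:
        return False
    if perp.max() / length > collinearity_tol:
        return False
    return abs(float(direction @ axis)) >= cos_min


def _pairing_mismatch(ptsA: np.ndarray, ptsB: np.ndarray, axis: np.ndarray) -> float:
    """Bilateral-symmetry score: sorted by projection on the dominant
    axis, the two triplets should line up pairwise (left/right partners of
    the same classes sit at matching anteroposterior stations). Returns
    the mean pairwise projection mismatch relative to triplet length;
    ~0 for clean bilateral pairs."""
    projA = np.sort(ptsA @ axis)
    projB = np.sort(ptsB @ axis)
    length = max(projA[-1] - projA[0], projB[-1] - projB[0])
    if length <= 0:
        return np.inf
    return float(np.mean(np.abs(projA - projB))) / length


def find_seed_six(
    stats: CorrelationStats,
    positions: dict[int, np.ndarray],
    collinearity_tol: float = 0.15,
    axis_angle_tol_deg: float = 30.0,
    pool_size: int = 12,
    pairing_tol: float = 0.3,
    corr_margin: float = 0.002,
) -> tuple[list[int], tuple[list[int], list[int]]]:
    """Find the two bilateral, roughly collinear high-correlation triplets.

    The search pool is limited to the ``pool_size`` tracks with the highest
    correlation scores. Within it, a 6-subset is valid when it splits into
    two triplets that are each roughly collinear, aligned with the dominant
    spatial axis, and arranged as matching bilateral pairs along it. Among
    valid subsets, the one with the highest mean pairwise correlation wins
    (the command-interneuron core is the most coherent set in the head);
    statistically indistinguishable near-ties (within ``corr_margin``) are
    broken by the lowest bilateral pairing mismatch, then by compactness —
    the seed classes sit close together.
    """
    ids = [tid for tid in stats.track_ids if tid in positions]
    if len(ids) < 6:
        raise ValueError(f"need at least 6 tracks with positions; got {len(ids)}")
    P = np.array([positions[tid] for tid in ids])
    axis = _principal_axis(P)
    cos_min = np.cos(np.deg2rad(axis_angle_tol_deg))

    # correlation score: mean of a track's 5 strongest partners
    scores = []
    for tid in ids:
        row = np.delete(stats.row(tid), stats._index[tid])
        scores.append(np.sort(row)[::-1][:5].mean())
    pool = [ids[i] for i in np.argsort(scores)[::-1][:pool_size]]

    idx = {tid: stats._index[tid] for tid in pool}
    subsets = []
    for sub in combinations(pool, 6):
        pairs = [stats.C[idx[a], idx[b]] for a, b in combinations(sub, 2)]
        subsets.append((float(np.mean(pairs)), sub))
    subsets.sort(key=lambda s: -s[0])

    valid = []  # (corr, mismatch, extent, sub, split)
    for corr, sub in subsets:
        pts = {tid: positions[tid] for tid in sub}
        best_split, best_mismatch = None, np.inf
        for tripA in combinations(sub, 3):
            tripB = tuple(t for t in sub if t not in tripA)
            if tripA > tripB:
                continue  # unordered split
            ptsA = np.array([pts[t] for t in tripA])
            ptsB = np.array([pts[t] for t in tripB])
            if not (
                _triplet_geometry(ptsA, axis, collinearity_tol, cos_min)
                and _triplet_geometry(ptsB, axis, collinearity_tol, cos_min)
            ):
                continue
            mismatch = _pairing_mismatch(ptsA, ptsB, axis)
            if mismatch <= pairing_tol and mismatch < best_mismatch:
                best_split, best_mismatch = (list(tripA), list(tripB)), mismatch
        if best_split is not None:
            pset = np.array([pts[t] for t in sub])
            extent = float(np.mean([
                np.linalg.norm(a - b) for a, b in combinations(pset, 2)
            ]))
            valid.append((corr, best_mismatch, extent, sub, best_split))
    if not valid:
        raise RuntimeError(
            "no 6-subset of correlated tracks forms two collinear bilateral "
            "triplets along the dominant axis; seed the identification manually"
        )
    best_corr = max(v[0] for v in valid)
    near_best = [v for v in valid if v[0] >= best_corr - corr_margin]
    corr, mismatch, extent, sub, split = min(near_best, key=lambda v: (v[1], v[2], -v[0]))
    return list(sub), split


@dataclass
class BodyFrame:
    """Worm body coordinate frame: x anterior, y dorsal, z left.

    ``axes`` rows are the (anterior, dorsal, left) unit vectors; positions
    map to normalized coordinates via (p - origin) @ axes.T / scale.
    """

    origin: np.ndarray
    axes: np.ndarray  # (3, 3), rows = anterior, dorsal, left
    scale: float

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if np.linalg.norm(self.axes @ self.axes.T - np.eye(3)) > 1e-6:
            raise ValueError("axes must be orthonormal")

    def normalize(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.origin) @ self.axes.T / self.scale


def build_body_frame(
    seed_positions: np.ndarray,
    head_direction: np.ndarray,
    all_positions: np.ndarray,
) -> BodyFrame:
    """Anchor the body frame on the seed six.

    Anterior = dominant spatial axis signed along the user-supplied head
    direction; dorsal = normal of the least-squares plane through the six
    seeds, signed toward the side holding the majority of all neurons;
    left completes the right-handed (anterior, dorsal, left) triad. The
    origin is the seed centroid and the scale their mean pairwise distance.
    """
    seed_positions = np.asarray(seed_positions, dtype=float)
    all_positions = np.asarray(all_positions, dtype=float)
    head_direction = np.asarray(head_direction, dtype=float)
    if seed_positions.shape != (6, 3):
        raise ValueError("seed_positions must be (6, 3)")
    hnorm = np.linalg.norm(head_direction)
    if hnorm == 0:
        raise ValueError("head_direction must be nonzero")
    head_direction = head_direction / hnorm

    anterior = _principal_axis(all_positions)
    cos = float(anterior @ head_direction)
    if abs(cos) < np.cos(np.deg2rad(80.0)):
        raise ValueError(
            "head direction is within 10 degrees of orthogonal to the dominant "
            "axis; re-specify it"
        )
    if cos < 0:
        anterior = -anterior

    origin = seed_positions.mean(axis=0)
    centred = seed_positions - origin
    _, _, Vt = np.linalg.svd(centred, full_matrices=False)
    normal = Vt[-1]
    normal = normal - (normal @ anterior) * anterior
    nn = np.linalg.norm(normal)
    if nn < 1e-12:
        raise ValueError("degenerate seed plane; cannot determine the dorsal axis")
    normal /= nn
    side = np.sign((all_positions - origin) @ normal)
    dorsal = normal if (side > 0).sum() >= (side < 0).sum() else -normal
    left = np.cross(anterior, dorsal)
    scale = float(np.mean([np.linalg.norm(a - b) for a, b in combinations(seed_positions, 2)]))
    return BodyFrame(origin=origin, axes=np.vstack([anterior, dorsal, left]), scale=scale)


@dataclass
class IdentityAssignment:
    mapping: dict[int, str]  # track_id -> class_name
    costs: dict[int, float]
    unassigned: list[int]
    groups: dict[int, str]
    seed_six: list[int]

    def __post_init__(self) -> None:
        names = list(self.mapping.values())
        if len(names) != len(set(names)):
            raise ValueError("assignment must be injective over class names")


def track_groups(
    track_ids: list[int], stats: CorrelationStats, seed_six: list[int]
) -> dict[int, str]:
    """Classify each track by its mean correlation with the seed six:
    backward above c_mu + c_sigma, forward below -(c_mu + c_sigma)."""
    groups = {}
    hi = stats.c_mu + stats.c_sigma
    for tid in track_ids:
        others = [s for s in seed_six if s != tid]
        m = float(np.mean([stats.corr(tid, s) for s in others]))
        if tid in seed_six:
            groups[tid] = "backward"
        elif m > hi:
            groups[tid] = "backward"
        elif m < -hi:
            groups[tid] = "forward"
        else:
            groups[tid] = "other"
    return groups


def assign_identities(
    track_ids: list[int],
    positions: dict[int, np.ndarray],
    frame: BodyFrame,
    stats: CorrelationStats,
    seed_six: list[int],
    atlas: list[AtlasNeuron] | None = None,
    lambda_corr: float = 1.0,
) -> IdentityAssignment:
    """Assign atlas classes to tracks.

    Cost = squared normalized-position distance + lambda_corr if the
    track's activity group disagrees with the atlas neuron's group. Seed
    tracks are restricted to backward-group classes. After the LAP, a swap
    pass enforces the left/right order of bilateral class pairs by the
    sign of the left-axis coordinate.
    """
    if not seed_six:
        raise ValueError("seed six must be determined (or supplied) before assignment")
    if atlas is None:
        atlas = default_atlas()
    groups = track_groups(track_ids, stats, seed_six)
    Q = {tid: frame.normalize(positions[tid])[0] for tid in track_ids}

    n, m = len(track_ids), len(atlas)
    cost = np.empty((n, m))
    for i, tid in enumerate(track_ids):
        for j, neuron in enumerate(atlas):
            c = float(((Q[tid] - neuron.position) ** 2).sum())
            if groups[tid] != neuron.group:
                c += lambda_corr
            if tid in seed_six and neuron.group != "backward":
                c = np.inf  # seed candidates are backward by construction
            cost[i, j] = c
    pairs = solve_assignment(cost)

    mapping = {track_ids[i]: atlas[j].class_name for i, j in pairs}
    costs = {track_ids[i]: float(cost[i, j]) for i, j in pairs}

    # left/right consistency: for each bilateral pair assigned to two
    # tracks, the track with the larger left coordinate takes the L class
    by_class = {v: k for k, v in mapping.items()}
    for neuron in atlas:
        if neuron.side != "L":
            continue
        lname, rname = neuron.class_name, neuron.class_name[:-1] + "R"
        if lname in by_class and rname in by_class:
            tl, tr = by_class[lname], by_class[rname]
            if Q[tl][2] < Q[tr][2]:
                mapping[tl], mapping[tr] = rname, lname
                by_class[lname], by_class[rname] = tr, tl
    unassigned = [tid for tid in track_ids if tid not in mapping]
    return IdentityAssignment(
        mapping=mapping, costs=costs, unassigned=unassigned,
        groups=groups, seed_six=list(seed_six),
    )


def correlation_neighborhood(
    track_id: int, stats: CorrelationStats, threshold_sds: float = 1.0
) -> tuple[list[int], list[int]]:
    """Tracks strongly correlated / anti-correlated with a chosen track."""
    if track_id not in stats._index:
        raise KeyError(f"unknown track id {track_id}")
    row = stats.row(track_id)
    hi = stats.c_mu + threshold_sds * stats.c_sigma
    correlated, anticorrelated = [], []
    for tid in stats.track_ids:
        if tid == track_id:
            continue
        c = row[stats._index[tid]]
        if c > hi:
            correlated.append(tid)
        elif c < -hi:
            anticorrelated.append(tid)
    return correlated, anticorrelated


def identify_tracks(
    tracks,
    traces: list[Trace],
    head_direction,
    atlas: list[AtlasNeuron] | None = None,
    lambda_corr: float = 1.0,
    collinearity_tol: float = 0.15,
    axis_angle_tol_deg: float = 30.0,
) -> tuple[IdentityAssignment, BodyFrame, CorrelationStats]:
    """Full identification pass over tracked, trace-extracted neurons."""
    positions = {tr.track_id: tr.mean_position() for tr in tracks}
    stats = correlation_stats(traces)
    seed_six, _ = find_seed_six(
        stats, positions, collinearity_tol=collinearity_tol,
        axis_angle_tol_deg=axis_angle_tol_deg,
    )
    frame = build_body_frame(
        np.array([positions[tid] for tid in seed_six]),
        head_direction,
        np.array([positions[tid] for tid in stats.track_ids if tid in positions]),
    )
    assignment = assign_identities(
        list(positions), positions, frame, stats, seed_six,
        atlas=atlas, lambda_corr=lambda_corr,
    )
    return assignment, frame, stats
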
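"""Two-stage LAP tracking, track restoration and position inference.

Stage 1 links detections frame-to-frame as a linear assignment problem
with squared-distance costs and a non-link alternative of 1.05 * cmax.
Stage 2 closes gaps by linking segment ends to segment starts under time
and distance limits, with the same cost scheme. A restoration pass then
re-links still-unconnected segments by comparing their mean-distance
profiles against a set of long reference tracks — a sequence-independent
cue that survives frames where a neuron went undetected. Finally, missing
positions inside (and optionally beyond) each track are inferred from the
average displacement of the track's closest neighbours:

    p_A(t) = p_A(t_ref) + (1/|N|) * sum_{J in N} [p_J(t) - p_J(t_ref)]

which is exact under rigid motion of the neighbourhood and degrades
gracefully under small elastic deformations. The same inference
reconstructs full tracks from a single manually placed spot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._lap import solve_assignment
from .core import Spot, Track

log = logging.getLogger(__name__)


@dataclass
class TrackingParams:
    max_link_distance: float = 3.0  # um, stage-1 frame-to-frame
    max_time_gap: int = 5  # frames, stage-2 gap closing
    gap_max_distance: float = 4.0  # um, stage-2
    restore_max_distance: float = 6.0  # um, restoration endpoint limit
    restore_max_gap: int = 50  # frames, restoration
    n_neighbors: int = 20  # Eq-style inference neighbourhood

    def __post_init__(self) -> None:
        for name in ("max_link_distance", "gap_max_distance", "restore_max_distance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.max_time_gap < 1 or self.restore_max_gap < 1:
            raise ValueError("time gaps must be >= 1 frame")
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")


@dataclass
class Segment:
    """A time-ordered run of spots for one putative neuron.

    Stage-1 output has consecutive frames only; after gap closing and
    restoration a segment may skip frames (filled later by inference).
    """

    spots: list[Spot] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.spots = sorted(self.spots, key=lambda s: s.t)

    @property
    def start_t(self) -> int:
        return self.spots[0].t

    @property
    def end_t(self) -> int:
        return self.spots[-1].t

    @property
    def start_pos(self) -> np.ndarray:
        return self.spots[0].position

    @property
    def end_pos(self) -> np.ndarray:
        return self.spots[-1].position

    def __len__(self) -> int:
        return len(self.spots)


def _check_no_duplicates(segments: list[Segment]) -> None:
    seen: set[tuple[int, int]] = set()
    for si, seg in enumerate(segments):
        ts = [s.t for s in seg.spots]
        if len(set(ts)) != len(ts):
            raise AssertionError(f"segment {si} holds two spots in one frame")
        for s in seg.spots:
            key = (s.t, id(s))
            if key in seen:
                raise AssertionError("spot assigned to two segments")
            seen.add(key)


def link_frames(spots_by_frame: list[list[Spot]], params: TrackingParams) -> list[Segment]:
    """Stage 1: frame-to-frame linking.

    For each consecutive frame pair a rectangular assignment is solved with
    cost = squared Euclidean distance (um^2); pairs farther apart than
    ``max_link_distance`` are forbidden and every spot may take the
    non-link alternative 1.05 * cmax instead. Accepted links chain into
    segments of strictly consecutive frames.
    """
    open_segments: list[Segment] = []  # segments whose last spot is at t-1
    closed: list[Segment] = []
    prev: list[Segment] = []
    for t, frame_spots in enumerate(spots_by_frame):
        current_owner: list[Segment] = []
        if prev and frame_spots:
            a = np.array([seg.end_pos for seg in prev])
            b = np.array([s.position for s in frame_spots])
            d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(-1)
            d2[d2 > params.max_link_distance**2] = np.inf
            pairs = dict(solve_assignment(d2))
        else:
            pairs = {}
        matched_cols = set(pairs.values())
        for i, seg in enumerate(prev):
            if i in pairs:
                seg.spots.append(frame_spots[pairs[i]])
            else:
                closed.append(seg)
        current_owner = [prev[i] for i in sorted(pairs)]
        for j, s in enumerate(frame_spots):
            if j not in matched_cols:
                current_owner.append(Segment([s]))
        prev = current_owner
    closed.extend(prev)
    closed.sort(key=lambda s: (s.start_t, *s.start_pos))
    _check_no_duplicates(closed)
    return closed


def link_segments(segments: list[Segment], params: TrackingParams) -> list[Segment]:
    """Stage 2: gap closing.

    LAP over (segment end, segment start) pairs, cost = squared distance
    between the end spot and the start spot, forbidding dt <= 0,
    dt > max_time_gap and distance > gap_max_distance. Accepted pairs are
    concatenated; skipped frames stay empty for later inference.
    """
    n = len(segments)
    if n == 0:
        return []
    ends = np.array([seg.end_pos for seg in segments])
    starts = np.array([seg.start_pos for seg in segments])
    end_t = np.array([seg.end_t for seg in segments])
    start_t = np.array([seg.start_t for seg in segments])
    d2 = ((ends[:, None, :] - starts[None, :, :]) ** 2).sum(-1)
    dt = start_t[None, :] - end_t[:, None]
    forbid = (dt <= 0) | (dt > params.max_time_gap) | (d2 > params.gap_max_distance**2)
    d2[forbid] = np.inf
    pairs = dict(solve_assignment(d2))
    return _merge_chains(segments, pairs)


def _merge_chains(segments: list[Segment], successor: dict[int, int]) -> list[Segment]:
    has_pred = set(successor.values())
    merged: list[Segment] = []
    for i in range(len(segments)):
        if i in has_pred:
            continue
        spots = list(segments[i].spots)
        j = i
        while j in successor:
            j = successor[j]
            spots.extend(segments[j].spots)
        merged.append(Segment(spots))
    merged.sort(key=lambda s: (s.start_t, *s.start_pos))
    _check_no_duplicates(merged)
    return merged


def _segment_positions(segments: list[Segment], n_frames: int) -> np.ndarray:
    P = np.full((len(segments), n_frames, 3), np.nan)
    for i, seg in enumerate(segments):
        for s in seg.spots:
            P[i, s.t] = s.position
    return P


def restore_segments(
    segments: list[Segment],
    params: TrackingParams,
    n_frames: int | None = None,
    reference_span: float = 0.5,
    min_shared_refs: int = 3,
) -> list[Segment]:
    """Re-link still-unconnected segments by relative-distance profiles.

    A segment's profile is its mean distance to each long reference track
    over the frames where both exist. Candidate pairs (earlier, later) must
    be disjoint in time within ``restore_max_gap`` frames and
    ``restore_max_distance`` um of endpoint separation; the pair with the
    lowest mean absolute profile difference over shared references is
    linked first, greedily, each segment used at most once.
    """
    if not segments:
        return []
    if n_frames is None:
        n_frames = max(seg.end_t for seg in segments) + 1
    ref_idx = [i for i, seg in enumerate(segments) if len(seg) >= reference_span * n_frames]
    if len(ref_idx) < 3:
        log.warning("restoration skipped: only %d long reference tracks", len(ref_idx))
        return segments
    P = _segment_positions(segments, n_frames)
    refs = P[ref_idx]  # (R, T, 3)
    # profile[i, r] = mean distance of segment i to reference r on shared frames
    profiles = np.full((len(segments), len(ref_idx)), np.nan)
    for i in range(len(segments)):
        diff = np.linalg.norm(P[i][None, :, :] - refs, axis=-1)  # (R, T)
        valid = np.isfinite(diff)
        counts = valid.sum(axis=1)
        sums = np.where(valid, diff, 0.0).sum(axis=1)
        profiles[i] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    candidates = []
    for i, a in enumerate(segments):
        for j, b in enumerate(segments):
            if i == j:
                continue
            gap = b.start_t - a.end_t
            if gap < 1 or gap > params.restore_max_gap:
                continue
            if np.linalg.norm(b.start_pos - a.end_pos) > params.restore_max_distance:
                continue
            shared = np.isfinite(profiles[i]) & np.isfinite(profiles[j])
            if shared.sum() < min_shared_refs:
                log.debug("pair (%d, %d) skipped: %d shared references", i, j, shared.sum())
                continue
            diff = float(np.mean(np.abs(profiles[i][shared] - profiles[j][shared])))
            candidates.append((diff, i, j))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    used: set[int] = set()
    successor: dict[int, int] = {}
    for diff, i, j in candidates:
        if i in used or j in used:
            continue
        # a segment may gain at most one predecessor and one successor
        if i in successor or j in set(successor.values()):
            continue
        successor[i] = j
        used.update((i, j))
    return _merge_chains(segments, successor)


def tracks_from_segments(segments: list[Segment]) -> list[Track]:
    ordered = sorted(segments, key=lambda s: (s.start_t, *s.start_pos))
    return [Track(track_id=i, spots=list(seg.spots)) for i, seg in enumerate(ordered)]


def _nearest_known_frame(frames: np.ndarray, t: int) -> int:
    """Nearest frame with a known position; earlier frame wins ties (so a
    one-frame gap uses t-1, the previous-frame reference)."""
    deltas = np.abs(frames - t)
    best = np.min(deltas)
    tied = frames[deltas == best]
    earlier = tied[tied < t]
    return int(earlier.max()) if earlier.size else int(tied.min())


def infer_missing_position(
    track: Track,
    t: int,
    all_tracks: list[Track],
    n_neighbors: int = 20,
) -> Spot:
    """Infer the position of ``track`` at frame ``t`` from its neighbours.

    The reference frame is the track's nearest frame with a known
    position (preferring the previous frame); neighbours are the
    ``n_neighbors`` tracks closest at the reference frame that have
    positions at both frames, preferring purely detected ones. The
    returned spot carries the neighbourhood-average displacement applied
    to the reference position.
    """
    frames = np.array(track.frames)
    if frames.size == 0:
        raise ValueError("track has no known positions")
    t_ref = _nearest_known_frame(frames, t)
    p_ref = track.position_at(t_ref)
    cands = []
    for other in all_tracks:
        if other is track or other.track_id == track.track_id:
            continue
        s_ref, s_t = other.spot_at(t_ref), other.spot_at(t)
        if s_ref is None or s_t is None:
            continue
        detected = s_ref.source == "detected" and s_t.source == "detected"
        dist = float(np.linalg.norm(s_ref.position - p_ref))
        cands.append((0 if detected else 1, dist, s_t.position - s_ref.position))
    if not cands:
        log.warning(
            "track %d frame %d: no eligible neighbours; carrying position over",
            track.track_id, t,
        )
        return Spot(t=t, position=p_ref.copy(), intensity=0.0, source="inferred")
    cands.sort(key=lambda c: (c[0], c[1]))
    disp = np.mean([c[2] for c in cands[:n_neighbors]], axis=0)
    return Spot(t=t, position=p_ref + disp, intensity=0.0, source="inferred")


def fill_gaps(
    tracks: list[Track],
    n_neighbors: int = 20,
    extend: bool = True,
    n_frames: int | None = None,
) -> list[Track]:
    """Fill every gap frame of every track by neighbour-displacement
    inference, frame by frame forward in time so earlier inferences can
    serve as references; with ``extend`` tracks are also extrapolated to
    the first and last frame of the recording so traces span it fully.
    """
    if not tracks:
        return []
    if n_frames is None:
        n_frames = max(tr.end_t for tr in tracks) + 1
    n = len(tracks)
    P = np.full((n, n_frames, 3), np.nan)
    S = np.zeros((n, n_frames), dtype=np.int8)  # 0 missing, 1 detected/manual, 2 inferred
    for i, tr in enumerate(tracks):
        for s in tr.spots:
            P[i, s.t] = s.position
            S[i, s.t] = 1
    first = np.array([tr.start_t for tr in tracks])
    last = np.array([tr.end_t for tr in tracks])

    for t in range(n_frames):
        inside = (S[:, t] == 0) & (first <= t) & (t <= last)
        if extend:
            need = (S[:, t] == 0)
        else:
            need = inside
        idx = np.nonzero(need)[0]
        if idx.size == 0:
            continue
        known = S[:, t] > 0  # snapshot: fills within this frame do not feed each other
        for i in idx:
            kf = np.nonzero(S[i] > 0)[0]
            t_ref = _nearest_known_frame(kf, t)
            p_ref = P[i, t_ref]
            elig = known.copy()
            elig[i] = False
            elig &= S[:, t_ref] > 0
            j = np.nonzero(elig)[0]
            if j.size == 0:
                P[i, t] = p_ref
                S[i, t] = 2
                continue
            detected_both = (S[j, t] == 1) & (S[j, t_ref] == 1)
            dist = np.linalg.norm(P[j, t_ref] - p_ref, axis=1)
            order = np.lexsort((dist, ~detected_both))
            chosen = j[order[:n_neighbors]]
            disp = (P[chosen, t] - P[chosen, t_ref]).mean(axis=0)
            P[i, t] = p_ref + disp
            S[i, t] = 2

    out = []
    for i, tr in enumerate(tracks):
        spots = list(tr.spots)
        for t in np.nonzero(S[i] == 2)[0]:
            spots.append(Spot(t=int(t), position=P[i, t].copy(), intensity=0.0, source="inferred"))
        out.append(Track(track_id=tr.track_id, spots=spots))
    return out


def add_manual_spot(
    position,
    t: int,
    tracks: list[Track],
    n_neighbors: int = 20,
    n_frames: int | None = None,
) -> Track:
    """Create a track from one manually placed spot and reconstruct its
    position at every other frame by the same neighbour-displacement
    inference, propagated forward and backward from ``t``."""
    position = np.asarray(position, dtype=float)
    if n_frames is None:
        n_frames = max(tr.end_t for tr in tracks) + 1
    if not 0 <= t < n_frames:
        raise IndexError(f"frame {t} out of range [0, {n_frames})")
    dists = []
    for tr in tracks:
        p = tr.position_at(t)
        if p is not None:
            dists.append(np.linalg.norm(p - position))
    if not dists or min(dists) > 10.0:
        log.warning("manual spot at %s is > 10 um from every track; likely not a neuron", position)
    new_id = max((tr.track_id for tr in tracks), default=-1) + 1
    new = Track(track_id=new_id, spots=[Spot(t=t, position=position, intensity=0.0, source="manual")])
    for tau in list(range(t + 1, n_frames)) + list(range(t - 1, -1, -1)):
        spot = infer_missing_position(new, tau, tracks, n_neighbors=n_neighbors)
        new.add(spot)
    return new


def track_recording(
    spots_by_frame: list[list[Spot]],
    params: TrackingParams,
    n_frames: int | None = None,
    extend: bool = True,
) -> list[Track]:
    """Full tracking pass: link, close gaps, restore, fill."""
    if n_frames is None:
        n_frames = len(spots_by_frame)
    segments = link_frames(spots_by_frame, params)
    segments = link_segments(segments, params)
    segments = restore_segments(segments, params, n_frames=n_frames)
    tracks = tracks_from_segments(segments)
    return fill_gaps(tracks, n_neighbors=params.n_neighbors, extend=extend, n_frames=n_frames)
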
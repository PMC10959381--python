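"""Detection evaluation: 3 um ground-truth matching and accuracy.

A detection counts as a true positive when it can be paired one-to-one
with a ground-truth soma centre within 3 um (pairing solved as a
minimum-distance assignment; a greedy variant is available for
sensitivity analysis). The headline metric is

    accuracy = TP / (TP + FP + FN)

with rates quoted against the ground-truth count (TP + FN); true
negatives are deliberately absent throughout, since almost every voxel of
a sparse volume is a trivial negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._lap import solve_assignment
from .core import GroundTruth, Recording, Spot
from .detect import DetectionParams, detect_spots
from .simulate import add_multiplicative_noise

MATCH_RADIUS_UM = 3.0


@dataclass
class DetectionEvaluation:
    TP: int
    FN: int
    FP: int
    tp_rate: float
    fn_rate: float
    fp_rate: float
    accuracy: float

    def rounded(self, ndigits: int = 2) -> dict:
        """Display form, rounded to 2 decimals like published tables."""
        return {
            "TP": self.TP, "FN": self.FN, "FP": self.FP,
            "tp_rate": round(self.tp_rate, ndigits),
            "fn_rate": round(self.fn_rate, ndigits),
            "fp_rate": round(self.fp_rate, ndigits),
            "accuracy": round(self.accuracy, ndigits),
        }


def compute_metrics(TP: int, FN: int, FP: int) -> DetectionEvaluation:
    """Rates and accuracy from raw counts, at full precision."""
    if TP < 0 or FN < 0 or FP < 0:
        raise ValueError("counts must be non-negative")
    if TP + FN + FP == 0:
        raise ValueError("metrics undefined for all-zero counts")
    n_truth = TP + FN
    return DetectionEvaluation(
        TP=TP, FN=FN, FP=FP,
        tp_rate=TP / n_truth if n_truth else np.nan,
        fn_rate=FN / n_truth if n_truth else np.nan,
        fp_rate=FP / n_truth if n_truth else np.nan,
        accuracy=TP / (TP + FP + FN),
    )


def match_to_ground_truth(
    detections: list[Spot],
    truth_positions: np.ndarray,
    radius: float = MATCH_RADIUS_UM,
    method: str = "optimal",
) -> tuple[int, int, int, list[tuple[int, int]]]:
    """Pair detections with ground-truth points within ``radius`` um.

    Returns (TP, FN, FP, pairing) where pairing holds (detection index,
    truth index) pairs. ``optimal`` solves the one-to-one minimum-distance
    assignment; ``greedy`` takes closest pairs first.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    truth_positions = np.atleast_2d(np.asarray(truth_positions, dtype=float))
    n, m = len(detections), len(truth_positions)
    if n == 0 or m == 0:
        return 0, m, n, []
    det = np.array([s.position for s in detections])
    dist = np.linalg.norm(det[:, None, :] - truth_positions[None, :, :], axis=-1)
    if method == "optimal":
        cost = dist.copy()
        cost[cost > radius] = np.inf
        # alternative = radius guarantees maximum-cardinality pairing:
        # any in-radius pair is cheaper than leaving both ends unmatched
        pairs = solve_assignment(cost, alternative=radius)
    elif method == "greedy":
        order = np.argsort(dist, axis=None)
        used_d, used_t, pairs = set(), set(), []
        for flat in order:
            i, j = np.unravel_index(flat, dist.shape)
            if dist[i, j] > radius:
                break
            if i in used_d or j in used_t:
                continue
            pairs.append((int(i), int(j)))
            used_d.add(i)
            used_t.add(j)
    else:
        raise ValueError(f"unknown matching method {method!r}")
    TP = len(pairs)
    return TP, m - TP, n - TP, pairs


def evaluate_detections(
    detections: list[Spot],
    truth_positions: np.ndarray,
    radius: float = MATCH_RADIUS_UM,
    method: str = "optimal",
) -> DetectionEvaluation:
    TP, FN, FP, _ = match_to_ground_truth(detections, truth_positions, radius, method)
    return compute_metrics(TP, FN, FP)


def noise_robustness_curve(
    rec: Recording,
    truth: GroundTruth,
    params: DetectionParams,
    variances: list[float],
    seed: int,
    frame: int = 0,
) -> pd.DataFrame:
    """Detection accuracy under increasing multiplicative noise.

    For each sigma^2: add speckle noise to the designated frame, rerun
    detection, and evaluate against the ground truth of that frame.
    Deterministic under ``seed``.
    """
    if any(v < 0 for v in variances):
        raise ValueError("variances must be non-negative")
    _, truth_pos = truth.frame(frame)
    single = Recording(rec.frames[frame][None], rec.voxel_size, rec.frame_interval)
    rows = []
    for k, var in enumerate(variances):
        noisy = add_multiplicative_noise(single, var, seed=seed + k)
        spots = detect_spots(noisy.volume(0), params, rec.voxel_size, t=frame)
        ev = evaluate_detections(spots, truth_pos)
        rows.append((var, ev.TP, ev.FN, ev.FP, ev.tp_rate, ev.fn_rate, ev.fp_rate, ev.accuracy))
    return pd.DataFrame(
        rows,
        columns=["variance", "TP", "FN", "FP", "tp_rate", "fn_rate", "fp_rate", "accuracy"],
    )


def tracking_identity_recovery(
    tracks,
    truth: GroundTruth,
    radius: float = MATCH_RADIUS_UM,
) -> float:
    """Fraction of (neuron, frame) ground-truth entries covered by the
    matched track within ``radius`` um.

    Each ground-truth neuron is matched to the track that spends the most
    frames within the radius of it (majority overlap); a frame counts as
    recovered when that track has a position within the radius there.
    """
    n_frames = truth.n_frames
    track_pos = {}
    for tr in tracks:
        P = np.full((n_frames, 3), np.nan)
        for s in tr.spots:
            if s.t < n_frames:
                P[s.t] = s.position
        track_pos[tr.track_id] = P
    total = 0
    recovered = 0
    for nid in truth.neuron_ids:
        sub = truth.positions_of(nid)
        T = np.full((n_frames, 3), np.nan)
        for t, r in sub.iterrows():
            T[int(t)] = (r.x_um, r.y_um, r.z_um)
        valid = np.isfinite(T[:, 0])
        total += int(valid.sum())
        best_tid, best_hits = None, -1
        for tid, P in track_pos.items():
            d = np.linalg.norm(P - T, axis=1)
            hits = int(np.sum(d[valid] <= radius))
            if hits > best_hits:
                best_tid, best_hits = tid, hits
        if best_tid is not None:
            recovered += best_hits
    return recovered / total if total else 0.0
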
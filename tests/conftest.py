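import numpy as np
import pytest

from wormtrace.detect import DetectionParams, threshold_from_reference
from wormtrace.simulate import SimConfig, simulate_recording


@pytest.fixture(scope="session")
def small_scene():
    """A clean 20-neuron, 30-frame rendered scene with motion but no
    dropout and no noise; shared by detection/tracking/ROI tests."""
    cfg = SimConfig(n_neurons=20, n_frames=30, seed=11, dropout_prob=0.0)
    rec, truth, activity = simulate_recording(cfg)
    return cfg, rec, truth, activity


@pytest.fixture(scope="session")
def small_scene_threshold(small_scene):
    """Detection threshold calibrated at half the dimmest true product."""
    _, rec, truth, _ = small_scene
    _, pos = truth.frame(0)
    return threshold_from_reference(
        rec.volume(0), pos, DetectionParams(), rec.voxel_size, fraction=0.5
    )


@pytest.fixture(scope="session")
def static_scene():
    """No drift, no jitter, no dropout: ground-truth tracks are constant."""
    cfg = SimConfig(
        n_neurons=15,
        n_frames=25,
        seed=21,
        drift_per_frame=(0.0, 0.0, 0.0),
        elastic_jitter_sd=0.0,
        dropout_prob=0.0,
    )
    rec, truth, activity = simulate_recording(cfg)
    return cfg, rec, truth, activity


def calibrated_params(rec, truth, fraction=0.5, min_intensity=None):
    sub = truth.table[truth.table.t == 0]
    if min_intensity is not None:
        sub = sub[sub.intensity > min_intensity]
    thr = threshold_from_reference(
        rec.volume(0),
        sub[["x_um", "y_um", "z_um"]].to_numpy(),
        DetectionParams(),
        rec.voxel_size,
        fraction=fraction,
    )
    return DetectionParams(threshold=thr)


def brute_force_assignment(cost: np.ndarray, alternative: float):
    """Exhaustive minimum over all partial one-to-one matchings: matched
    pair costs plus ``alternative`` per unmatched node. Independent oracle
    for the LAP solver; feasible for <= 6 elements per side."""
    from itertools import combinations, permutations

    n, m = cost.shape
    best_total = alternative * (n + m)
    best_pairs: list = []
    for k in range(1, min(n, m) + 1):
        for rows in combinations(range(n), k):
            for cols in permutations(range(m), k):
                pairs = list(zip(rows, cols))
                if any(not np.isfinite(cost[r, c]) for r, c in pairs):
                    continue
                total = sum(cost[r, c] for r, c in pairs) + alternative * (n + m - 2 * k)
                if total < best_total - 1e-12:
                    best_total, best_pairs = total, pairs
    return best_total, best_pairs
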
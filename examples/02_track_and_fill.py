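"""Track nuclei across volumes, surviving detection dropout.

Simulates 40 neurons for 80 frames with drift, elastic jitter and a 10%
per-frame chance that a neuron dims below the detection threshold, then
runs the full tracking chain: frame-to-frame LAP linking, gap closing,
distance-profile restoration, and neighbour-displacement gap filling.
"""

from wormtrace import DetectionParams, SimConfig, TrackingParams, simulate_recording
from wormtrace.detect import detect_all_frames, threshold_from_reference
from wormtrace.evaluate import tracking_identity_recovery
from wormtrace.track import track_recording

cfg = SimConfig(n_neurons=40, n_frames=80, seed=5)  # dropout_prob defaults to 0.1
rec, truth, _ = simulate_recording(cfg)

bright = truth.table[(truth.table.t == 0) & (truth.table.intensity > 20)]
threshold = threshold_from_reference(
    rec.volume(0), bright[["x_um", "y_um", "z_um"]].to_numpy(),
    DetectionParams(), rec.voxel_size,
)
spots = detect_all_frames(rec, DetectionParams(threshold=threshold))
n_detected = sum(len(f) for f in spots)

tracks = track_recording(spots, TrackingParams(), n_frames=cfg.n_frames)
n_inferred = sum(1 for tr in tracks for s in tr.spots if s.source == "inferred")
recovery = tracking_identity_recovery(tracks, truth)

print(f"raw detections:        {n_detected} "
      f"({n_detected / (cfg.n_neurons * cfg.n_frames):.0%} of neuron-frames)")
print(f"tracks built:          {len(tracks)}")
print(f"positions inferred:    {n_inferred} (filled where neurons dimmed out)")
print(f"identity recovery:     {recovery:.2%} of neuron-frames within 3 um of truth")
# with ~10% dropout the raw detections miss 1 frame in 10; gap closing and
# the Eq-style neighbour inference restore near-complete tracks, so the
# recovery fraction should stay above 99%
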
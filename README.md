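# wormtrace

Single-neuron activity traces and neuron identities from 3D time-lapse
calcium imaging of the *C. elegans* head.

Whole-brain recordings of the worm are 4D grids — hundreds of volumes, each
holding ~100 densely packed, nucleus-localized GCaMP signals. Turning them
into per-neuron traces requires (1) finding every nucleus in every volume,
(2) linking detections into tracks that survive frames where a neuron's
fluorescence dips below the detection threshold, (3) outlining each nucleus
well enough to read out a clean fluorescence value, and (4) deciding *which*
neuron each track is. `wormtrace` implements that pipeline for recordings of
paralyzed or nearly immobile worms acquired in the GCaMP channel alone — no
RFP reference channel and no learned model, so it runs on a desktop CPU and
every step is inspectable.

The package is aimed at experimentalists processing their own recordings
(via the `wormtrace` command line or the Python API) and at methods people
who want a transparent, fully simulated test bed: the built-in generator
renders ground-truth recordings with known positions, activity and noise,
so every stage can be validated end to end without any data download.

## Method

**Detection.** Each volume is convolved with a 3D Laplacian-of-Gaussian
filter built in physical units (plane spacing of ~2 μm vs ~0.27 μm pixels is
handled by the kernel, not the caller). Strict 26-connected local maxima of
the (sign-flipped) response are kept where the element-wise product of
response and image exceeds a user threshold, tuned on a live preview.

**Tracking.** Two linear-assignment stages in the TrackMate tradition:
frame-to-frame linking with cost `d²` (μm²) and a non-link alternative of
`1.05·cmax`, then gap closing over segment (end, start) pairs under time and
distance limits. A restoration pass then re-links segments that the LAP
stages left apart, by comparing each segment's mean distance profile to a
set of long reference tracks — a sequence-independent cue that survives long
dropouts. Finally, missing positions are inferred from the `N = 20` closest
neighbours:

    p_A(t) = p_A(t−1) + (1/|N|) Σ_{J∈N} [ p_J(t) − p_J(t−1) ]

which is exact under rigid motion and degrades gracefully under the ≤ 2 μm
elastic deformations seen over ~100 s. The same formula reconstructs a full
track from a single manually placed spot.

**ROI segmentation and traces.** Around each tracked spot a ~6 μm crop is
smoothed at several scales and thresholded (Otsu-anchored ladder); the
component best matching a ~2 μm nucleus is fitted with an intensity-weighted
second-moment ellipsoid (`semi_axis = √5·√eigenvalue`), giving sub-voxel
centres. Shapes are consolidated per track (intensity-weighted average).
The trace is the mean of the brightest 90% of ROI voxels minus the mean of
a one-voxel corona just outside it, then optionally smoothed.

**Identification.** Traces are correlated pairwise (Pearson; `C_μ`, `C_σ`
summarize all pairs). The search for the seed six — the AVA/AVE/AIB
candidate pairs — looks for two roughly collinear, bilaterally paired
triplets of maximally correlated tracks along the dominant spatial axis
(first principal component). They anchor a body frame (x anterior from the
user-supplied head direction, y dorsal from the seed plane normal signed
toward the neuron-rich side, z left; coordinates scaled by the seed-six mean
pairwise distance). Tracks are then assigned to a ~21-class model atlas by
another LAP whose cost is squared normalized-position distance plus a
penalty when the track's activity group (backward / forward / other, judged
against `C_μ ± C_σ`) disagrees with the atlas class, with a left/right
consistency pass afterwards.

**Evaluation.** A detection is a true positive when it pairs one-to-one
with a ground-truth soma within 3 μm (minimum-distance assignment); the
headline metric is `accuracy = TP / (TP + FP + FN)` with rates quoted
against the ground-truth count. True negatives are excluded by design —
nearly every voxel is a trivial negative.

## Worked example

`examples/02_track_and_fill.py` simulates 40 neurons for 80 volumes with
drift, elastic jitter and 10% per-frame detection dropout, then runs
detection and the full tracking chain:

```
raw detections:        2893 (90% of neuron-frames)
tracks built:          40
positions inferred:    307 (filled where neurons dimmed out)
identity recovery:     100.00% of neuron-frames within 3 um of truth
```

One track per true neuron; the ~10% of neuron-frames lost to dropout come
back as inferred positions, and every neuron-frame ends up within the 3 μm
matching radius of its ground truth. The other examples cover detection
scoring (`01`), ROI fitting and trace fidelity (`03`), identification on an
atlas-generated head (`04`), and the speckle-noise robustness study (`05`).

The same pipeline runs from the shell:

```
wormtrace simulate --out sim --n-neurons 100 --n-frames 200 --seed 1
wormtrace preview  --recording sim/recording.tif --threshold 300 --out preview.png
wormtrace run      --config config.yaml --run-dir run1
```

Stages (`detect`, `track`, `segment`, `extract`, `identify`, `evaluate`) can
also be run one at a time against the same run directory and resume from
each other's CSV outputs.

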
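# Methods

This note records the models, parameter choices and numerical decisions
behind `wormtrace`, and what the synthetic test bed does and does not show
about real recordings.

## Data model and conventions

Recordings are `(t, z, y, x)` grids with voxel sizes `(dx, dy, dz)` in μm
and a frame interval in seconds. All geometry downstream of I/O works in
physical micrometres, with positions reported `(x, y, z)` and
`x = column·dx`. This matters because z is typically 7–8× coarser than xy
(defaults 0.27, 0.27, 2.0 μm): kernels, distances and ellipsoids are
correct only in physical units.

## Pre-processing

Two steps, both optional and order-configurable (default: denoise, then
background): a per-frame scalar background equal to the mean of a
user-chosen dark crop (default: the 32×32 corner with the lowest mean in
frame 0), clamped at zero afterwards because detection assumes non-negative
intensities; and temporal denoising. The "image Kalman filter" is
implemented as the one-parameter recursive filter
`est_t = est_{t−1} + g·(obs_t − est_{t−1})` with gain `g ∈ (0, 1]`
(default 0.5, `g = 1` is the identity) — the simplest filter consistent
with that name; its steady-state output variance on white noise is
`g/(2−g)` of the input. A 3-frame running median is available for
low-SNR light-sheet data.

## Detection

The LoG response is computed as the sum of per-axis second-derivative
Gaussian filters with per-axis sigma `σ/d_axis` voxels and support radius
`filter_size // 2` (default 9, i.e. radius 4), reflective boundaries, sign
flipped so bright blobs peak positively. σ defaults to 1 μm — matched to
~2 μm nuclei. Candidates are strict 26-connected local maxima (edge voxels
may be maxima; exact plateau ties are effectively impossible in float and
are not specially handled); a candidate survives if
`response × intensity > threshold` at its voxel. Duplicate maxima closer
than 1.5 μm are merged keeping the brighter. The threshold is deliberately
a free, human-tuned parameter; `threshold_from_reference` reproduces the
tuning a user does on a preview frame (a fraction — default half — of the
dimmest reference nucleus's product value).

## Tracking

Every linking step is one rectangular assignment problem with forbidden
pairs and a per-node non-link alternative of `1.05·cmax`, `cmax` being the
largest finite cost of that instance (if every pair is forbidden nothing
links). The solver embeds the rectangular problem in an augmented square
matrix and calls `scipy.optimize.linear_sum_assignment`; a zero alternative
is nudged to 10⁻¹² so matching wins exact ties.

Stage 1 links consecutive frames with cost `d²` and a distance cutoff
(default 3 μm). Stage 2 links segment ends to starts with the same cost,
`1 ≤ Δt ≤ max_time_gap` (default 5 frames) and a 4 μm cutoff. Restoration
then computes, for every segment, its mean distance to each "reference"
track (segments covering ≥ 50% of the recording; at least 3 required, else
the pass is skipped) over shared frames only — no imputation — and greedily
merges time-disjoint candidate pairs (gap ≤ 50 frames, endpoints ≤ 6 μm) in
ascending order of mean absolute profile difference, each segment used at
most once, pairs with fewer than 3 shared references skipped.

Gap filling proceeds frame by frame, forward in time, so earlier inferences
can serve as references. The reference frame for a missing position is the
nearest frame with a known position (earlier frame on ties, so a one-frame
gap uses exactly the previous-frame formula); neighbours must have
positions at both frames, detected spots preferred over inferred ones to
limit error propagation, the 20 closest used. Within one frame all
inferences read a snapshot of positions known before that frame, making the
result independent of track order. Tracks are extrapolated to the first and
last frame of the recording by the same mechanism (flag `extend`,
default on) so traces span the recording. A manually added spot becomes a
one-point track reconstructed forward and backward the same way; a warning
is issued if it lies > 10 μm from every existing track.

The inference is exact (machine precision) under rigid translation of the
neighbourhood — asserted in the tests — and on simulated elastic jitter of
0.05–0.2 μm/frame the error stays well under 1 μm.

## ROI segmentation and traces

The crop half-width is 6 μm (the "~6 μm extent" is read as a radius; a
config constant, not a magic number). Smoothing scales are 0.5/1.0/1.5 μm.
The binary threshold is anchored on Otsu computed over the non-background
voxels of the crop (> 5% of crop max): a crop is mostly empty space, and
plain Otsu lands near 0.4 of peak while the ~2 μm isophote of a
Gaussian-profile nucleus sits near 0.6 of peak. Factors
(0.8, 1.0, 1.2, 1.5, 2.0)×Otsu are tried; among components containing the
spot and not swallowing any neighbouring track's spot, the one whose
equivalent-sphere diameter is closest to 2 μm wins. If nothing works, a
2 μm sphere is used and logged.

The ellipsoid fit is moment-based (robust on small voxel counts,
deterministic): intensity-weighted centroid and covariance,
`semi_axis = √(5·eigenvalue)` (the uniform-ellipsoid relation), eigenvector
orientation with determinant forced positive; degenerate axes are floored
at half the z plane spacing. Quality is the fraction of mask voxels inside
the fit. Consolidation weights per-frame fits by ROI intensity; rotations
are column-sign-aligned to the brightest frame, averaged, and projected to
the nearest rotation via SVD. For speed, consolidation samples up to 20
evenly spaced detected frames per track — the shape is modelled as
stationary, so more frames only average noise.

Traces: ROI voxels are those inside the consolidated ellipsoid placed at
the frame's (possibly inferred) position; signal is the mean of voxels at
or above the 10th intensity percentile ("brightest 90%"); background is the
mean of the one-voxel 26-connected shell just outside the ROI, computed on
the same (background-subtracted) image; the difference is recorded
unclamped, and no ΔF/F normalization is applied. The corona is a 3D voxel
shell, so with anisotropic voxels it is geometrically thicker in z.
Smoothing is a centred moving average with shrinking edge windows
(odd window, default 5).

## Identification

Correlations are Pearson, on smoothed traces, pairwise-complete over shared
frames (≥ 3); constant traces get zero correlations and a warning. `C_μ`
and `C_σ` are taken over all off-diagonal pairs.

The seed-six search pools the 12 tracks with the highest correlation score
(mean of each track's 5 strongest partners) and enumerates 6-subsets. A
subset is geometrically valid when it splits into two triplets that are
each roughly collinear (max perpendicular deviation / length ≤ 0.15),
aligned within 30° of the dominant axis, and bilaterally paired — sorted by
projection along the axis, the two triplets' stations must agree within 30%
of their length. Among valid subsets the highest mean pairwise correlation
wins; near-ties within 0.002 (below which sample correlations are not
distinguishable) are broken by pairing symmetry, then compactness, since
the command-interneuron core is both the most coherent and the most
tightly clustered arrangement. If no subset is valid the stage raises and
asks for manual seeding rather than guessing.

The body frame: anterior is the dominant axis signed along the
user-supplied head direction (an error is raised if that direction is
within 10° of orthogonal — the sign would be guesswork); dorsal is the
seed-plane normal, orthogonalized against anterior and signed toward the
side holding the majority of all neurons; left completes the right-handed
(anterior, dorsal, left) triad, i.e. `left = anterior × dorsal`. The origin
is the seed centroid and the scale their mean pairwise distance, making
normalized coordinates invariant to similarity transforms of the input —
asserted end to end in the tests.

Assignment cost is `‖q_track − q_atlas‖² + λ·[group mismatch]` with
`λ = 1` in normalized-distance² units (position and group terms are then
comparable: a group mismatch outweighs ~1 seed-spacing of position error).
A track's group is judged by its mean correlation with the seed six:
backward above `C_μ + C_σ`, forward below `−(C_μ + C_σ)`, otherwise other.
Seed tracks are restricted to backward-group atlas classes — they are
backward by construction, and this keeps a near-miss seed set (e.g. a RIM
swapped in for an AIB under heavy placement noise) from contaminating
non-backward classes. After the LAP, bilateral class pairs are swapped
where needed so the track with the larger left coordinate holds the L
label; mirroring the left axis therefore swaps L/R labels exactly, which
is the symmetry the tests assert. (Flipping the user's head direction is
*not* a pure L/R swap: it mirrors the anterior axis and legitimately
remaps anterior–posterior structure.)

The shipped atlas is a deliberately approximate, editable 21-class table
(AVA/AVE/AIB/RIM/VA01/DA01 backward; AVB/RIB/RME×4/RID/RIS/DB01 forward)
in normalized body-frame coordinates, laid out to respect bilateral
symmetry, anteroposterior order and a dorsal-side majority; it is
normalized on load so the seed-six centroid is the origin and their mean
pairwise distance is 1. It is a stand-in to be replaced by a
user-calibrated table for real data; all identification tests generate
scenes *from* this atlas, so they validate the algorithm, not the anatomy.

## Evaluation

Matching is a one-to-one minimum-distance assignment restricted to pairs
within 3 μm (the radius itself makes maximum cardinality optimal); a greedy
closest-first variant exists for sensitivity analysis. Metrics:
`accuracy = TP/(TP+FP+FN)`; `tp/fn/fp` rates all use the ground-truth count
`TP + FN` as denominator — the convention consistent with the published
worked-example tables this protocol reproduces, of which three printed
cells disagree with their own counts at 2-decimal rounding and are asserted
from the arithmetic instead. True negatives are excluded throughout.

## The simulator

What it emulates: ~100 Gaussian nuclei (σ = 1 μm → ~2 μm somas) in a
12×165×440-voxel head volume, placed ≥ 4 μm apart with an elongated spread
(placements < 2 μm apart are an error); rigid drift (default
(0.015, 0.008, 0.004) μm/frame) plus per-neuron random-walk jitter
(0.05 μm/frame step), which together produce the ~1–2 μm relative
displacements per 100 s that restoration and inference are built for;
two anti-correlated activity groups sharing a slow saturating-exponential
latent (GCaMP6-like rise/decay at random intervals — only the correlation
structure matters downstream), with the first six backward neurons tightly
coherent and later backward cells following the latent more loosely
(0.85 latent + 0.15 independent), mirroring the coherence hierarchy between
command interneurons and the rest of their group; per-frame dropout
(probability 0.1) implemented by scaling brightness to 5% — the neuron is
still there, just under threshold, so inference is genuinely exercised;
multiplicative speckle noise `I·(1+n)`, `n ~ N(0, σ²)`, clamped at zero;
and a small uniform background (2.0) so noise acts on empty voxels too.
The two bilateral backward triplets are planted at the atlas seed geometry
(scaled to 20 μm) so the seed search is exercised. Everything is
reproducible from the config seed.

What it does not emulate: optical PSF structure, photobleaching, body
bends or any deformation beyond drift + jitter, autofluorescence, and
anatomically faithful neuron positions. Consequently, passing tests show
the algorithms are correct under their stated assumptions — they do not
show the pipeline survives strong posture changes (it is documented not
to), nor that the shipped atlas matches real worms.

One physical effect the simulator *does* reproduce and tests must respect:
with 2 μm plane spacing an ROI often spans a single z-plane, so sub-plane
z-motion modulates the extracted trace by several percent. Trace-fidelity
is therefore asserted as exact (r ≥ 0.95, in practice ≈ 1) on motion-free
renders, and only loosely under motion.

## Problem sizes and runtime

Defaults were chosen so the whole validation suite runs on one desktop
CPU: the tracking-recovery study uses the full default conditions
(100 neurons × 200 frames, ~35 s end to end); the noise study uses a
3-frame render of the same volume (the protocol only needs one volume);
identification statistics use 20 trace-level replicates of the 21-class
atlas scene (~10 s). The acceptance script repeats all of these from
scratch in a few minutes.

## Known limitations

* Restoration compares distance profiles on shared frames only; two
  segments with no temporal overlap in their reference coverage cannot be
  compared and stay unlinked.
* The seed-six search is exhaustive only within the 12 most correlated
  tracks; if fewer than six of the true seed neurons make that pool the
  stage fails (by design, loudly).
* Under heavy placement noise the seed search may settle on an adjacent
  backward-group subset (e.g. RIM for AIB); the backward-class restriction
  confines the damage and label recovery is typically unaffected, but the
  reported seed set is then not literally AVA/AVE/AIB.
* Anteroposterior ordering within same-side, same-group class runs is
  enforced only through the position cost, not by an explicit constraint
  pass; only left/right order has a dedicated swap pass.
* The trace corona picks up signal from neighbours closer than ~2× the
  nucleus radius; in dense packings this couples traces slightly (visible
  in the simulator as reduced correlation with truth at 4 μm spacing).
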
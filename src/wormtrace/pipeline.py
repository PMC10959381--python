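"""Pipeline orchestration: config, stage running, resumable run directories.

A run directory holds one sub-directory per stage (inputs/, detections/,
tracks/, shapes/, traces/, identities/, eval/) plus a manifest recording
the config hash, package version, seed and per-stage timings. Stages can
be re-run individually; each reads its upstream stage's CSV output from
disk, so partial runs resume where they left off.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .atlas import default_atlas, load_atlas
from .core import Recording
from .detect import DetectionParams, detect_all_frames, preview_detection
from .evaluate import evaluate_detections, noise_robustness_curve
from .identify import correlation_neighborhood, identify_tracks
from .io import (
    ensure_dir,
    read_detections,
    read_ground_truth,
    read_recording,
    read_tracks,
    write_detections,
    write_ground_truth,
    write_recording,
    write_tracks,
)
from .preprocess import subtract_background, temporal_denoise
from .roi import consolidated_track_shapes
from .simulate import SimConfig, simulate_recording
from .track import TrackingParams, track_recording
from .traces import extract_all_traces, write_traces

log = logging.getLogger(__name__)

STAGE_ORDER = ["detect", "track", "segment", "extract", "identify"]


class StageDependencyError(RuntimeError):
    """A stage was asked to run before its upstream output exists."""


def _strict(cls, data: dict, context: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {context} config keys: {sorted(unknown)}")
    return cls(**data)


@dataclass
class InputConfig:
    recording: str | None = None
    ground_truth: str | None = None
    n_z: int = 12
    voxel_size: tuple[float, float, float] = (0.27, 0.27, 2.0)
    frame_interval: float = 1 / 3


@dataclass
class PreprocessConfig:
    denoise: str = "kalman"  # kalman | median | none
    gain: float = 0.5
    dark_crop: tuple[int, int, int, int] | None = None
    background: bool = True
    denoise_first: bool = True  # denoise -> background by default; order is configurable


@dataclass
class SegmentationConfig:
    max_sample_frames: int = 20


@dataclass
class TraceConfig:
    window: int = 5


@dataclass
class IdentificationConfig:
    head_direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    lambda_corr: float = 1.0
    collinearity_tol: float = 0.15
    axis_angle_tol_deg: float = 30.0
    threshold_sds: float = 1.0
    atlas: str | None = None  # path to a CSV atlas; None = shipped default


@dataclass
class EvaluationConfig:
    radius: float = 3.0
    variances: tuple[float, ...] = (0.01, 0.05, 1.0, 2.0)


@dataclass
class PipelineConfig:
    seed: int = 0
    inputs: InputConfig = field(default_factory=InputConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    detection: DetectionParams = field(default_factory=DetectionParams)
    tracking: TrackingParams = field(default_factory=TrackingParams)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    trace: TraceConfig = field(default_factory=TraceConfig)
    identification: IdentificationConfig = field(default_factory=IdentificationConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sections = {
            "inputs": InputConfig,
            "preprocess": PreprocessConfig,
            "detection": DetectionParams,
            "tracking": TrackingParams,
            "segmentation": SegmentationConfig,
            "trace": TraceConfig,
            "identification": IdentificationConfig,
            "evaluation": EvaluationConfig,
        }
        kwargs = {}
        for key, scls in sections.items():
            if key in data:
                kwargs[key] = _strict(scls, data.pop(key) or {}, key)
        if "seed" in data:
            kwargs["seed"] = int(data.pop("seed"))
        if data:
            raise ValueError(f"unknown config keys: {sorted(data)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_preprocessed_recording(cfg: PipelineConfig) -> Recording:
    if cfg.inputs.recording is None:
        raise StageDependencyError("no input recording configured")
    rec = read_recording(
        cfg.inputs.recording,
        voxel_size=cfg.inputs.voxel_size,
        n_z=cfg.inputs.n_z,
        frame_interval=cfg.inputs.frame_interval,
    )
    pp = cfg.preprocess
    steps = []
    if pp.denoise != "none":
        steps.append("denoise")
    if pp.background:
        steps.append("background")
    if not pp.denoise_first:
        steps.reverse()
    for step in steps:
        if step == "denoise":
            rec = temporal_denoise(rec, gain=pp.gain, mode=pp.denoise)
        else:
            rec = subtract_background(rec, dark_crop=pp.dark_crop)
    return rec


def _require(path: Path, stage: str, produced_by: str) -> Path:
    if not path.exists():
        raise StageDependencyError(
            f"stage '{stage}' needs {path.name} from stage '{produced_by}'; "
            f"run '{produced_by}' first"
        )
    return path


def run_stage(stage: str, cfg: PipelineConfig, run_dir) -> None:
    run_dir = ensure_dir(run_dir)
    if stage == "detect":
        rec = load_preprocessed_recording(cfg)
        spots = detect_all_frames(rec, cfg.detection)
        out = ensure_dir(run_dir / "detections")
        write_detections(spots, out / "detections.csv")
    elif stage == "track":
        src = _require(run_dir / "detections" / "detections.csv", "track", "detect")
        spots = read_detections(src)
        tracks = track_recording(spots, cfg.tracking, n_frames=len(spots))
        out = ensure_dir(run_dir / "tracks")
        write_tracks(tracks, out / "tracks.csv")
        audit = {
            "n_tracks": len(tracks),
            "inferred_frames": {
                tr.track_id: [s.t for s in tr.spots if s.source == "inferred"]
                for tr in tracks
            },
        }
        (out / "tracking_audit.json").write_text(json.dumps(audit, indent=1))
    elif stage == "segment":
        src = _require(run_dir / "tracks" / "tracks.csv", "segment", "track")
        rec = load_preprocessed_recording(cfg)
        tracks = read_tracks(src)
        shapes = consolidated_track_shapes(
            rec, tracks, max_sample_frames=cfg.segmentation.max_sample_frames
        )
        rows = []
        for tid, sh in shapes.items():
            rows.append([tid, *sh.semi_axes, *sh.orientation.ravel(), sh.quality])
        import pandas as pd

        cols = ["track_id", "a_um", "b_um", "c_um"] + [
            f"r{i}{j}" for i in range(3) for j in range(3)
        ] + ["quality"]
        out = ensure_dir(run_dir / "shapes")
        pd.DataFrame(rows, columns=cols).to_csv(out / "shapes.csv", index=False)
    elif stage == "extract":
        tsrc = _require(run_dir / "tracks" / "tracks.csv", "extract", "track")
        ssrc = _require(run_dir / "shapes" / "shapes.csv", "extract", "segment")
        import pandas as pd

        from .roi import RoiShape

        rec = load_preprocessed_recording(cfg)
        tracks = read_tracks(tsrc)
        sdf = pd.read_csv(ssrc)
        shapes = {}
        for r in sdf.itertuples():
            R = np.array([[getattr(r, f"r{i}{j}") for j in range(3)] for i in range(3)])
            shapes[int(r.track_id)] = RoiShape(
                center=np.zeros(3), semi_axes=np.array([r.a_um, r.b_um, r.c_um]),
                orientation=R, quality=float(r.quality),
            )
        traces = extract_all_traces(rec, tracks, shapes, window=cfg.trace.window)
        out = ensure_dir(run_dir / "traces")
        write_traces(traces, out / "traces.csv")
        flags = {
            tr.track_id: {
                "frames": tr.frames.tolist(),
                "inferred": tr.frames_inferred.astype(int).tolist(),
            }
            for tr in traces
        }
        (out / "trace_flags.json").write_text(json.dumps(flags, indent=1))
    elif stage == "identify":
        tsrc = _require(run_dir / "tracks" / "tracks.csv", "identify", "track")
        trsrc = _require(run_dir / "traces" / "traces.csv", "identify", "extract")
        import pandas as pd

        from .traces import Trace

        tracks = read_tracks(tsrc)
        tdf = pd.read_csv(trsrc, index_col="t")
        traces = []
        for col in tdf.columns:
            v = tdf[col].to_numpy()
            ok = np.isfinite(v)
            traces.append(Trace(track_id=int(col), frames=np.nonzero(ok)[0], values=v[ok]))
        idc = cfg.identification
        atlas = load_atlas(idc.atlas) if idc.atlas else default_atlas()
        assignment, frame, stats = identify_tracks(
            tracks, traces, np.asarray(idc.head_direction), atlas=atlas,
            lambda_corr=idc.lambda_corr, collinearity_tol=idc.collinearity_tol,
            axis_angle_tol_deg=idc.axis_angle_tol_deg,
        )
        out = ensure_dir(run_dir / "identities")
        rows = [
            (tid, cls, assignment.costs.get(tid, np.nan), assignment.groups.get(tid, ""))
            for tid, cls in sorted(assignment.mapping.items())
        ]
        pd.DataFrame(rows, columns=["track_id", "class_name", "cost", "group"]).to_csv(
            out / "identities.csv", index=False
        )
        meta = {
            "seed_six": assignment.seed_six,
            "unassigned": assignment.unassigned,
            "c_mu": stats.c_mu,
            "c_sigma": stats.c_sigma,
            "frame_origin": frame.origin.tolist(),
            "frame_axes": frame.axes.tolist(),
            "frame_scale": frame.scale,
        }
        (out / "identification_meta.json").write_text(json.dumps(meta, indent=1))
    elif stage == "evaluate":
        src = _require(run_dir / "detections" / "detections.csv", "evaluate", "detect")
        if cfg.inputs.ground_truth is None:
            raise StageDependencyError("evaluation needs a ground-truth CSV in the config")
        truth = read_ground_truth(cfg.inputs.ground_truth)
        spots = read_detections(src)
        _, pos0 = truth.frame(0)
        ev = evaluate_detections(spots[0], pos0, radius=cfg.evaluation.radius)
        out = ensure_dir(run_dir / "eval")
        (out / "detection_metrics.json").write_text(json.dumps(ev.rounded() | {
            "accuracy_full": ev.accuracy}, indent=1))
    else:
        raise ValueError(f"unknown stage {stage!r}")


def run_pipeline(cfg: PipelineConfig, run_dir, stages: list[str] | None = None) -> Path:
    """Run the pipeline stages in order and write a manifest.

    Returns the run directory. Stage outputs land in per-stage
    sub-directories; rerunning with the same config and seed reproduces
    identical CSVs.
    """
    run_dir = ensure_dir(run_dir)
    stages = stages or STAGE_ORDER
    bad = [s for s in stages if s not in STAGE_ORDER + ["evaluate"]]
    if bad:
        raise ValueError(f"unknown stages {bad}")
    timings = {}
    for stage in stages:
        t0 = time.time()
        log.info("running stage %s", stage)
        run_stage(stage, cfg, run_dir)
        timings[stage] = round(time.time() - t0, 3)
    manifest = {
        "config_digest": cfg.digest(),
        "config": cfg.to_dict(),
        "version": __version__,
        "seed": cfg.seed,
        "stages": stages,
        "timings_s": timings,
    }
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return run_dir


def simulate_to_dir(sim_cfg: SimConfig, out_dir) -> Path:
    """Render a synthetic recording and write recording + ground truth."""
    out_dir = ensure_dir(out_dir)
    rec, truth, activity = simulate_recording(sim_cfg)
    write_recording(rec, out_dir / "recording.tif")
    write_ground_truth(truth, out_dir / "ground_truth.csv")
    np.savetxt(out_dir / "activity.csv", activity.brightness, delimiter=",")
    (out_dir / "sim_config.yaml").write_text(yaml.safe_dump(dataclasses.asdict(sim_cfg)))
    return out_dir
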
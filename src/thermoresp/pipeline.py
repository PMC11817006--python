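"""Readers/writers, run configuration, and the end-to-end pipeline."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .features import FeatureVector, extract_features
from .preprocess import FilterConfig, preprocess_sequence
from .scoring import (
    FEATURES,
    ScoreModel,
    evaluate,
    fit_model,
    weight_search,
)
from .tracker import BreathTrace, TrackerConfig, track
from .video import PHASE_CODES, FrameSequence, RegionOfInterest

logger = logging.getLogger(__name__)

_LUMA = np.array([0.299, 0.587, 0.114])


def has_video_codec() -> bool:
    """True when an ffmpeg backend for MP4/AVI reading is importable."""
    try:
        import imageio_ffmpeg  # noqa: F401

        return True
    except ImportError:
        return False


def _to_uint8_gray(frames: np.ndarray) -> np.ndarray:
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim == 4:
        if frames.shape[-1] not in (3, 4):
            raise ValueError(f"cannot interpret frame stack of shape {frames.shape}")
        frames = frames[..., :3].astype(np.float64) @ _LUMA
    if frames.dtype != np.uint8:
        data = frames.astype(np.float64)
        lo, hi = data.min(), data.max()
        if lo >= 0 and hi <= 255:
            frames = np.clip(np.round(data), 0, 255).astype(np.uint8)
        elif hi > lo:
            frames = np.round((data - lo) / (hi - lo) * 255.0).astype(np.uint8)
        else:
            frames = np.zeros_like(data, dtype=np.uint8)
    return frames


def read_video(path, fps_override: float | None = None) -> FrameSequence:
    """Load MP4/AVI, multi-page TIFF, or .npy stacks as 8-bit grayscale.

    TIFF and .npy carry no frame rate, so ``fps_override`` is required for
    them; for MP4/AVI the container metadata is used unless overridden.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"video file not found: {path}")
    suffix = path.suffix.lower()
    fps = fps_override
    if suffix in (".tif", ".tiff"):
        frames = tifffile.imread(path)
    elif suffix == ".npy":
        frames = np.load(path)
    elif suffix in (".mp4", ".avi", ".mkv", ".mov"):
        try:
            import imageio.v2 as iio

            reader = iio.get_reader(path, format="FFMPEG")
            meta = reader.get_meta_data()
            if fps is None:
                fps = meta.get("fps")
            frames = np.stack([np.asarray(f) for f in reader])
            reader.close()
        except (ImportError, IndexError, ValueError) as exc:
            raise RuntimeError(
                f"no video backend available to read {path}; install an ffmpeg "
                "plugin for imageio or convert the video to multi-page TIFF"
            ) from exc
    else:
        raise ValueError(f"unsupported video format: {suffix}")
    frames = _to_uint8_gray(frames)
    if frames.shape[0] == 0:
        raise ValueError(f"video {path} contains zero frames")
    if fps is None:
        raise ValueError(
            f"frame rate unknown for {path}; pass fps_override (container has no fps metadata)"
        )
    return FrameSequence(frames=frames, fps=float(fps))


def write_video(seq: FrameSequence, path) -> None:
    """Write a frame stack as multi-page TIFF, .npy, or MP4 (if a backend exists)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, seq.frames, photometric="minisblack")
    elif suffix == ".npy":
        np.save(path, seq.frames)
    elif suffix in (".mp4", ".avi"):
        try:
            import imageio.v2 as iio

            writer = iio.get_writer(
                path, format="FFMPEG", fps=seq.fps, quality=10, macro_block_size=1
            )
            for frame in seq.frames:
                writer.append_data(frame)
            writer.close()
        except (ImportError, IndexError, ValueError) as exc:
            raise RuntimeError(
                f"no video backend available to write {path}; install an ffmpeg "
                "plugin for imageio or write multi-page TIFF instead"
            ) from exc
    else:
        raise ValueError(f"unsupported video format: {suffix}")


def write_trace(trace: BreathTrace, csv_path, summary_path=None) -> None:
    trace.to_dataframe().to_csv(csv_path, index=False)
    if summary_path is not None:
        with open(summary_path, "w") as fh:
            json.dump(
                {
                    "fps": trace.fps,
                    "n_frames": trace.n_frames,
                    "mouth_area": trace.mouth_area,
                    "expiration_starts": [int(i) for i in trace.expiration_starts],
                    "inspiration_starts": [int(i) for i in trace.inspiration_starts],
                    "total_plume": int(trace.plume_counts.sum()),
                },
                fh,
                indent=2,
            )


def read_trace(csv_path, fps: float | None = None) -> BreathTrace:
    """Rebuild a BreathTrace from its CSV; onsets come from phase transitions."""
    df = pd.read_csv(csv_path)
    frames = df["frame"].to_numpy(int)
    times = df["time_s"].to_numpy(float)
    phases = np.array([PHASE_CODES[p] for p in df["phase"]], dtype=np.int8)
    counts = df["plume_count"].to_numpy(np.int64)
    if fps is None:
        dt = np.diff(times)
        if len(dt) == 0 or not np.all(dt > 0):
            raise ValueError("cannot infer fps from trace timestamps; pass fps")
        fps = 1.0 / float(np.median(dt))
    exp_starts, insp_starts = [], []
    for j in range(1, len(phases)):
        if phases[j] != phases[j - 1]:
            if phases[j] == PHASE_CODES["expiration"]:
                exp_starts.append(int(frames[j]))
            elif phases[j] == PHASE_CODES["inspiration"]:
                insp_starts.append(int(frames[j]))
    return BreathTrace(
        frame_indices=frames,
        times=times,
        phases=phases,
        plume_counts=counts,
        expiration_starts=exp_starts,
        inspiration_starts=insp_starts,
        fps=fps,
        mouth_area=int(counts.max(initial=0)),
    )


def features_to_frame(rows: dict[str, FeatureVector], labels: dict | None = None) -> pd.DataFrame:
    records = []
    for sid, fv in rows.items():
        rec = {"subject_id": sid, **fv.as_dict()}
        if labels is not None and sid in labels:
            rec["label"] = labels[sid]
        records.append(rec)
    return pd.DataFrame(records)


@dataclass
class SubjectSpec:
    subject_id: str
    video: str
    chest_roi: RegionOfInterest
    mouth_roi: RegionOfInterest
    label: int | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "SubjectSpec":
        missing = [k for k in ("id", "video", "chest_roi", "mouth_roi") if k not in d]
        if missing:
            raise ValueError(f"subject entry missing required keys: {missing}")
        chest = RegionOfInterest.from_dict({**d["chest_roi"], "role": "chest"})
        mouth = RegionOfInterest.from_dict({**d["mouth_roi"], "role": "mouth"})
        return cls(
            subject_id=str(d["id"]),
            video=str(d["video"]),
            chest_roi=chest,
            mouth_roi=mouth,
            label=None if d.get("label") is None else int(d["label"]),
        )


@dataclass
class PipelineConfig:
    """Everything a full run needs: subjects, stage settings, output paths."""

    subjects: list[SubjectSpec]
    output_dir: str = "thermoresp_out"
    fps_override: float | None = None
    filter_cfg: FilterConfig = field(default_factory=FilterConfig)
    tracker_cfg: TrackerConfig = field(default_factory=TrackerConfig)
    trr_per_minute: bool = False
    scoring_mode: str = "search"  # search | fixed | none
    weights: dict | None = None
    n_iter: int = 1000
    weight_range: tuple[int, int] = (1, 50)
    rng_seed: int = 0
    feature_subset: list[str] = field(default_factory=lambda: list(FEATURES))
    plot: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw, base_dir=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base_dir: Path | None = None) -> "PipelineConfig":
        subjects = [SubjectSpec.from_dict(d) for d in raw.get("subjects", [])]
        if not subjects:
            raise ValueError("config lists no subjects")
        if base_dir is not None:
            for s in subjects:
                p = Path(s.video)
                if not p.is_absolute():
                    s.video = str(base_dir / p)
        scoring = raw.get("scoring", {})
        cfg = cls(
            subjects=subjects,
            output_dir=str(raw.get("output_dir", "thermoresp_out")),
            fps_override=raw.get("fps_override"),
            filter_cfg=FilterConfig(**raw.get("filter", {})),
            tracker_cfg=TrackerConfig(**raw.get("tracker", {})),
            trr_per_minute=bool(raw.get("features", {}).get("trr_per_minute", False)),
            scoring_mode=str(scoring.get("mode", "search")),
            weights=scoring.get("weights"),
            n_iter=int(scoring.get("n_iter", 1000)),
            weight_range=tuple(scoring.get("weight_range", (1, 50))),
            rng_seed=int(scoring.get("rng_seed", 0)),
            feature_subset=list(scoring.get("feature_subset", FEATURES)),
            plot=bool(raw.get("plot", False)),
        )
        if cfg.scoring_mode == "fixed" and not cfg.weights:
            raise ValueError("scoring mode 'fixed' requires explicit weights")
        if base_dir is not None and not Path(cfg.output_dir).is_absolute():
            cfg.output_dir = str(base_dir / cfg.output_dir)
        return cfg


def plot_trace(trace: BreathTrace, path) -> None:
    """Phase/volume trace figure (optional report extra)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(10, 5))
    ax1.step(trace.times, trace.phases, where="post", lw=1)
    ax1.set_yticks([0, 1, 2], ["undet.", "insp.", "exp."])
    ax1.set_ylabel("phase")
    ax2.plot(trace.times, trace.plume_counts, lw=1)
    for t in trace.expiration_start_times():
        ax2.axvline(t, color="purple", ls="--", lw=0.8)
    for t in trace.inspiration_start_times():
        ax2.axvline(t, color="gold", ls="--", lw=0.8)
    ax2.set_xlabel("time (s)")
    ax2.set_ylabel("plume pixels")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: PipelineConfig):
    """Read -> preprocess -> track -> features per subject, then fit and score.

    Returns ``(features_df, model, report)``; model/report are None when no
    labels are available or scoring is disabled. All artifacts are written
    under ``config.output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_log: dict = {
        "version": __version__,
        "tracker": vars(config.tracker_cfg).copy(),
        "filter": vars(config.filter_cfg).copy(),
        "scoring_mode": config.scoring_mode,
        "rng_seed": config.rng_seed,
        "n_iter": config.n_iter,
        "weight_range": list(config.weight_range),
        "feature_subset": config.feature_subset,
        "subjects": {},
    }

    feature_rows: dict[str, FeatureVector] = {}
    labels: dict[str, int] = {}
    for spec in config.subjects:
        t0 = time.time()
        try:
            seq = read_video(spec.video, fps_override=config.fps_override)
            spec.chest_roi.validate_within(seq.frame_shape)
            spec.mouth_roi.validate_within(seq.frame_shape)
            seq = preprocess_sequence(seq, config.filter_cfg)
            trace = track(seq, spec.chest_roi, spec.mouth_roi, config.tracker_cfg)
            fv = extract_features(trace, trr_per_minute=config.trr_per_minute)
            write_trace(
                trace,
                out / f"trace_{spec.subject_id}.csv",
                out / f"trace_{spec.subject_id}.json",
            )
            if config.plot:
                plot_trace(trace, out / f"trace_{spec.subject_id}.png")
            if not fv.is_complete():
                logger.warning(
                    "subject %s has undefined interval features; excluded from fitting",
                    spec.subject_id,
                )
                run_log["subjects"][spec.subject_id] = "excluded: undefined features"
                continue
            feature_rows[spec.subject_id] = fv
            if spec.label is not None:
                labels[spec.subject_id] = spec.label
            run_log["subjects"][spec.subject_id] = f"ok ({time.time() - t0:.1f}s)"
        except Exception as exc:  # noqa: BLE001 - per-subject isolation
            logger.error("subject %s failed: %s", spec.subject_id, exc)
            run_log["subjects"][spec.subject_id] = f"failed: {exc}"

    features_df = features_to_frame(feature_rows, labels)
    features_df.to_csv(out / "features.csv", index=False)

    model, report = None, None
    if config.scoring_mode != "none" and "label" in features_df.columns:
        y = features_df["label"].to_numpy(int).astype(bool)
        if y.sum() < 2 or (~y).sum() < 2:
            raise ValueError(
                "cohort-level fit needs at least 2 subjects per class after tracking"
            )
        if config.scoring_mode == "fixed":
            model, report = fit_model(
                features_df, y, config.weights, config.feature_subset
            )
        else:
            model, _log = weight_search(
                features_df,
                y,
                n_iter=config.n_iter,
                weight_range=config.weight_range,
                rng_seed=config.rng_seed,
                feature_subset=config.feature_subset,
            )
            _log.to_csv(out / "search_log.csv", index=False)
            report = evaluate(y, model.predict(features_df))
        model.to_json(out / "model.json")
        with open(out / "report.json", "w") as fh:
            json.dump(report.to_dict(rounded=True), fh, indent=2)
        (out / "confusion.txt").write_text(report.confusion_text())

    with open(out / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2, default=str)
    return features_df, model, report
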
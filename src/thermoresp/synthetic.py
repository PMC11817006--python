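"""Synthetic thermal breathing videos with exact ground-truth annotations.

The renderer produces the two signals the analysis pipeline relies on:

* a textured, high-contrast chest band that translates vertically
  (upward during inspiration, back down during expiration), and
* a warm exhalation plume in front of the mouth whose intensity follows a
  raised-cosine envelope over each expiration.

Noise (salt-and-pepper, additive Gaussian, drifting warm ambient blobs) is
applied on top of the clean render; the ground truth is always derived from
the clean frames.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter as _smooth

from .video import (
    PHASE_EXPIRATION,
    PHASE_INSPIRATION,
    FrameSequence,
    RegionOfInterest,
)

INSPIRATION = "inspiration"
EXPIRATION = "expiration"

# Cohort-level feature means used as simulation defaults
# (control group first, positive/COPD-like group second).
DEFAULT_GROUP_MEANS = {
    "control": {"trv": 292_177.0, "ade_s": 1.652137, "adi_s": 1.260358, "trr": 15.75},
    "copd": {"trv": 720_140.0, "ade_s": 1.007284, "adi_s": 1.141885, "trr": 20.825},
}
DEFAULT_GROUP_SDS = {
    "control": {"trv": 150_000.0, "ade_s": 0.45, "adi_s": 0.35, "trr": 3.5},
    "copd": {"trv": 150_000.0, "ade_s": 0.45, "adi_s": 0.35, "trr": 3.5},
}
FEATURE_COLUMNS = ["trv", "ade_s", "adi_s", "trr"]


@dataclass
class BreathProgram:
    """Per-breath timing and signal-strength parameters.

    ``expiration_durations`` / ``inspiration_durations`` are seconds per
    breath; the program is cycled (or truncated) to cover the requested
    video duration.
    """

    expiration_durations: np.ndarray
    inspiration_durations: np.ndarray
    plume_intensity: float = 80.0
    chest_amplitude: float = 6.0
    start_phase: str = EXPIRATION

    def __post_init__(self) -> None:
        self.expiration_durations = np.atleast_1d(
            np.asarray(self.expiration_durations, dtype=float)
        )
        self.inspiration_durations = np.atleast_1d(
            np.asarray(self.inspiration_durations, dtype=float)
        )
        if len(self.expiration_durations) != len(self.inspiration_durations):
            raise ValueError("expiration and inspiration duration lists must align")
        if np.any(self.expiration_durations <= 0) or np.any(self.inspiration_durations <= 0):
            raise ValueError("all breath durations must be positive")
        if self.plume_intensity < 0:
            raise ValueError("plume_intensity must be >= 0")
        if self.start_phase not in (INSPIRATION, EXPIRATION):
            raise ValueError(f"start_phase must be inspiration|expiration, got {self.start_phase}")

    @property
    def n_breaths(self) -> int:
        return len(self.expiration_durations)

    @classmethod
    def regular(
        cls,
        n_breaths: int,
        expiration_s: float,
        inspiration_s: float,
        plume_intensity: float = 80.0,
        chest_amplitude: float = 6.0,
        start_phase: str = EXPIRATION,
    ) -> "BreathProgram":
        """A strictly periodic program of ``n_breaths`` identical breaths."""
        return cls(
            expiration_durations=np.full(n_breaths, float(expiration_s)),
            inspiration_durations=np.full(n_breaths, float(inspiration_s)),
            plume_intensity=plume_intensity,
            chest_amplitude=chest_amplitude,
            start_phase=start_phase,
        )


@dataclass
class NoiseSpec:
    """Corruption model: impulse noise, sensor noise, and ambient warm blobs."""

    salt_pepper_fraction: float = 0.0
    gaussian_sigma: float = 0.0
    ambient_blob_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.salt_pepper_fraction <= 1.0:
            raise ValueError("salt_pepper_fraction must be in [0, 1]")
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be >= 0")
        if self.ambient_blob_rate < 0:
            raise ValueError("ambient_blob_rate must be >= 0")

    @property
    def is_null(self) -> bool:
        return (
            self.salt_pepper_fraction == 0
            and self.gaussian_sigma == 0
            and self.ambient_blob_rate == 0
        )


@dataclass
class GroundTruth:
    """Frame-accurate annotation of a rendered video."""

    phases: np.ndarray  # int8 phase code per frame
    expiration_start_times: list
    inspiration_start_times: list
    expiration_start_frames: list
    inspiration_start_frames: list
    plume_counts: np.ndarray  # int per frame, 0 outside expiration
    fps: float

    def __post_init__(self) -> None:
        for times in (self.expiration_start_times, self.inspiration_start_times):
            if np.any(np.diff(times) <= 0):
                raise ValueError("start times must be strictly increasing")

    def n_breaths(self, window_end: float | None = None) -> int:
        """Number of expiration onsets (optionally within ``[0, window_end)``)."""
        if window_end is None:
            return len(self.expiration_start_times)
        return int(sum(t < window_end for t in self.expiration_start_times))

    def total_plume(self, window_end: float | None = None) -> int:
        if window_end is None:
            return int(self.plume_counts.sum())
        n = int(round(window_end * self.fps))
        return int(self.plume_counts[:n].sum())

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "fps": self.fps,
                    "phases": [int(p) for p in self.phases],
                    "expiration_start_times": [float(t) for t in self.expiration_start_times],
                    "inspiration_start_times": [float(t) for t in self.inspiration_start_times],
                    "expiration_start_frames": [int(i) for i in self.expiration_start_frames],
                    "inspiration_start_frames": [int(i) for i in self.inspiration_start_frames],
                    "plume_counts": [int(c) for c in self.plume_counts],
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            phases=np.asarray(d["phases"], dtype=np.int8),
            expiration_start_times=d["expiration_start_times"],
            inspiration_start_times=d["inspiration_start_times"],
            expiration_start_frames=d["expiration_start_frames"],
            inspiration_start_frames=d["inspiration_start_frames"],
            plume_counts=np.asarray(d["plume_counts"], dtype=np.int64),
            fps=float(d["fps"]),
        )


def default_rois(frame_shape: tuple[int, int]) -> tuple[RegionOfInterest, RegionOfInterest]:
    """Chest / mouth ROI layout for a side-view subject, scaled to the frame."""
    h, w = frame_shape
    chest = RegionOfInterest(
        x=int(0.08 * w), y=int(0.40 * h), width=int(0.30 * w), height=int(0.48 * h), role="chest"
    )
    mouth = RegionOfInterest(
        x=int(0.52 * w), y=int(0.10 * h), width=int(0.38 * w), height=int(0.45 * h), role="mouth"
    )
    return chest, mouth


def _phase_segments(program: BreathProgram, duration: float):
    """Alternating (start_time, phase) segments cycling the program to cover
    ``[0, duration)``."""
    segments = []
    t = 0.0
    breath = 0
    if program.start_phase == EXPIRATION:
        order = ("exp", "insp")
    else:
        order = ("insp", "exp")
    while t < duration:
        i = breath % program.n_breaths
        for kind in order:
            if t >= duration:
                break
            d = (
                program.expiration_durations[i]
                if kind == "exp"
                else program.inspiration_durations[i]
            )
            segments.append((t, kind, float(d)))
            t += float(d)
        breath += 1
    return segments


def _chest_displacement(program: BreathProgram, segments, times: np.ndarray) -> np.ndarray:
    """Piecewise-linear vertical displacement of the chest band.

    Displacement is in image rows: 0 = rest (end of expiration),
    ``-chest_amplitude`` = fully risen chest (end of inspiration).  Constant
    speed within each phase gives a first-frame-detectable flow signal.
    """
    a = program.chest_amplitude
    disp = np.zeros_like(times)
    for start, kind, dur in segments:
        end = start + dur
        mask = (times >= start - 1e-9) & (times < end - 1e-9)
        if not np.any(mask):
            continue
        u = (times[mask] - start) / dur
        if kind == "insp":  # chest rises: 0 -> -a
            disp[mask] = -a * u
        else:  # expiration: chest falls back: -a -> 0
            disp[mask] = -a * (1.0 - u)
    # start_phase boundary: if the program starts with inspiration the chest
    # starts at rest, if with expiration it starts risen; both handled above.
    return disp


def _plume_envelope(segments, times: np.ndarray) -> np.ndarray:
    """Raised-cosine (sin^2) plume envelope, nonzero only during expiration."""
    env = np.zeros_like(times)
    for start, kind, dur in segments:
        if kind != "exp":
            continue
        end = start + dur
        mask = (times >= start - 1e-9) & (times < end - 1e-9)
        u = (times[mask] - start) / dur
        env[mask] = np.sin(np.pi * u) ** 2
    return env


def render_clean_video(
    program: BreathProgram,
    frame_shape: tuple[int, int] = (128, 160),
    fps: float = 30.0,
    duration: float = 40.0,
    chest_roi: RegionOfInterest | None = None,
    mouth_roi: RegionOfInterest | None = None,
    texture_seed: int = 0,
    background: int = 30,
) -> tuple[np.ndarray, GroundTruth]:
    """Render noiseless frames plus their ground truth.

    Returns the raw ``(n_frames, h, w)`` uint8 stack; wrap in
    :class:`FrameSequence` or use :func:`render_video` for the noisy path.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    h, w = frame_shape
    if chest_roi is None or mouth_roi is None:
        d_chest, d_mouth = default_rois(frame_shape)
        chest_roi = chest_roi or d_chest
        mouth_roi = mouth_roi or d_mouth
    for roi in (chest_roi, mouth_roi):
        try:
            roi.validate_within(frame_shape)
        except ValueError as exc:
            raise ValueError(f"frame_shape {frame_shape} too small for ROIs: {exc}") from exc

    n_frames = int(round(duration * fps))
    times = np.arange(n_frames) / fps
    segments = _phase_segments(program, duration)
    disp = _chest_displacement(program, segments, times)
    env = _plume_envelope(segments, times)

    # Per-frame phase labels and onset bookkeeping.
    phases = np.zeros(n_frames, dtype=np.int8)
    exp_times, insp_times, exp_frames, insp_frames = [], [], [], []
    for start, kind, _dur in segments:
        if start >= duration - 1e-9:
            continue
        frame0 = int(math.ceil(start * fps - 1e-9))
        if kind == "exp":
            exp_times.append(start)
            exp_frames.append(frame0)
        else:
            insp_times.append(start)
            insp_frames.append(frame0)
    boundaries = sorted(zip(exp_frames + insp_frames,
                            [PHASE_EXPIRATION] * len(exp_frames)
                            + [PHASE_INSPIRATION] * len(insp_frames)))
    for frame0, code in boundaries:
        phases[frame0:] = code

    # Chest band: Gaussian vertical envelope carrying a frozen smooth texture
    # that translates rigidly with the band (texture gives the flow estimator
    # horizontal gradients; a flat band is aperture-ambiguous).
    rng = np.random.default_rng(texture_seed)
    band_sigma = max(2.5, chest_roi.height / 8.0)
    margin = int(math.ceil(program.chest_amplitude)) + 8
    tex_h = chest_roi.height + 2 * margin
    texture = _smooth(rng.normal(0.0, 1.0, (tex_h, chest_roi.width)), 2.5)
    texture /= max(np.abs(texture).max(), 1e-12)

    band_center0 = chest_roi.y + chest_roi.height / 2.0
    rows = np.arange(chest_roi.y, chest_roi.y + chest_roi.height)

    # Plume: 2-D Gaussian footprint anchored at the mouth-ROI center.
    cy, cx = mouth_roi.center
    yy, xx = np.mgrid[0:h, 0:w]
    plume_sigma_y = mouth_roi.height / 6.0
    plume_sigma_x = mouth_roi.width / 6.0
    footprint = np.exp(
        -((yy - cy) ** 2) / (2 * plume_sigma_y**2) - ((xx - cx) ** 2) / (2 * plume_sigma_x**2)
    )

    frames = np.empty((n_frames, h, w), dtype=np.uint8)
    base = np.full((h, w), float(background))
    rs, cs = chest_roi.slices()
    for i in range(n_frames):
        img = base.copy()
        center = band_center0 + disp[i]
        envelope = np.exp(-((rows - center) ** 2) / (2 * band_sigma**2))
        # sample the rigid texture at rows shifted by the displacement
        pos = rows - disp[i] - chest_roi.y + margin
        i0 = np.clip(np.floor(pos).astype(int), 0, tex_h - 2)
        frac = (pos - i0)[:, None]
        tex = texture[i0, :] * (1 - frac) + texture[i0 + 1, :] * frac
        img[rs, cs] += envelope[:, None] * (120.0 + 80.0 * tex)
        if program.plume_intensity > 0 and env[i] > 0:
            img += program.plume_intensity * env[i] * footprint
        frames[i] = np.clip(np.round(img), 0, 255).astype(np.uint8)

    # Ground-truth plume counts: positive consecutive-frame differences in the
    # mouth ROI on true-expiration frames (the quantity the tracker measures).
    counts = np.zeros(n_frames, dtype=np.int64)
    mrs, mcs = mouth_roi.slices()
    for i in range(1, n_frames):
        if phases[i] == PHASE_EXPIRATION:
            diff = frames[i, mrs, mcs].astype(np.int32) - frames[i - 1, mrs, mcs].astype(np.int32)
            counts[i] = int(np.count_nonzero(diff >= 1))

    gt = GroundTruth(
        phases=phases,
        expiration_start_times=exp_times,
        inspiration_start_times=insp_times,
        expiration_start_frames=exp_frames,
        inspiration_start_frames=insp_frames,
        plume_counts=counts,
        fps=fps,
    )
    return frames, gt


def apply_noise(frames: np.ndarray, noise: NoiseSpec, fps: float) -> np.ndarray:
    """Corrupt a clean uint8 stack. Deterministic given ``noise.rng_seed``."""
    if noise.is_null:
        return frames.copy()
    rng = np.random.default_rng(noise.rng_seed)
    n_frames, h, w = frames.shape
    out = frames.astype(np.float64)

    if noise.ambient_blob_rate > 0:
        duration = n_frames / fps
        n_blobs = rng.poisson(noise.ambient_blob_rate * duration)
        yy, xx = np.mgrid[0:h, 0:w]
        for _ in range(n_blobs):
            t0 = rng.uniform(0, duration)
            life = rng.uniform(0.8, 3.0)
            y0, x0 = rng.uniform(0, h), rng.uniform(0, w)
            vy, vx = rng.uniform(-6, 6, size=2)  # px/s drift
            sigma = rng.uniform(2.5, 5.0)
            amp = rng.uniform(8.0, 20.0)
            f0 = max(0, int(t0 * fps))
            f1 = min(n_frames, int((t0 + life) * fps))
            for i in range(f0, f1):
                t = i / fps - t0
                u = t / life
                temporal = math.sin(math.pi * min(max(u, 0.0), 1.0)) ** 2
                cy, cx = y0 + vy * t, x0 + vx * t
                out[i] += amp * temporal * np.exp(
                    -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2)
                )

    if noise.gaussian_sigma > 0:
        out += rng.normal(0.0, noise.gaussian_sigma, out.shape)

    out = np.clip(np.round(out), 0, 255).astype(np.uint8)

    if noise.salt_pepper_fraction > 0:
        n_px = h * w
        n_hit = int(round(noise.salt_pepper_fraction * n_px))
        for i in range(n_frames):
            idx = rng.choice(n_px, size=n_hit, replace=False)
            vals = rng.integers(0, 2, size=n_hit) * 255
            flat = out[i].reshape(-1)
            flat[idx] = vals.astype(np.uint8)
    return out


def render_video(
    program: BreathProgram,
    noise: NoiseSpec | None = None,
    frame_shape: tuple[int, int] = (128, 160),
    fps: float = 30.0,
    duration: float = 40.0,
    chest_roi: RegionOfInterest | None = None,
    mouth_roi: RegionOfInterest | None = None,
) -> tuple[FrameSequence, GroundTruth]:
    """Render a (possibly noisy) synthetic breathing video with ground truth.

    Ground truth always describes the clean render; noise corrupts only the
    returned pixel data.
    """
    noise = noise or NoiseSpec()
    clean, gt = render_clean_video(
        program,
        frame_shape=frame_shape,
        fps=fps,
        duration=duration,
        chest_roi=chest_roi,
        mouth_roi=mouth_roi,
        texture_seed=noise.rng_seed,
    )
    noisy = apply_noise(clean, noise, fps)
    return FrameSequence(frames=noisy, fps=fps), gt


def sample_feature_table(
    n_per_group: int,
    group_means: dict | None = None,
    group_sds: dict | None = None,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Draw a two-group labeled feature table from per-group normal models.

    Columns: ``subject_id, trv, ade_s, adi_s, trr, label`` with label 1 for
    the positive (COPD-like) group. Negative draws of positive-valued
    features are clipped at a small positive floor.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    means = group_means or DEFAULT_GROUP_MEANS
    sds = group_sds or DEFAULT_GROUP_SDS
    for grp in ("control", "copd"):
        if any(sds[grp][c] < 0 for c in FEATURE_COLUMNS):
            raise ValueError("standard deviations must be >= 0")
    rng = np.random.default_rng(rng_seed)
    rows = []
    for grp, label in (("control", 0), ("copd", 1)):
        for k in range(n_per_group):
            row = {"subject_id": f"{grp}_{k:03d}", "label": label}
            for col in FEATURE_COLUMNS:
                v = rng.normal(means[grp][col], sds[grp][col])
                row[col] = max(v, 1e-6) if col != "trv" else max(v, 0.0)
            rows.append(row)
    return pd.DataFrame(rows, columns=["subject_id"] + FEATURE_COLUMNS + ["label"])
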
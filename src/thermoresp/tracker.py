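"""Dual-ROI respiration tracking.

The chest ROI drives a two-state phase machine from the mean vertical
component of dense optical flow; the mouth ROI accumulates the count of
pixels whose intensity rose by at least ``diff_threshold`` between
consecutive frames, but only while the chest is in expiration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.registration import optical_flow_ilk

from .video import (
    PHASE_EXPIRATION,
    PHASE_INSPIRATION,
    PHASE_NAMES,
    PHASE_UNDETERMINED,
    FrameSequence,
    RegionOfInterest,
)


@dataclass
class TrackerConfig:
    """Thresholds and window for respiration tracking.

    ``flow_threshold`` (px/frame) suppresses sub-threshold chest jitter;
    ``diff_threshold`` (grayscale units) is the minimum positive pixel change
    counted as plume; the analysis window is ``[window_start, window_end)``
    seconds. ``chest_sign_convention=True`` means a rising chest (negative
    vertical flow in image coordinates) marks inspiration.
    """

    flow_threshold: float = 0.05
    diff_threshold: float = 1.0
    window_start: float = 0.0
    window_end: float = 40.0
    chest_sign_convention: bool = True
    reset_on_inspiration: bool = True
    flow_radius: int = 7

    def __post_init__(self) -> None:
        if self.window_end <= self.window_start:
            raise ValueError("window_end must exceed window_start")
        if self.flow_threshold < 0 or self.diff_threshold < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass
class BreathTrace:
    """Per-frame phase labels and plume pixel counts over the window."""

    frame_indices: np.ndarray
    times: np.ndarray
    phases: np.ndarray  # int8 phase codes
    plume_counts: np.ndarray
    expiration_starts: list  # frame indices (into the original sequence)
    inspiration_starts: list
    fps: float
    mouth_area: int

    @property
    def n_frames(self) -> int:
        return len(self.frame_indices)

    @property
    def window_duration(self) -> float:
        return self.n_frames / self.fps

    def expiration_start_times(self) -> np.ndarray:
        return np.asarray(self.expiration_starts, dtype=float) / self.fps

    def inspiration_start_times(self) -> np.ndarray:
        return np.asarray(self.inspiration_starts, dtype=float) / self.fps

    def phase_names(self) -> list[str]:
        return [PHASE_NAMES[int(p)] for p in self.phases]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": self.frame_indices,
                "time_s": self.times,
                "phase": self.phase_names(),
                "plume_count": self.plume_counts,
            }
        )


def _mean_vertical_flow(prev: np.ndarray, curr: np.ndarray, radius: int) -> float:
    """Mean vertical (row-axis) dense optical flow; positive = downward."""
    v, _u = optical_flow_ilk(
        prev.astype(np.float32), curr.astype(np.float32), radius=radius
    )
    return float(v.mean())


def chest_flow(
    prev_frame: np.ndarray,
    curr_frame: np.ndarray,
    roi: RegionOfInterest,
    radius: int = 7,
) -> float:
    """Mean vertical displacement (px/frame) of the chest ROI between frames.

    Positive values are downward in image coordinates (chest falling).
    """
    if prev_frame.shape != curr_frame.shape:
        raise ValueError("frames must share one shape")
    roi.validate_within(prev_frame.shape)
    return _mean_vertical_flow(roi.crop(prev_frame), roi.crop(curr_frame), radius)


def update_phase(state: int, flow: float, cfg: TrackerConfig) -> int:
    """Two-state phase rule with a dead zone.

    Sub-threshold flow holds the current state; otherwise the sign decides:
    with the default convention, negative (upward) flow = inspiration.
    """
    if abs(flow) <= cfg.flow_threshold:
        return state
    upward = flow < 0
    if cfg.chest_sign_convention:
        return PHASE_INSPIRATION if upward else PHASE_EXPIRATION
    return PHASE_EXPIRATION if upward else PHASE_INSPIRATION


def count_plume_pixels(
    prev_frame: np.ndarray,
    curr_frame: np.ndarray,
    roi: RegionOfInterest,
    diff_threshold: float = 1.0,
) -> int:
    """Number of ROI pixels that brightened by at least ``diff_threshold``."""
    if prev_frame.shape != curr_frame.shape:
        raise ValueError("frames must share one shape")
    roi.validate_within(prev_frame.shape)
    diff = roi.crop(curr_frame).astype(np.float64) - roi.crop(prev_frame).astype(np.float64)
    return int(np.count_nonzero(diff >= diff_threshold))


def track(
    seq: FrameSequence,
    chest_roi: RegionOfInterest,
    mouth_roi: RegionOfInterest,
    cfg: TrackerConfig | None = None,
) -> BreathTrace:
    """Run the dual-ROI tracker over the analysis window.

    Plume counts are recorded only on frames classified as expiration and are
    forced to 0 otherwise. With ``reset_on_inspiration`` the difference
    reference follows the previous frame (so the first expiration frame
    differences against the end of inspiration); without it, the reference
    freezes at the last expiration frame while the chest is not exhaling.
    """
    cfg = cfg or TrackerConfig()
    chest_roi.validate_within(seq.frame_shape)
    mouth_roi.validate_within(seq.frame_shape)
    if seq.duration + 1e-9 < cfg.window_end:
        raise ValueError(
            f"video duration {seq.duration:.2f}s is shorter than the required "
            f"analysis window end {cfg.window_end:.2f}s"
        )
    start = int(np.ceil(cfg.window_start * seq.fps - 1e-9))
    end = int(round(cfg.window_end * seq.fps))
    idx = np.arange(start, end)
    n = len(idx)

    phases = np.full(n, PHASE_UNDETERMINED, dtype=np.int8)
    counts = np.zeros(n, dtype=np.int64)
    exp_starts: list[int] = []
    insp_starts: list[int] = []

    frames = seq.frames
    state = PHASE_UNDETERMINED
    ref = frames[idx[0]]
    chest_prev = chest_roi.crop(frames[idx[0]])
    for j in range(1, n):
        i = idx[j]
        chest_curr = chest_roi.crop(frames[i])
        flow = _mean_vertical_flow(chest_prev, chest_curr, cfg.flow_radius)
        chest_prev = chest_curr
        new_state = update_phase(state, flow, cfg)
        if new_state != state:
            if new_state == PHASE_EXPIRATION:
                exp_starts.append(int(i))
            elif new_state == PHASE_INSPIRATION:
                insp_starts.append(int(i))
                if cfg.reset_on_inspiration:
                    ref = frames[i]
        state = new_state
        phases[j] = state
        if state == PHASE_EXPIRATION:
            counts[j] = count_plume_pixels(ref, frames[i], mouth_roi, cfg.diff_threshold)
            ref = frames[i]
        elif cfg.reset_on_inspiration:
            ref = frames[i]

    return BreathTrace(
        frame_indices=idx,
        times=idx / seq.fps,
        phases=phases,
        plume_counts=counts,
        expiration_starts=exp_starts,
        inspiration_starts=insp_starts,
        fps=seq.fps,
        mouth_area=mouth_roi.area,
    )
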
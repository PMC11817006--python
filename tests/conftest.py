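import numpy as np
import pytest

from thermoresp.synthetic import BreathProgram, NoiseSpec, default_rois, render_video
from thermoresp.tracker import BreathTrace
from thermoresp.video import PHASE_CODES


@pytest.fixture(scope="session")
def regular_video():
    """Noiseless periodic breathing video (period 5 s, fps 10, 42 s)."""
    program = BreathProgram.regular(
        n_breaths=5, expiration_s=2.5, inspiration_s=2.5,
        plume_intensity=80.0, chest_amplitude=6.0,
    )
    seq, gt = render_video(
        program, NoiseSpec(rng_seed=1), frame_shape=(96, 128), fps=10.0, duration=42.0
    )
    chest, mouth = default_rois((96, 128))
    return seq, gt, chest, mouth


def make_trace(
    phase_names: list[str],
    counts: list[int] | None = None,
    fps: float = 10.0,
) -> BreathTrace:
    """Hand-build a BreathTrace from per-frame phase names."""
    phases = np.array([PHASE_CODES[p] for p in phase_names], dtype=np.int8)
    counts = np.zeros(len(phases), dtype=np.int64) if counts is None else np.asarray(
        counts, dtype=np.int64
    )
    exp_starts, insp_starts = [], []
    for j in range(1, len(phases)):
        if phases[j] != phases[j - 1]:
            if phases[j] == PHASE_CODES["expiration"]:
                exp_starts.append(j)
            elif phases[j] == PHASE_CODES["inspiration"]:
                insp_starts.append(j)
    if phases[0] == PHASE_CODES["expiration"]:
        exp_starts.insert(0, 0)
    elif phases[0] == PHASE_CODES["inspiration"]:
        insp_starts.insert(0, 0)
    return BreathTrace(
        frame_indices=np.arange(len(phases)),
        times=np.arange(len(phases)) / fps,
        phases=phases,
        plume_counts=counts,
        expiration_starts=exp_starts,
        inspiration_starts=insp_starts,
        fps=fps,
        mouth_area=10_000,
    )
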
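"""Per-frame denoising chain: normalize -> median -> Gaussian -> bilateral.

All filters use reflect padding and accept either a single 2-D frame or a
(n_frames, h, w) stack (the window is always 2-D, applied frame by frame).
Integer input comes back as uint8; float input stays float for exact
comparison against per-window oracle implementations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .video import FrameSequence


@dataclass
class FilterConfig:
    """Configuration of the denoising chain.

    A kernel of 1 disables the corresponding filter (a 1x1 window is the
    identity for all three filters); ``normalize=False`` skips scaling.
    """

    median_kernel: int = 5
    gaussian_kernel: int = 5
    gaussian_sigma: float | None = None  # None -> derived from kernel size
    bilateral_kernel: int = 9
    bilateral_sigma_space: float = 2.0
    bilateral_sigma_range: float = 25.0
    normalize: bool = True
    low_pct: float = 1.0
    high_pct: float = 99.0

    def __post_init__(self) -> None:
        for name in ("median_kernel", "gaussian_kernel", "bilateral_kernel"):
            k = getattr(self, name)
            if k < 1 or k % 2 == 0:
                raise ValueError(f"{name} must be odd and >= 1, got {k}")

    @classmethod
    def disabled(cls) -> "FilterConfig":
        return cls(median_kernel=1, gaussian_kernel=1, bilateral_kernel=1, normalize=False)


def default_gaussian_sigma(kernel: int) -> float:
    """Conventional sigma-from-kernel rule: 0.3*((k-1)/2 - 1) + 0.8."""
    return 0.3 * ((kernel - 1) / 2.0 - 1.0) + 0.8


def gaussian_kernel_2d(kernel: int, sigma: float) -> np.ndarray:
    """Normalized truncated 2-D Gaussian kernel."""
    if kernel % 2 == 0:
        raise ValueError(f"kernel must be odd, got {kernel}")
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    half = kernel // 2
    ax = np.arange(-half, half + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    k = np.exp(-(xx**2 + yy**2) / (2.0 * sigma**2))
    return k / k.sum()


def _restore_dtype(out: np.ndarray, template: np.ndarray) -> np.ndarray:
    if np.issubdtype(template.dtype, np.integer):
        return np.clip(np.round(out), 0, 255).astype(np.uint8)
    return out


def normalize_sequence(
    seq: FrameSequence, low_pct: float = 1.0, high_pct: float = 99.0
) -> FrameSequence:
    """Percentile-based global intensity rescale to the full [0, 255] range.

    The low/high percentiles are computed over the whole stack so that the
    mapping is consistent across frames. Degenerate (constant) sequences
    produce all-zero output with a warning rather than an error.
    """
    if not (0 <= low_pct < high_pct <= 100):
        raise ValueError(f"need 0 <= low_pct < high_pct <= 100, got ({low_pct}, {high_pct})")
    data = seq.frames.astype(np.float64)
    lo, hi = np.percentile(data, [low_pct, high_pct])
    if hi <= lo:
        warnings.warn(
            "sequence has zero dynamic range between the requested percentiles; "
            "returning all-zero frames",
            RuntimeWarning,
            stacklevel=2,
        )
        return FrameSequence(frames=np.zeros_like(seq.frames, dtype=np.uint8), fps=seq.fps)
    scaled = (data - lo) / (hi - lo) * 255.0
    out = np.clip(np.round(scaled), 0, 255).astype(np.uint8)
    return FrameSequence(frames=out, fps=seq.fps)


def median_filter(frame: np.ndarray, kernel: int = 5) -> np.ndarray:
    """Median of the k x k window centered on each pixel (reflect borders)."""
    if kernel % 2 == 0:
        raise ValueError(f"median kernel must be odd, got {kernel}")
    if kernel == 1:
        return frame.copy()
    frame = np.asarray(frame)
    size = (1, kernel, kernel) if frame.ndim == 3 else (kernel, kernel)
    return ndimage.median_filter(frame, size=size, mode="reflect")


def gaussian_filter(frame: np.ndarray, kernel: int = 5, sigma: float | None = None) -> np.ndarray:
    """Convolution with the normalized truncated Gaussian kernel."""
    if kernel % 2 == 0:
        raise ValueError(f"gaussian kernel must be odd, got {kernel}")
    if sigma is not None and sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if kernel == 1:
        return np.asarray(frame).copy()
    sigma = default_gaussian_sigma(kernel) if sigma is None else sigma
    frame = np.asarray(frame)
    k2 = gaussian_kernel_2d(kernel, sigma)
    weights = k2[None, :, :] if frame.ndim == 3 else k2
    out = ndimage.correlate(frame.astype(np.float64), weights, mode="reflect")
    return _restore_dtype(out, frame)


def bilateral_filter(
    frame: np.ndarray,
    kernel: int = 9,
    sigma_space: float = 2.0,
    sigma_range: float = 25.0,
) -> np.ndarray:
    """Edge-preserving filter: spatial-Gaussian x range-Gaussian weighting.

    Each output pixel is the normalized sum over the k x k window of
    ``Gs(spatial distance) * Gr(intensity difference) * neighbor``.
    """
    if kernel % 2 == 0:
        raise ValueError(f"bilateral kernel must be odd, got {kernel}")
    if sigma_space <= 0 or sigma_range <= 0:
        raise ValueError("bilateral sigmas must be positive")
    frame = np.asarray(frame)
    if kernel == 1:
        return frame.copy()
    squeeze = frame.ndim == 2
    is_int = np.issubdtype(frame.dtype, np.integer)
    stack = frame[None] if squeeze else frame
    work = stack.astype(np.int16 if is_int else np.float64)
    half = kernel // 2
    # edge-inclusive reflection, matching scipy.ndimage mode="reflect"
    padded = np.pad(work, ((0, 0), (half, half), (half, half)), mode="symmetric")
    # float32 accumulation for 8-bit input: worst-case error ~1e-3 gray
    # levels, far below the final uint8 quantization step
    acc_dtype = np.float32 if is_int else np.float64
    num = np.zeros(work.shape, dtype=acc_dtype)
    den = np.zeros(work.shape, dtype=acc_dtype)
    h, w = work.shape[1:]
    # 8-bit input: intensity differences are integers in [-255, 255], so the
    # range weight reduces to an exact 511-entry lookup table.
    if is_int:
        diffs = np.arange(-255, 256, dtype=np.float64)
        range_lut = np.exp(-(diffs**2) / (2.0 * sigma_range**2)).astype(np.float32)
    for dy in range(-half, half + 1):
        for dx in range(-half, half + 1):
            gs = math.exp(-(dy * dy + dx * dx) / (2.0 * sigma_space**2))
            neighbor = padded[:, half + dy : half + dy + h, half + dx : half + dx + w]
            if is_int:
                wgt = range_lut[(neighbor - work) + 255]
                wgt *= np.float32(gs)
            else:
                wgt = gs * np.exp(-((neighbor - work) ** 2) / (2.0 * sigma_range**2))
            num += wgt * neighbor
            den += wgt
    out = num / den
    if squeeze:
        out = out[0]
    return _restore_dtype(out, frame)


def preprocess_sequence(seq: FrameSequence, cfg: FilterConfig | None = None) -> FrameSequence:
    """Apply the full chain (normalize, median, Gaussian, bilateral) in order."""
    cfg = cfg or FilterConfig()
    out = seq
    if cfg.normalize:
        out = normalize_sequence(out, cfg.low_pct, cfg.high_pct)
    frames = out.frames
    frames = median_filter(frames, cfg.median_kernel)
    frames = gaussian_filter(frames, cfg.gaussian_kernel, cfg.gaussian_sigma)
    frames = bilateral_filter(
        frames, cfg.bilateral_kernel, cfg.bilateral_sigma_space, cfg.bilateral_sigma_range
    )
    return FrameSequence(frames=frames, fps=seq.fps)
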
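"""Core video data structures shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Integer phase codes used in per-frame phase arrays.
PHASE_UNDETERMINED = 0
PHASE_INSPIRATION = 1
PHASE_EXPIRATION = 2

PHASE_NAMES = {
    PHASE_UNDETERMINED: "undetermined",
    PHASE_INSPIRATION: "inspiration",
    PHASE_EXPIRATION: "expiration",
}
PHASE_CODES = {v: k for k, v in PHASE_NAMES.items()}


@dataclass
class FrameSequence:
    """An ordered stack of grayscale frames with a known frame rate.

    Parameters
    ----------
    frames : ndarray of shape (n_frames, height, width)
        8-bit grayscale pixel data.
    fps : float
        Frames per second; must be positive.
    """

    frames: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a (n_frames, height, width) array, got ndim={self.frames.ndim}"
            )
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration(self) -> float:
        """Video duration in seconds."""
        return self.n_frames / self.fps

    def times(self) -> np.ndarray:
        """Timestamp of each frame in seconds (frame 0 at t=0)."""
        return np.arange(self.n_frames) / self.fps


@dataclass
class RegionOfInterest:
    """A pixel rectangle in frame coordinates.

    Coordinates are 0-based; the rectangle is half-open:
    ``[x, x + width) x [y, y + height)``.
    """

    x: int
    y: int
    width: int
    height: int
    role: str = field(default="chest")

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(
                f"ROI width/height must be positive, got {self.width}x{self.height}"
            )
        if self.x < 0 or self.y < 0:
            raise ValueError(f"ROI origin must be non-negative, got ({self.x}, {self.y})")

    @property
    def area(self) -> int:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        """(row, col) center of the rectangle."""
        return self.y + self.height / 2.0, self.x + self.width / 2.0

    def validate_within(self, frame_shape: tuple[int, int]) -> None:
        h, w = frame_shape
        if self.x + self.width > w or self.y + self.height > h:
            raise ValueError(
                f"ROI {self.role} [{self.x}:{self.x + self.width}, "
                f"{self.y}:{self.y + self.height}] exceeds frame shape {h}x{w}"
            )

    def slices(self) -> tuple[slice, slice]:
        """(row_slice, col_slice) for indexing a frame array."""
        return slice(self.y, self.y + self.height), slice(self.x, self.x + self.width)

    def crop(self, frame: np.ndarray) -> np.ndarray:
        rs, cs = self.slices()
        return frame[..., rs, cs]

    def to_dict(self) -> dict:
        return {
            "x": self.x,
            "y": self.y,
            "width": self.width,
            "height": self.height,
            "role": self.role,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegionOfInterest":
        return cls(
            x=int(d["x"]),
            y=int(d["y"]),
            width=int(d["width"]),
            height=int(d["height"]),
            role=str(d.get("role", "chest")),
        )
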
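"""Reduce a breath trace to the four per-subject scalar features."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .tracker import BreathTrace

logger = logging.getLogger(__name__)


@dataclass
class FeatureVector:
    """Four respiratory features for one subject.

    ``trv``  total respiratory volume: accumulated plume pixel count.
    ``ade_s`` mean time (s) between consecutive expiration starts.
    ``adi_s`` mean time (s) between consecutive inspiration starts.
    ``trr``  completed breath cycles in the window (or per minute).

    ``ade_s``/``adi_s`` are NaN with the corresponding ``*_defined`` flag
    False when fewer than two starts were observed; they are never imputed.
    """

    trv: float
    ade_s: float
    adi_s: float
    trr: float
    ade_defined: bool = True
    adi_defined: bool = True
    trr_per_minute: bool = False

    def as_dict(self) -> dict:
        return {"trv": self.trv, "ade_s": self.ade_s, "adi_s": self.adi_s, "trr": self.trr}

    def is_complete(self) -> bool:
        return self.ade_defined and self.adi_defined


def total_volume(trace: BreathTrace) -> float:
    """Sum of per-frame plume pixel counts over the analysis window."""
    return float(trace.plume_counts.sum())


def mean_interval(start_times: np.ndarray) -> float:
    """Mean gap between consecutive start times; NaN if fewer than two."""
    start_times = np.asarray(start_times, dtype=float)
    if len(start_times) < 2:
        return math.nan
    return float(np.mean(np.diff(start_times)))


def respiratory_rate(trace: BreathTrace, per_minute: bool = False) -> float:
    """Completed expiration->inspiration cycles in the window.

    A cycle is counted at each expiration start that is followed by an
    inspiration start within the window. ``per_minute`` rescales by
    60 / window length.
    """
    exp = np.asarray(trace.expiration_starts, dtype=float)
    insp = np.asarray(trace.inspiration_starts, dtype=float)
    if len(exp) == 0 or len(insp) == 0:
        cycles = 0
    else:
        cycles = int(np.count_nonzero(exp < insp.max()))
    if per_minute:
        return cycles * 60.0 / trace.window_duration
    return float(cycles)


def extract_features(trace: BreathTrace, trr_per_minute: bool = False) -> FeatureVector:
    """Bundle the four features; undefined intervals propagate as flags."""
    ade = mean_interval(trace.expiration_start_times())
    adi = mean_interval(trace.inspiration_start_times())
    ade_ok, adi_ok = not math.isnan(ade), not math.isnan(adi)
    if not ade_ok:
        logger.warning("fewer than 2 expiration starts: ADE undefined")
    if not adi_ok:
        logger.warning("fewer than 2 inspiration starts: ADI undefined")
    return FeatureVector(
        trv=total_volume(trace),
        ade_s=ade,
        adi_s=adi,
        trr=respiratory_rate(trace, per_minute=trr_per_minute),
        ade_defined=ade_ok,
        adi_defined=adi_ok,
        trr_per_minute=trr_per_minute,
    )
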
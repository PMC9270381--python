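"""Subordinated "performance time" transform.

A score sequence S(1..tau) maps to strictly increasing event stamps

    H(t) = sum_{i <= t} 1 / max(S(i), s_min),

so a run of large scores becomes a tight cluster of points on the H axis,
and the sequence can be analysed as a one-dimensional point process.

The transform is undefined at S = 0 (a duck), which is common in batting
careers. The floor policy substitutes ``s_min`` (default 0.5) so that a
duck contributes the *largest* possible increment (2.0, strictly above the
increment 1.0 of the worst positive score) and the worse-score =>
longer-gap ordering is preserved. The floor is a configuration knob, not a
claim about the source data, and is recorded on every transformed series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_model import CareerRecord

DEFAULT_S_MIN = 0.5


@dataclass(frozen=True)
class PerformanceTimeSeries:
    """Strictly increasing subordinated time stamps, one per game; no event at 0."""

    stamps: np.ndarray
    s_min: float = DEFAULT_S_MIN

    def __post_init__(self) -> None:
        stamps = np.asarray(self.stamps, dtype=float)
        if stamps.size and np.any(np.diff(stamps) <= 0):
            raise ValueError("performance-time stamps must be strictly increasing")
        if stamps.size and stamps[0] <= 0:
            raise ValueError("first stamp must be > 0 (origin carries no event)")
        object.__setattr__(self, "stamps", stamps)

    def __len__(self) -> int:
        return int(self.stamps.size)

    @property
    def horizon(self) -> float:
        """Observation span (0, H(tau)] — the last stamp."""
        return float(self.stamps[-1]) if len(self) else 0.0

    @property
    def gaps(self) -> np.ndarray:
        """Inter-event increments 1/S~(t)."""
        return np.diff(self.stamps, prepend=0.0)


def to_performance_time(
    career: CareerRecord | np.ndarray,
    s_min: float = DEFAULT_S_MIN,
) -> PerformanceTimeSeries:
    """Map a score sequence onto the subordinated H axis (cumulative 1/score,
    zeros floored at ``s_min``)."""
    if s_min <= 0:
        raise ValueError(f"s_min must be > 0, got {s_min}")
    scores = career.scores if isinstance(career, CareerRecord) else np.asarray(career)
    if scores.size == 0:
        raise ValueError("cannot transform an empty career")
    adjusted = np.maximum(scores.astype(float), s_min)
    return PerformanceTimeSeries(np.cumsum(1.0 / adjusted), s_min=s_min)


def from_performance_time(stamps: np.ndarray | PerformanceTimeSeries) -> np.ndarray:
    """Invert the subordination: S(t) = 1/deltaH(t), before any rounding.

    Exact inverse of :func:`to_performance_time` on all-positive scores;
    floored zero scores come back as ``s_min``.
    """
    arr = stamps.stamps if isinstance(stamps, PerformanceTimeSeries) else np.asarray(stamps, float)
    if arr.size == 0:
        return np.asarray([])
    gaps = np.diff(arr, prepend=0.0)
    if np.any(gaps <= 0):
        raise ValueError("stamps must be strictly increasing and start above 0")
    return 1.0 / gaps
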
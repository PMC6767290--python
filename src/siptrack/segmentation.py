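"""Drink-event segmentation.

Two levels of partitioning:

* macro-events — full bottle-in-motion intervals (transport to the mouth,
  sipping, return), found by thresholding motion indicators against the
  stationary upright placement of the bottle between drinks;
* micro-events — each macro-event is split into lift / sip / place, where
  the sip is the interval over which the axial angle alpha is stationary:
  the bottle lid encourages drinking from one edge, so axial rotations
  happen during transport but are suppressed while drinking.

The sip detector thresholds the sample-over-sample |change in alpha| at
``alpha_diff_max`` (8 degrees by default), merges compliant runs separated
by fewer than ``merge_gap`` non-compliant samples, and keeps the longest
merged run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_types import AngleSeries, ValidationError
from .preprocess import ConditionedRecording, compute_inclination

__all__ = [
    "SegmentationConfig",
    "MacroEvent",
    "MicroPartition",
    "detect_macro_events",
    "partition_micro_events",
    "circular_diff",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Thresholds for macro- and micro-event detection.

    ``alpha_diff_max`` and ``merge_gap`` follow the published sip
    detector.  The macro-event motion indicator marks a sample as moving
    when the acceleration magnitude deviates from 1 g by more than
    ``mag_dev_thresh``, the rolling standard deviation of inclination over
    ``std_window_s`` exceeds ``theta_std_thresh``, or the inclination
    itself exceeds ``theta_active_thresh`` (the bottle rests *upright*
    between drinks, so a sustained tilt — e.g. holding the bottle steady
    at drinking angle — is motion even when nothing varies).  Runs of
    motion separated by stillness shorter than ``min_still_s`` are joined,
    and joined runs shorter than ``min_event_s`` are discarded.
    """

    alpha_diff_max: float = 8.0  # degrees per sample
    merge_gap: int = 2  # gaps strictly shorter than this are merged
    mag_dev_thresh: float = 0.05  # g
    theta_std_thresh: float = 2.0  # degrees
    theta_active_thresh: float = 5.0  # degrees
    std_window_s: float = 0.5
    min_event_s: float = 1.0
    min_still_s: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "alpha_diff_max",
            "merge_gap",
            "mag_dev_thresh",
            "theta_std_thresh",
            "theta_active_thresh",
            "std_window_s",
            "min_event_s",
            "min_still_s",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


@dataclass(frozen=True)
class MacroEvent:
    """Half-open sample range [start, end) of one bottle-in-motion interval."""

    start: int
    end: int
    drink_index: int  # 1-based order within the trial

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValidationError(f"invalid macro-event range [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MicroPartition:
    """Lift / sip / place ranges, relative to the macro-event.

    The three half-open ranges are contiguous, in order, and tile the
    event exactly; the sip is never empty.  ``fallback`` flags events
    where no alpha-stationary run was found and the whole event was
    declared the sip.
    """

    lift: tuple[int, int]
    sip: tuple[int, int]
    place: tuple[int, int]
    fallback: bool = False

    def __post_init__(self) -> None:
        if not (
            self.lift[0] == 0
            and self.lift[1] == self.sip[0]
            and self.sip[1] == self.place[0]
            and self.sip[0] < self.sip[1]
        ):
            raise ValidationError(
                f"micro ranges must tile the event in order with a non-empty "
                f"sip: lift={self.lift} sip={self.sip} place={self.place}"
            )

    @property
    def n_samples(self) -> int:
        return self.place[1]

    def to_dict(self) -> dict:
        return {
            "lift": list(self.lift),
            "sip": list(self.sip),
            "place": list(self.place),
            "fallback": self.fallback,
        }


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) ranges of maximal True runs."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


def detect_macro_events(
    rec: ConditionedRecording, cfg: SegmentationConfig | None = None
) -> list[MacroEvent]:
    """Find bottle-in-motion intervals in a conditioned trial.

    Returns events in time order with ``drink_index`` 1..K; an empty list
    for a fully stationary trace.
    """
    cfg = cfg or SegmentationConfig()
    theta = compute_inclination(rec).values
    window = max(int(round(cfg.std_window_s * rec.rate)), 2)
    theta_std = (
        pd.Series(theta).rolling(window, center=True, min_periods=1).std(ddof=0).to_numpy()
    )
    moving = (
        (np.abs(rec.magnitude() - 1.0) > cfg.mag_dev_thresh)
        | (theta_std > cfg.theta_std_thresh)
        | (theta > cfg.theta_active_thresh)
    )
    min_event = max(int(round(cfg.min_event_s * rec.rate)), 1)
    min_still = max(int(round(cfg.min_still_s * rec.rate)), 1)

    merged: list[list[int]] = []
    for s, e in _runs(moving):
        if merged and s - merged[-1][1] < min_still:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    events = [
        MacroEvent(start=s, end=e, drink_index=i + 1)
        for i, (s, e) in enumerate((s, e) for s, e in merged if e - s >= min_event)
    ]
    return events


def circular_diff(alpha: np.ndarray) -> np.ndarray:
    """Sample-over-sample change of an angle series, wrapped to (-180, 180].

    Wrapping keeps a constant angle sitting on the +/-180 branch cut from
    registering spurious 360-degree jumps.
    """
    d = np.diff(alpha)
    return (d + 180.0) % 360.0 - 180.0


def partition_micro_events(
    alpha: AngleSeries | np.ndarray, cfg: SegmentationConfig | None = None
) -> MicroPartition:
    """Split one macro-event into lift / sip / place from its alpha trace.

    A sample is compliant when |alpha[n] - alpha[n-1]| <= alpha_diff_max
    (the first sample is compliant by convention).  Maximal compliant runs
    separated by fewer than ``merge_gap`` non-compliant samples are merged
    (the merged span includes the gap samples, keeping the sip
    contiguous); the longest merged run is the sip, ties broken to the
    earliest.  Lift and place are the remainders on either side.
    """
    cfg = cfg or SegmentationConfig()
    values = alpha.values if isinstance(alpha, AngleSeries) else np.asarray(alpha, float)
    n = len(values)
    if n < 3:
        raise ValidationError(f"macro-event too short to partition ({n} samples)")
    compliant = np.empty(n, dtype=bool)
    compliant[0] = True
    compliant[1:] = np.abs(circular_diff(values)) <= cfg.alpha_diff_max

    runs = _runs(compliant)
    if not runs:  # unreachable under the first-sample convention; kept as guard
        return MicroPartition(lift=(0, 0), sip=(0, n), place=(n, n), fallback=True)

    merged: list[list[int]] = [list(runs[0])]
    for s, e in runs[1:]:
        if s - merged[-1][1] < cfg.merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    s, e = max(merged, key=lambda r: r[1] - r[0])  # ties -> earliest (max is stable)
    return MicroPartition(lift=(0, s), sip=(s, e), place=(e, n))
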
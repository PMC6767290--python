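"""Inclination-signature (IS) features and single-factor benchmark features.

The IS set is 33 hand-engineered features of the inclination curve theta
over one drink event: 13 kinematic scalars (durations of the event and of
its lift/sip/place phases, extreme values and rates, curve integrals) plus
20 amplitude-occupancy fractions from exclusive binning of the raw curve
(10 equal-width bins over [0, 180] degrees) and of the curve normalised by
its maximum (10 bins over [0, 1]).  Exclusive binning partitions the
amplitude axis, so each sample lands in exactly one bin and the fractions
sum to one; occupancy fractions are a low-level time-invariant description
of the curve shape.

``scope`` selects whether amplitude-shape features (max, rates, bins) are
computed over the whole macro-event or restricted to the sip micro-event;
the sip-scoped variant corresponds to models trained on the stationary
drinking phase alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_types import AngleSeries, ValidationError
from .segmentation import MicroPartition

__all__ = [
    "FeatureVector",
    "BenchmarkFeatures",
    "IS_FEATURE_NAMES",
    "extract_is_features",
    "extract_benchmark_features",
]

N_BINS = 10

_KINEMATIC_NAMES = [
    "duration_macro_s",
    "duration_lift_s",
    "duration_sip_s",
    "duration_place_s",
    "theta_max_deg",
    "theta_time_to_max_frac",
    "theta_sip_start_deg",
    "theta_sip_end_deg",
    "theta_sip_mean_deg",
    "dtheta_max_deg_per_s",
    "dtheta_min_deg_per_s",
    "theta_integral_sip_deg_s",
    "theta_integral_macro_deg_s",
]

#: fixed registry order: 13 kinematic + 10 raw bins + 10 normalised bins
IS_FEATURE_NAMES: tuple[str, ...] = tuple(
    _KINEMATIC_NAMES
    + [f"theta_bin_raw_{i:02d}" for i in range(N_BINS)]
    + [f"theta_bin_norm_{i:02d}" for i in range(N_BINS)]
)


@dataclass(frozen=True)
class FeatureVector:
    """The 33 IS features for one drink (34 with an appended fill ratio)."""

    names: tuple[str, ...]
    values: np.ndarray
    scope: str  # "macro" | "sip"

    def __post_init__(self) -> None:
        if len(self.names) != len(self.values):
            raise ValidationError("feature names/values length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite feature value")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


@dataclass(frozen=True)
class BenchmarkFeatures:
    """Single-factor motion features used by linear-regression benchmarks."""

    sip_duration_s: float
    integral_theta_deg_s: float
    max_theta_deg: float

    def __post_init__(self) -> None:
        if self.sip_duration_s < 0:
            raise ValidationError("negative sip duration")
        if not 0.0 <= self.max_theta_deg <= 180.0:
            raise ValidationError("max_theta outside [0, 180] degrees")


def _bin_fractions(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    counts, _ = np.histogram(x, bins=N_BINS, range=(lo, hi))
    return counts / len(x)


def _integral(x: np.ndarray, dt: float) -> float:
    return float(np.trapezoid(x, dx=dt)) if len(x) > 1 else 0.0


def extract_is_features(
    theta: AngleSeries,
    partition: MicroPartition,
    scope: str = "macro",
) -> FeatureVector:
    """Extract the 33 IS features from theta over one macro-event.

    ``theta`` spans the whole macro-event; ``partition`` gives the
    lift/sip/place split relative to it.  Sip-anchored features (theta at
    sip start/end, sip mean, sip integral) and the four durations are
    scope-independent; max, time-to-max, rate extremes and the bin
    occupancies are computed over the window ``scope`` selects.
    """
    if scope not in ("macro", "sip"):
        raise ValidationError(f"scope must be 'macro' or 'sip', got {scope!r}")
    values = theta.values
    rate = theta.rate
    n = len(values)
    if partition.n_samples != n:
        raise ValidationError(
            f"partition covers {partition.n_samples} samples, theta has {n}"
        )
    dt = 1.0 / rate
    s0, s1 = partition.sip
    sip = values[s0:s1]
    window = sip if scope == "sip" else values

    theta_max = float(np.max(window))
    time_to_max = float(np.argmax(window)) / max(len(window) - 1, 1)
    dtheta = np.diff(window) * rate
    feats = {
        "duration_macro_s": n / rate,
        "duration_lift_s": (partition.lift[1] - partition.lift[0]) / rate,
        "duration_sip_s": (s1 - s0) / rate,
        "duration_place_s": (partition.place[1] - partition.place[0]) / rate,
        "theta_max_deg": theta_max,
        "theta_time_to_max_frac": time_to_max,
        "theta_sip_start_deg": float(sip[0]),
        "theta_sip_end_deg": float(sip[-1]),
        "theta_sip_mean_deg": float(np.mean(sip)),
        "dtheta_max_deg_per_s": float(np.max(dtheta)) if len(dtheta) else 0.0,
        "dtheta_min_deg_per_s": float(np.min(dtheta)) if len(dtheta) else 0.0,
        "theta_integral_sip_deg_s": _integral(sip, dt),
        "theta_integral_macro_deg_s": _integral(values, dt),
    }

    raw_bins = _bin_fractions(window, 0.0, 180.0)
    if theta_max > 0:
        norm_bins = _bin_fractions(window / theta_max, 0.0, 1.0)
    else:
        warnings.warn(
            "theta is identically zero over the event; normalised bins "
            "defaulted to all mass in the first bin",
            stacklevel=2,
        )
        norm_bins = np.zeros(N_BINS)
        norm_bins[0] = 1.0

    out = np.concatenate(
        [np.array([feats[k] for k in _KINEMATIC_NAMES]), raw_bins, norm_bins]
    )
    return FeatureVector(names=IS_FEATURE_NAMES, values=out, scope=scope)


def extract_benchmark_features(
    theta: AngleSeries, partition: MicroPartition
) -> BenchmarkFeatures:
    """Sip duration, integral of inclination over the sip, and max inclination."""
    s0, s1 = partition.sip
    if s1 <= s0:
        raise ValidationError("empty sip micro-event")
    values = theta.values
    return BenchmarkFeatures(
        sip_duration_s=(s1 - s0) / theta.rate,
        integral_theta_deg_s=_integral(values[s0:s1], 1.0 / theta.rate),
        max_theta_deg=float(np.max(values)),
    )
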
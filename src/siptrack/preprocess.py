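"""Signal conditioning and gravity-based angle estimation.

Pipeline order: bias removal -> exclusion masking -> resampling to a
uniform grid -> causal moving-average smoothing -> angle estimation.

Two angles are derived from the conditioned static-acceleration vector,
assuming dynamic acceleration is negligible so the accelerometer reads the
gravity direction in the sensor frame:

* inclination  theta = atan2(sqrt(ay^2 + az^2), ax), the tilt of the
  bottle's vertical axis away from vertical, in [0, 180] degrees;
* axial angle  alpha = atan2(az, ay), the sensor's angular position in the
  bottle's cross-sectional plane, in (-180, 180] degrees.  alpha is
  undefined when the bottle is upright (ay = az = 0); the estimate then
  carries the last defined value forward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_types import AngleSeries, Recording, ValidationError

__all__ = [
    "BiasEstimate",
    "ConditionedRecording",
    "estimate_bias",
    "condition",
    "compute_inclination",
    "compute_axial_angle",
]

#: sanity guard on per-axis bias magnitude, g
BIAS_MAX = 0.5


@dataclass(frozen=True)
class BiasEstimate:
    """Per-axis accelerometer offsets, in g.

    Convention: the x offset is measured relative to the +1 g an upright
    stationary bottle should read, so that subtracting the bias leaves the
    gravity component in the signal: a corrected stationary upright read
    is (1, 0, 0) g.
    """

    bx: float
    by: float
    bz: float

    def __post_init__(self) -> None:
        b = np.array([self.bx, self.by, self.bz])
        if not np.all(np.isfinite(b)):
            raise ValidationError("bias estimate is not finite")
        if np.any(np.abs(b) >= BIAS_MAX):
            raise ValidationError(
                f"bias magnitude exceeds the {BIAS_MAX} g sanity guard: "
                f"({self.bx:.3g}, {self.by:.3g}, {self.bz:.3g}) — was the "
                f"bottle stationary and upright at the start of the trial?"
            )


@dataclass
class ConditionedRecording:
    """A bias-corrected trace on a uniform grid, smoothed, ready for analysis."""

    trial_id: str
    subject_id: str
    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    rate: float
    steps: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.t)

    def magnitude(self) -> np.ndarray:
        return np.sqrt(self.ax**2 + self.ay**2 + self.az**2)


def estimate_bias(rec: Recording, n_init: int = 50) -> BiasEstimate:
    """Estimate per-axis bias from the initial stationary-upright samples.

    Averages the first ``n_init`` samples of the trace, during which the
    bottle is assumed to rest upright so the true signal is (1, 0, 0) g.
    """
    if len(rec) < n_init:
        raise ValidationError(
            f"trial {rec.trial_id!r}: {len(rec)} samples < n_init={n_init} "
            "required for the stationary bias estimate"
        )
    return BiasEstimate(
        bx=float(np.mean(rec.ax[:n_init]) - 1.0),
        by=float(np.mean(rec.ay[:n_init])),
        bz=float(np.mean(rec.az[:n_init])),
    )


def _causal_moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """y[n] = mean(x[n-window+1 .. n]), shrinking the window at the head.

    For the default window of 2: y[0] = x[0], y[n] = (x[n] + x[n-1]) / 2.
    """
    if window <= 1:
        return x.copy()
    c = np.concatenate(([0.0], np.cumsum(x)))
    n = len(x)
    idx = np.arange(n)
    lo = np.maximum(idx - window + 1, 0)
    return (c[idx + 1] - c[lo]) / (idx + 1 - lo)


def condition(
    rec: Recording,
    bias: BiasEstimate,
    target_rate: float = 20.0,
    ma_window: int = 2,
) -> ConditionedRecording:
    """Bias-correct, apply exclusions, resample and smooth a recording.

    Samples inside the recording's exclusion intervals are dropped, then
    each axis is linearly interpolated onto a uniform ``1/target_rate``
    grid spanning the remaining samples (interpolation bridges any
    excluded gaps), and a causal ``ma_window``-sample moving average is
    applied per axis.
    """
    if target_rate <= 0:
        raise ValidationError(f"target_rate must be positive, got {target_rate}")
    keep = np.ones(len(rec), dtype=bool)
    for t0, t1 in rec.exclusions:
        keep &= ~((rec.t >= t0) & (rec.t < t1))
    t = rec.t[keep]
    if len(t) < 2:
        raise ValidationError(
            f"trial {rec.trial_id!r}: fewer than 2 samples remain after "
            "applying exclusion intervals"
        )
    axes = [
        rec.ax[keep] - bias.bx,
        rec.ay[keep] - bias.by,
        rec.az[keep] - bias.bz,
    ]
    dt = 1.0 / target_rate
    n_grid = int(np.floor((t[-1] - t[0]) / dt + 1e-9)) + 1
    grid = t[0] + dt * np.arange(n_grid)
    resampled = [np.interp(grid, t, x) for x in axes]
    smoothed = [_causal_moving_average(x, ma_window) for x in resampled]
    steps = [
        "bias_removed",
        f"exclusions_applied({len(rec.exclusions)})",
        f"resampled({target_rate}Hz)",
        f"smoothed(ma{ma_window})",
    ]
    return ConditionedRecording(
        trial_id=rec.trial_id,
        subject_id=rec.subject_id,
        t=grid,
        ax=smoothed[0],
        ay=smoothed[1],
        az=smoothed[2],
        rate=float(target_rate),
        steps=steps,
    )


def _carry_forward(values: np.ndarray, defined: np.ndarray, initial: float) -> np.ndarray:
    """Replace undefined entries with the last defined value (``initial`` if none)."""
    if defined.all():
        return values
    out = np.where(defined, values, np.nan)
    idx = np.where(defined, np.arange(len(out)), -1)
    idx = np.maximum.accumulate(idx)
    filled = np.where(idx >= 0, out[np.maximum(idx, 0)], initial)
    return filled


def compute_inclination(rec: ConditionedRecording, eps: float = 1e-6) -> AngleSeries:
    """Estimate the container inclination theta from static acceleration.

    theta[n] = atan2(sqrt(ay^2 + az^2), ax) in degrees, in [0, 180].  When
    both atan2 arguments are below ``eps`` in magnitude (free fall /
    signal dropout) the previous value is carried forward (0 at n = 0).
    """
    planar = np.hypot(rec.ay, rec.az)
    theta = np.degrees(np.arctan2(planar, rec.ax))
    defined = ~((planar < eps) & (np.abs(rec.ax) < eps))
    theta = _carry_forward(theta, defined, 0.0)
    return AngleSeries(kind="inclination", values=theta, rate=rec.rate)


def compute_axial_angle(rec: ConditionedRecording, eps: float = 1e-6) -> AngleSeries:
    """Estimate the cross-sectional (axial) angle alpha.

    alpha[n] = atan2(az, ay) in degrees, in (-180, 180].  Near-upright
    samples (sqrt(ay^2 + az^2) < eps) leave alpha undefined; the previous
    defined value is carried forward (0 if none yet).
    """
    planar = np.hypot(rec.ay, rec.az)
    alpha = np.degrees(np.arctan2(rec.az, rec.ay))
    # atan2 returns -180 for (ay < 0, az = -0.0); fold onto (-180, 180]
    alpha = np.where(alpha <= -180.0, alpha + 360.0, alpha)
    alpha = _carry_forward(alpha, planar >= eps, 0.0)
    return AngleSeries(kind="axial", values=alpha, rate=rec.rate)
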
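"""Domain types and CSV/JSON readers and writers shared across the pipeline.

A trial is one sitting in which a subject consumes a scripted sequence of
drinks from an instrumented bottle.  The sensor frame follows the bottle
geometry: ``x`` parallel to the bottle's vertical axis (reads +1 g when the
bottle stands upright), ``y`` tangential and ``z`` normal to the bottle
surface.  Accelerations are in units of g throughout.

File conventions: one trace CSV per trial with columns ``t,ax,ay,az``; one
label CSV per dataset with columns ``trial_id,drink_index,mass_g,
fill_ratio_pre``; optional proctor exclusion intervals in a sidecar JSON.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "Recording",
    "DrinkLabel",
    "ContainerGeometry",
    "AngleSeries",
    "read_recording",
    "write_recording",
    "read_labels",
    "write_labels",
]

TRACE_COLUMNS = ("t", "ax", "ay", "az")
LABEL_COLUMNS = ("trial_id", "drink_index", "mass_g", "fill_ratio_pre")

#: samples needed for the stationary bias estimate at the head of a trace
MIN_BIAS_SAMPLES = 50

#: sensor range guard, g
ACCEL_MAGNITUDE_MAX = 8.0


class FormatError(ValueError):
    """A file does not follow the expected column layout."""


class ValidationError(ValueError):
    """Data violates a domain invariant (units, monotonicity, ranges)."""


@dataclass
class Recording:
    """One trial's triaxial accelerometer trace plus metadata.

    ``t`` is in seconds and strictly increasing; ``ax, ay, az`` are in g.
    ``exclusions`` is an optional list of half-open ``[t_start, t_end)``
    intervals flagged for removal during preprocessing (proctor-noted
    protocol variations); excluded rows are retained here.
    """

    trial_id: str
    subject_id: str
    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    nominal_rate: float
    exclusions: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        n = len(self.t)
        if not (len(self.ax) == len(self.ay) == len(self.az) == n):
            raise ValidationError("t, ax, ay, az must have equal length")
        if n == 0:
            raise ValidationError(
                f"trial {self.trial_id!r}: empty recording (the stationary "
                f"bias estimate needs at least {MIN_BIAS_SAMPLES} samples)"
            )
        bad = np.nonzero(np.diff(self.t) <= 0)[0]
        if bad.size:
            raise ValidationError(
                f"trial {self.trial_id!r}: timestamps not strictly "
                f"increasing at row {bad[0] + 1}"
            )
        a = np.c_[self.ax, self.ay, self.az]
        if not np.all(np.isfinite(a)) or not np.all(np.isfinite(self.t)):
            raise ValidationError(f"trial {self.trial_id!r}: non-finite values")
        mag = np.linalg.norm(a, axis=1)
        if np.any(mag > ACCEL_MAGNITUDE_MAX):
            raise ValidationError(
                f"trial {self.trial_id!r}: |a| exceeds the "
                f"{ACCEL_MAGNITUDE_MAX} g sensor range guard"
            )

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class DrinkLabel:
    """Ground truth for one drink: scale mass and pre-drink fill ratio."""

    trial_id: str
    drink_index: int  # 1-based order within the trial
    mass_g: float
    fill_ratio_pre: float

    def __post_init__(self) -> None:
        if self.mass_g <= 0:
            raise ValidationError(
                f"trial {self.trial_id!r} drink {self.drink_index}: "
                f"mass_g must be positive, got {self.mass_g}"
            )
        if not 0.0 <= self.fill_ratio_pre <= 1.0:
            raise ValidationError(
                f"trial {self.trial_id!r} drink {self.drink_index}: "
                f"fill_ratio_pre outside [0, 1]: {self.fill_ratio_pre}"
            )


@dataclass(frozen=True)
class ContainerGeometry:
    """Container shape summary for fill-ratio/volume conversion.

    ``beta_ml`` is the linear density parameter: mL of liquid per unit of
    fill ratio.  For a uniform-cross-section bottle it equals the capacity.
    """

    beta_ml: float
    capacity_ml: float

    def __post_init__(self) -> None:
        if self.beta_ml <= 0:
            raise ValidationError(f"beta_ml must be positive, got {self.beta_ml}")
        if self.capacity_ml <= 0:
            raise ValidationError(
                f"capacity_ml must be positive, got {self.capacity_ml}"
            )


@dataclass
class AngleSeries:
    """A per-sample angle trace in degrees at a uniform rate.

    ``kind`` is ``"inclination"`` (tilt of the bottle axis from vertical,
    in [0, 180]) or ``"axial"`` (sensor position in the bottle's
    cross-sectional plane, in (-180, 180]).
    """

    kind: str
    values: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        if self.kind not in ("inclination", "axial"):
            raise ValidationError(f"unknown angle kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.kind == "inclination":
            if np.any((self.values < 0) | (self.values > 180)):
                raise ValidationError("inclination must lie in [0, 180] degrees")
        else:
            if np.any((self.values <= -180) | (self.values > 180)):
                raise ValidationError("axial angle must lie in (-180, 180] degrees")

    def __len__(self) -> int:
        return len(self.values)


def _infer_rate(t: np.ndarray) -> float:
    dt = np.median(np.diff(t)) if len(t) > 1 else np.nan
    return float(1.0 / dt) if np.isfinite(dt) and dt > 0 else float("nan")


def read_recording(
    path: str | Path,
    trial_id: str | None = None,
    subject_id: str = "",
    exclusions_path: str | Path | None = None,
) -> Recording:
    """Read a per-trial trace CSV (columns ``t,ax,ay,az``, units of g).

    ``trial_id`` defaults to the file stem.  If ``exclusions_path`` is
    given (or a ``<stem>.exclusions.json`` sidecar exists next to the
    trace), its ``[[t_start, t_end), ...]`` intervals are attached; the
    rows inside them are retained and only applied during preprocessing.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    if trial_id is None:
        trial_id = path.stem
    if exclusions_path is None:
        sidecar = path.with_suffix(".exclusions.json")
        exclusions_path = sidecar if sidecar.exists() else None
    exclusions: list[tuple[float, float]] = []
    if exclusions_path is not None:
        raw = json.loads(Path(exclusions_path).read_text())
        exclusions = [(float(a), float(b)) for a, b in raw]
    rec = Recording(
        trial_id=trial_id,
        subject_id=subject_id,
        t=df["t"].to_numpy(float),
        ax=df["ax"].to_numpy(float),
        ay=df["ay"].to_numpy(float),
        az=df["az"].to_numpy(float),
        nominal_rate=_infer_rate(df["t"].to_numpy(float)),
        exclusions=exclusions,
    )
    return rec


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a Recording as a trace CSV; round-trips within 1e-9 g."""
    path = Path(path)
    df = pd.DataFrame({"t": rec.t, "ax": rec.ax, "ay": rec.ay, "az": rec.az})
    # repr-precision floats so read_recording recovers the values exactly
    df.to_csv(path, index=False, float_format="%.17g")
    if rec.exclusions:
        path.with_suffix(".exclusions.json").write_text(
            json.dumps([list(iv) for iv in rec.exclusions])
        )
    return path


def read_labels(path: str | Path) -> list[DrinkLabel]:
    """Read a dataset label CSV, grouped and sorted by (trial_id, drink_index).

    The returned order is a pure function of the keys, independent of file
    row order.  A trial whose fill ratio increases with drink order is
    physically impossible under the refill-once protocol and triggers a
    warning naming the trial.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in LABEL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    df = df.sort_values(["trial_id", "drink_index"], kind="stable")
    labels = [
        DrinkLabel(
            trial_id=str(r.trial_id),
            drink_index=int(r.drink_index),
            mass_g=float(r.mass_g),
            fill_ratio_pre=float(r.fill_ratio_pre),
        )
        for r in df.itertuples(index=False)
    ]
    for tid, grp in df.groupby("trial_id", sort=False):
        fr = grp["fill_ratio_pre"].to_numpy(float)
        if np.any(np.diff(fr) > 0):
            warnings.warn(
                f"trial {tid!r}: fill_ratio_pre increases with drink_index",
                stacklevel=2,
            )
    return labels


def write_labels(labels: list[DrinkLabel], path: str | Path) -> Path:
    """Write drink labels as a dataset label CSV."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "trial_id": [l.trial_id for l in labels],
            "drink_index": [l.drink_index for l in labels],
            "mass_g": [l.mass_g for l in labels],
            "fill_ratio_pre": [l.fill_ratio_pre for l in labels],
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")
    return path
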
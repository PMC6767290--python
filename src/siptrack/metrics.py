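"""Per-drink and aggregate-consumption error metrics.

Per-drink accuracy is the mean absolute percentage error (MAPE).
Aggregate accuracy over the first n drinks of a trial is the overall
absolute percentage error OAPE(n) = 100 * |sum(pred) - sum(truth)| /
sum(truth); MOAPE(n) averages OAPE(n) across trials.  Because OAPE
compares sums, sequential errors of opposite sign cancel, which is why
cumulative aggregate estimates can be far more accurate than the
per-drink MAPE suggests.

Aggregate consumption can alternatively be estimated from endpoint fill
ratios ("residual volume estimation"): the volume drunk between drink i
and drink f is V = beta * (FR_i - FR_{f+1}), with beta the container's
linear density (mL per unit fill ratio).  A fill-ratio error at the
endpoint is amplified by 1/(1 - FR_{f+1}) when converted to a consumption
percentage error, so residual estimates are most distorted for trials
that drank little.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_types import ContainerGeometry, ValidationError

__all__ = [
    "EvaluationReport",
    "mape",
    "ape",
    "oape",
    "moape",
    "residual_volume_estimate",
    "oape_distortion",
    "compare_aggregation",
    "build_report",
]


def ape(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Per-element absolute percentage errors, on the 0-100 scale."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValidationError("pred and truth must have the same length")
    bad = np.flatnonzero(truth <= 0)
    if bad.size:
        raise ValidationError(f"non-positive truth value at index {bad[0]}")
    return 100.0 * np.abs(pred - truth) / truth


def mape(pred: np.ndarray, truth: np.ndarray) -> float:
    """Mean absolute percentage error, 0-100 scale."""
    return float(np.mean(ape(pred, truth)))


def oape(pred: np.ndarray, truth: np.ndarray, n: int | None = None) -> float:
    """Overall absolute percentage error of summed consumption over drinks 1..n."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if n is None:
        n = len(truth)
    if len(truth) < n:
        raise ValidationError(f"trial has {len(truth)} drinks < n={n}")
    s_true = float(np.sum(truth[:n]))
    if s_true <= 0:
        raise ValidationError("non-positive summed truth")
    return 100.0 * abs(float(np.sum(pred[:n])) - s_true) / s_true


def moape(
    trial_results: dict[str, tuple[np.ndarray, np.ndarray]], n: int
) -> float:
    """Mean OAPE(n) across trials; trials shorter than n are skipped with a warning.

    ``trial_results`` maps trial id to its (pred, truth) sequences in
    drink order.
    """
    values = []
    for tid, (pred, truth) in trial_results.items():
        if len(truth) < n:
            warnings.warn(
                f"trial {tid!r} has {len(truth)} drinks < n={n}; skipped",
                stacklevel=2,
            )
            continue
        values.append(oape(pred, truth, n))
    if not values:
        raise ValidationError(f"no trial has {n} drinks")
    return float(np.mean(values))


def residual_volume_estimate(
    fr_i: float, fr_f1: float, geom: ContainerGeometry
) -> float:
    """Aggregate consumption from endpoint fill ratios: beta * (fr_i - fr_f1).

    ``fr_i`` is the fill ratio at the initiation of the first drink of the
    span and ``fr_f1`` the fill ratio at the initiation of the drink after
    the last one.  Estimates may invert order, producing a (flagged)
    negative volume.
    """
    for name, v in (("fr_i", fr_i), ("fr_f1", fr_f1)):
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"{name} outside [0, 1]: {v}")
    v_hat = geom.beta_ml * (fr_i - fr_f1)
    if v_hat < 0:
        warnings.warn(
            f"negative residual volume ({v_hat:.3g} mL): fill-ratio "
            "estimates are out of order",
            stacklevel=2,
        )
    return float(v_hat)


def oape_distortion(ape_next: float, fr_next: float) -> float:
    """Residual-volume OAPE implied by a single endpoint fill-ratio error.

    ``ape_next`` is the absolute error of the endpoint fill-ratio
    estimate, |FR_hat - FR|, which — fill ratio being normalised to
    [0, 1] — is the error as a fraction of a full bottle.  For a trial
    that started full, that error maps to a consumption OAPE of
    ape_next / (1 - fr_next): the less was drunk (large ``fr_next``), the
    larger the distortion.  Arguments and result are fractions, not
    0-100 percentages.
    """
    if not 0.0 <= fr_next < 1.0:
        raise ValidationError(
            f"fr_next must lie in [0, 1) (fr_next = 1 means no consumption): {fr_next}"
        )
    if ape_next < 0:
        raise ValidationError("ape_next must be non-negative")
    return float(ape_next / (1.0 - fr_next))


@dataclass
class EvaluationReport:
    """MAPE / MOAPE summary of one model's held-out predictions.

    ``pooled_mape`` averages absolute percentage errors over all drinks;
    ``mean_trial_mape`` averages the per-trial MAPEs (both are reported
    because they weight unequal-length trials differently).  Percentages
    are on the 0-100 scale.
    """

    per_trial_mape: dict[str, float]
    pooled_mape: float
    mean_trial_mape: float
    mape_sd_across_trials: float
    moape_by_n: dict[int, float]
    per_trial_oape: dict[int, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_trial_mape": self.per_trial_mape,
            "pooled_mape": self.pooled_mape,
            "mean_trial_mape": self.mean_trial_mape,
            "mape_sd_across_trials": self.mape_sd_across_trials,
            "moape_by_n": {str(k): v for k, v in self.moape_by_n.items()},
            "per_trial_oape": {
                str(n): d for n, d in self.per_trial_oape.items()
            },
        }


def build_report(
    trial_results: dict[str, tuple[np.ndarray, np.ndarray]],
    ns: tuple[int, ...] = (3, 6, 9, 12),
) -> EvaluationReport:
    """Summarise held-out (pred, truth) sequences into an EvaluationReport."""
    per_trial = {tid: mape(p, t) for tid, (p, t) in trial_results.items()}
    all_ape = np.concatenate(
        [ape(p, t) for p, t in trial_results.values()]
    )
    trial_mapes = np.array(list(per_trial.values()))
    moape_by_n: dict[int, float] = {}
    per_trial_oape: dict[int, dict[str, float]] = {}
    for n in ns:
        eligible = {
            tid: oape(p, t, n)
            for tid, (p, t) in trial_results.items()
            if len(t) >= n
        }
        if eligible:
            moape_by_n[n] = float(np.mean(list(eligible.values())))
            per_trial_oape[n] = eligible
    return EvaluationReport(
        per_trial_mape=per_trial,
        pooled_mape=float(np.mean(all_ape)),
        mean_trial_mape=float(np.mean(trial_mapes)),
        mape_sd_across_trials=float(np.std(trial_mapes, ddof=1))
        if len(trial_mapes) > 1
        else 0.0,
        moape_by_n=moape_by_n,
        per_trial_oape=per_trial_oape,
    )


def compare_aggregation(
    volume_preds: dict[str, np.ndarray],
    fr_preds: dict[str, np.ndarray],
    truths: dict[str, np.ndarray],
    geom: ContainerGeometry,
    n: int = 11,
) -> dict:
    """Cumulative vs residual aggregate-consumption MOAPE(n), side by side.

    For each trial: the cumulative estimate sums the first n per-drink
    volume predictions; the residual estimate is beta * (FR_1 - FR_{n+1})
    using the predicted pre-drink fill ratios, so the trial must contain
    at least n+1 drinks (shorter trials are dropped with a warning).  With
    a 12-drink protocol the natural choice is n = 11, the longest span
    whose endpoint fill ratio is itself a pre-drink estimate.
    """
    if set(volume_preds) != set(truths) or set(fr_preds) != set(truths):
        raise ValidationError("volume, fill-ratio and truth trial sets differ")
    cumulative: dict[str, float] = {}
    residual: dict[str, float] = {}
    for tid, truth in truths.items():
        if len(truth) < n + 1 or len(fr_preds[tid]) < n + 1:
            warnings.warn(
                f"trial {tid!r} lacks drink {n + 1}; excluded from the "
                "residual comparison",
                stacklevel=2,
            )
            continue
        s_true = float(np.sum(truth[:n]))
        cumulative[tid] = 100.0 * abs(float(np.sum(volume_preds[tid][:n])) - s_true) / s_true
        fr_hat = np.clip(fr_preds[tid], 0.0, 1.0)
        v_res = residual_volume_estimate(float(fr_hat[0]), float(fr_hat[n]), geom)
        residual[tid] = 100.0 * abs(v_res - s_true) / s_true
    if not cumulative:
        raise ValidationError(f"no trial has {n + 1} drinks")
    return {
        "n": n,
        "trials": sorted(cumulative),
        "cumulative_moape": float(np.mean(list(cumulative.values()))),
        "residual_moape": float(np.mean(list(residual.values()))),
        "per_trial": {
            tid: {"cumulative": cumulative[tid], "residual": residual[tid]}
            for tid in cumulative
        },
    }
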
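"""End-to-end orchestration: raw traces to feature tables to reports.

Glue around the stage modules: condition a recording, segment it, extract
features for every detected drink, align drinks with labels, and run
leave-one-trial-out evaluations of a list of model specs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import FoldResult, ModelSpec, loto_evaluate
from .features import (
    IS_FEATURE_NAMES,
    extract_benchmark_features,
    extract_is_features,
)
from .io_types import AngleSeries, DrinkLabel, Recording, ValidationError
from .metrics import EvaluationReport, build_report
from .preprocess import (
    ConditionedRecording,
    compute_axial_angle,
    compute_inclination,
    condition,
    estimate_bias,
)
from .segmentation import (
    MacroEvent,
    MicroPartition,
    SegmentationConfig,
    detect_macro_events,
    partition_micro_events,
)

__all__ = [
    "ProcessedTrial",
    "process_recording",
    "drink_table",
    "evaluate_spec",
    "trial_sequences",
    "BENCHMARK_COLUMNS",
]

BENCHMARK_COLUMNS = ("sip_duration_s", "integral_theta_deg_s", "max_theta_deg")
META_COLUMNS = ("trial_id", "subject_id", "drink_index")


@dataclass
class ProcessedTrial:
    """Conditioned signal, angles and segmentation for one trial."""

    conditioned: ConditionedRecording
    theta: np.ndarray
    alpha: np.ndarray
    events: list[MacroEvent]
    partitions: list[MicroPartition]


def process_recording(
    rec: Recording, seg_cfg: SegmentationConfig | None = None
) -> ProcessedTrial:
    """Run conditioning, angle estimation and both segmentation levels."""
    seg_cfg = seg_cfg or SegmentationConfig()
    bias = estimate_bias(rec)
    cond = condition(rec, bias)
    theta = compute_inclination(cond)
    alpha = compute_axial_angle(cond)
    events = detect_macro_events(cond, seg_cfg)
    partitions = [
        partition_micro_events(alpha.values[ev.start : ev.end], seg_cfg)
        for ev in events
    ]
    return ProcessedTrial(
        conditioned=cond,
        theta=theta.values,
        alpha=alpha.values,
        events=events,
        partitions=partitions,
    )


def drink_table(
    trials: list[tuple[Recording, list[DrinkLabel]]],
    scope: str = "macro",
    seg_cfg: SegmentationConfig | None = None,
) -> pd.DataFrame:
    """Build the per-drink analysis table for a labelled cohort.

    One row per drink matched (in order) between detected macro-events and
    labels, holding the 33 IS features, the three benchmark features, the
    labels and trial metadata.  Trials whose detected event count differs
    from their label count are truncated to the shorter sequence with a
    warning.
    """
    rows: list[dict] = []
    for rec, labels in trials:
        proc = process_recording(rec, seg_cfg)
        n = min(len(proc.events), len(labels))
        if len(proc.events) != len(labels):
            warnings.warn(
                f"trial {rec.trial_id!r}: {len(proc.events)} detected events "
                f"vs {len(labels)} labels; using the first {n}",
                stacklevel=2,
            )
        for ev, part, lab in zip(proc.events[:n], proc.partitions[:n], labels[:n]):
            theta_ev = AngleSeries(
                kind="inclination",
                values=proc.theta[ev.start : ev.end],
                rate=proc.conditioned.rate,
            )
            fv = extract_is_features(theta_ev, part, scope=scope)
            bench = extract_benchmark_features(theta_ev, part)
            row = {
                "trial_id": rec.trial_id,
                "subject_id": rec.subject_id,
                "drink_index": lab.drink_index,
                "mass_g": lab.mass_g,
                "fill_ratio_pre": lab.fill_ratio_pre,
                "sip_duration_s": bench.sip_duration_s,
                "integral_theta_deg_s": bench.integral_theta_deg_s,
                "max_theta_deg": bench.max_theta_deg,
            }
            row.update(fv.as_dict())
            rows.append(row)
    if not rows:
        raise ValidationError("no drinks found in any trial")
    return pd.DataFrame(rows)


def _target_values(df: pd.DataFrame, target: str) -> np.ndarray:
    col = {"volume": "mass_g", "fill_ratio": "fill_ratio_pre"}[target]
    return df[col].to_numpy(float)


def evaluate_spec(
    df: pd.DataFrame,
    spec: ModelSpec,
    ns: tuple[int, ...] = (3, 6, 9, 12),
    group_by: str = "trial_id",
    strategy: str = "none",
    fr_query: np.ndarray | None = None,
    k_nearest: int = 150,
) -> tuple[list[FoldResult], EvaluationReport]:
    """LOTO-evaluate one model spec against a drink table.

    For single-factor LR specs, ``spec.lr_feature`` names the benchmark
    column used; SVM specs use the 33 IS feature columns.  ``fr_query``
    (aligned with ``df`` rows) supplies the per-drink fill-ratio values a
    multi-target ``strategy`` conditions on; ground-truth labels are used
    when it is omitted.
    """
    if spec.model == "lr_single":
        if spec.lr_feature not in BENCHMARK_COLUMNS:
            raise ValidationError(
                f"lr_feature must be one of {BENCHMARK_COLUMNS}, got {spec.lr_feature!r}"
            )
        X = df[[spec.lr_feature]].to_numpy(float)
    else:
        X = df[list(IS_FEATURE_NAMES)].to_numpy(float)
    y = _target_values(df, spec.target)
    fr = df["fill_ratio_pre"].to_numpy(float)
    folds = loto_evaluate(
        spec,
        X,
        y,
        trial_ids=df["trial_id"].to_numpy(),
        drink_index=df["drink_index"].to_numpy(),
        group_by=df[group_by].to_numpy() if group_by != "trial_id" else None,
        fr=fr if strategy != "none" else None,
        fr_query=(fr if fr_query is None else np.asarray(fr_query, float))
        if strategy != "none"
        else None,
        strategy=strategy,
        k_nearest=k_nearest,
    )
    report = build_report(trial_sequences(folds), ns=ns)
    return folds, report


def trial_sequences(folds: list[FoldResult]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-trial (pred, truth) sequences in drink order, from LOTO folds."""
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for f in folds:
        order = np.argsort(f.drink_index, kind="stable")
        out[f.held_out] = (f.y_pred[order], f.y_true[order])
    return out
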
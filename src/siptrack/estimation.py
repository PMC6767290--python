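"""Volume and fill-ratio regression with leave-one-trial-out validation.

Epsilon-insensitive support vector regression over the IS feature set,
with three kernels: linear, medium Gaussian (kernel scale 5.7, about
sqrt(33)) and coarse Gaussian (kernel scale 23, about 4*sqrt(33)).  The
Gaussian kernel is k(u, v) = exp(-||u - v||^2 / scale^2), evaluated on
z-score-standardised features, so the scales are calibrated to the
dimensionality of the standardised feature space.  Unless overridden, the
box constraint defaults to iqr(y)/1.349 and the epsilon tube to
iqr(y)/13.49 (iqr/1.349 is a robust estimate of the standard deviation of
the response).

Validation is leave-one-trial-out (LOTO): one fold per experimental
trial, trained on every other trial, so the train/test split sizes are
identical across folds.  A leave-one-subject-out (LOSO) mode is available
through the ``group_by`` argument.  Standardisation parameters are fit on
the training folds only.

Two strategies for injecting fill-ratio information into volume models
are provided: restricting the training set to the k drinks whose
fill-ratio labels are nearest the query drink's (estimated or true) fill
ratio, and appending the fill ratio as a 34th feature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.svm import SVR

from .io_types import ValidationError

__all__ = [
    "KERNEL_SCALES",
    "ModelSpec",
    "TrainedModel",
    "FoldResult",
    "fit",
    "fit_lr_single",
    "loto_evaluate",
    "condition_training_set",
    "append_fill_ratio_feature",
]

#: published kernel scales for the Gaussian SVR variants
KERNEL_SCALES = {"medium": 5.7, "coarse": 23.0}


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of one regression model.

    ``model`` is ``"svm"`` or ``"lr_single"`` (single-factor ordinary
    least squares; ``lr_feature`` names the factor).  ``kernel_scale``,
    ``box_constraint`` and ``epsilon_tube`` default to the conventions in
    the module docstring when None.
    """

    target: str = "volume"  # "volume" | "fill_ratio"
    model: str = "svm"  # "svm" | "lr_single"
    kernel: str = "medium"  # "linear" | "medium" | "coarse"
    kernel_scale: float | None = None
    box_constraint: float | None = None
    epsilon_tube: float | None = None
    scope: str = "macro"  # "macro" | "sip"
    lr_feature: str | None = None
    fr_source: str | None = None  # "truth" | "estimate" when FR information is used

    def __post_init__(self) -> None:
        if self.target not in ("volume", "fill_ratio"):
            raise ValidationError(f"unknown target {self.target!r}")
        if self.model not in ("svm", "lr_single"):
            raise ValidationError(f"unknown model {self.model!r}")
        if self.kernel not in ("linear", "medium", "coarse"):
            raise ValidationError(f"unknown kernel {self.kernel!r}")
        if self.kernel_scale is not None and self.kernel_scale <= 0:
            raise ValidationError("kernel_scale must be positive")

    @property
    def effective_kernel_scale(self) -> float | None:
        if self.kernel == "linear":
            return None
        return self.kernel_scale if self.kernel_scale is not None else KERNEL_SCALES[self.kernel]


@dataclass
class TrainedModel:
    """A fitted regressor plus the standardisation learned on its training set."""

    spec: ModelSpec
    mean: np.ndarray
    sd: np.ndarray
    kept: np.ndarray  # boolean mask of retained (non-constant) features
    regressor: object
    provenance: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        Z = (X[:, self.kept] - self.mean) / self.sd
        return np.asarray(self.regressor.predict(Z), dtype=float)


@dataclass(frozen=True)
class FoldResult:
    """Held-out predictions for one LOTO fold."""

    held_out: str
    y_true: np.ndarray
    y_pred: np.ndarray
    drink_index: np.ndarray
    train_groups: tuple[str, ...]
    standardization_mean: np.ndarray


def _default_hyperparameters(y: np.ndarray) -> tuple[float, float]:
    iqr = float(stats.iqr(y))
    if iqr <= 0:
        # degenerate (near-constant) response: fall back to unit box
        return 1.0, 0.1
    return iqr / 1.349, iqr / 13.49


def fit(spec: ModelSpec, X: np.ndarray, y: np.ndarray) -> TrainedModel:
    """Fit an SVR under ``spec`` with training-set z-score standardisation.

    Zero-variance features are dropped (with a warning) before
    standardisation.  Predictions are returned in label units.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValidationError("X must be 2-D with one row per label")
    if len(y) < 2:
        raise ValidationError("need at least 2 training rows")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValidationError("non-finite values in training data")

    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    kept = sd > 0
    if not kept.all():
        warnings.warn(
            f"dropping {int((~kept).sum())} zero-variance feature(s)", stacklevel=2
        )
    if not kept.any():
        raise ValidationError("all features have zero variance")
    Z = (X[:, kept] - mean[kept]) / sd[kept]

    C = spec.box_constraint
    eps = spec.epsilon_tube
    if C is None or eps is None:
        c_def, e_def = _default_hyperparameters(y)
        C = c_def if C is None else C
        eps = e_def if eps is None else eps

    if spec.kernel == "linear":
        reg = SVR(kernel="linear", C=C, epsilon=eps)
    else:
        scale = spec.effective_kernel_scale
        reg = SVR(kernel="rbf", gamma=1.0 / scale**2, C=C, epsilon=eps)
    reg.fit(Z, y)
    return TrainedModel(
        spec=spec, mean=mean[kept], sd=sd[kept], kept=kept, regressor=reg
    )


class _Line:
    """y = b0 + b1 * f, closed-form least squares on a single factor."""

    def __init__(self, b0: float, b1: float):
        self.b0, self.b1 = b0, b1

    def predict(self, Z: np.ndarray) -> np.ndarray:
        return self.b0 + self.b1 * np.asarray(Z, float).ravel()


def fit_lr_single(feature: np.ndarray, y: np.ndarray, spec: ModelSpec | None = None) -> TrainedModel:
    """Ordinary least-squares line through (feature, y) pairs.

    The single-factor benchmark models regress volume on sip duration or
    on the integral of inclination, and fill ratio on max inclination.
    """
    f = np.asarray(feature, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(f) != len(y) or len(y) < 2:
        raise ValidationError("need at least 2 matched (feature, y) points")
    if np.std(f) == 0:
        raise ValidationError("zero-variance feature cannot be regressed on")
    b1, b0 = np.polyfit(f, y, 1)
    spec = spec or ModelSpec(model="lr_single")
    return TrainedModel(
        spec=spec,
        mean=np.zeros(1),
        sd=np.ones(1),
        kept=np.ones(1, dtype=bool),
        regressor=_Line(float(b0), float(b1)),
    )


def condition_training_set(
    train_labels_fr: np.ndarray, query_fr: float, k: int = 150
) -> np.ndarray:
    """Indices of the k training drinks with fill-ratio labels nearest the query.

    Distance is |FR_label - query_fr|; ties break by original row order.
    """
    fr = np.asarray(train_labels_fr, dtype=float).ravel()
    if k > len(fr):
        raise ValidationError(f"k={k} exceeds training size {len(fr)}")
    order = np.argsort(np.abs(fr - query_fr), kind="stable")
    return np.sort(order[:k])


def append_fill_ratio_feature(
    X: np.ndarray, fr: np.ndarray, source: str
) -> tuple[np.ndarray, dict]:
    """Append the fill ratio as an extra feature column.

    The column is standardised together with the rest at fit time.
    Returns the augmented matrix and a provenance record noting whether
    the values are ground truth or upstream estimates.
    """
    X = np.asarray(X, dtype=float)
    fr = np.asarray(fr, dtype=float).ravel()
    if len(fr) != len(X):
        raise ValidationError(f"fr has {len(fr)} rows, X has {len(X)}")
    if source not in ("truth", "estimate"):
        raise ValidationError(f"fr source must be 'truth' or 'estimate', got {source!r}")
    return np.column_stack([X, fr]), {"fill_ratio_source": source}


def _fit_any(spec: ModelSpec, X: np.ndarray, y: np.ndarray) -> TrainedModel:
    if spec.model == "lr_single":
        return fit_lr_single(X[:, 0], y, spec=spec)
    return fit(spec, X, y)


def loto_evaluate(
    spec: ModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    trial_ids: np.ndarray,
    drink_index: np.ndarray | None = None,
    group_by: np.ndarray | None = None,
    fr: np.ndarray | None = None,
    fr_query: np.ndarray | None = None,
    strategy: str = "none",
    k_nearest: int = 150,
) -> list[FoldResult]:
    """Leave-one-trial-out evaluation of a model spec.

    One fold per unique value of ``group_by`` (default: ``trial_ids``,
    i.e. LOTO; pass subject ids for LOSO).  Fold order and every fit are
    deterministic given the inputs.

    ``strategy`` injects fill-ratio information into the fold fits:

    * ``"none"`` — plain fit on all training rows;
    * ``"append"`` — ``fr`` (training labels) and ``fr_query`` (held-out
      values, truth or estimate) become a 34th feature;
    * ``"partition"`` — for each held-out drink, the model is refit on the
      ``k_nearest`` training drinks whose fill-ratio labels are closest to
      that drink's ``fr_query`` value.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    trial_ids = np.asarray(trial_ids)
    groups = trial_ids if group_by is None else np.asarray(group_by)
    if drink_index is None:
        drink_index = np.zeros(len(y), dtype=int)
    drink_index = np.asarray(drink_index)
    unique_groups = sorted(set(groups.tolist()))
    if len(unique_groups) < 2:
        raise ValidationError("need at least 2 trials/groups for leave-one-out")
    if strategy not in ("none", "append", "partition"):
        raise ValidationError(f"unknown strategy {strategy!r}")
    if strategy != "none" and (fr is None or fr_query is None):
        raise ValidationError(f"strategy {strategy!r} requires fr and fr_query")

    results: list[FoldResult] = []
    for g in unique_groups:
        test = groups == g
        train = ~test
        X_tr, y_tr = X[train], y[train]
        if strategy == "append":
            X_tr, _ = append_fill_ratio_feature(X_tr, fr[train], spec.fr_source or "truth")
            X_te, _ = append_fill_ratio_feature(X[test], fr_query[test], spec.fr_source or "truth")
            model = _fit_any(spec, X_tr, y_tr)
            pred = model.predict(X_te)
        elif strategy == "partition":
            k = min(k_nearest, len(y_tr))
            preds = []
            for i in np.flatnonzero(test):
                sel = condition_training_set(fr[train], float(fr_query[i]), k)
                model = _fit_any(spec, X_tr[sel], y_tr[sel])
                preds.append(model.predict(X[i][None, :])[0])
            pred = np.asarray(preds)
            model = _fit_any(spec, X_tr, y_tr)  # fold-level standardisation record
        else:
            model = _fit_any(spec, X_tr, y_tr)
            pred = model.predict(X[test])
        results.append(
            FoldResult(
                held_out=str(g),
                y_true=y[test].copy(),
                y_pred=pred,
                drink_index=drink_index[test].copy(),
                train_groups=tuple(str(u) for u in unique_groups if u != g),
                standardization_mean=model.mean.copy(),
            )
        )
    return results
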
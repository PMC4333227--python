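"""Multi-class SVM recursive feature elimination (MSVM-RFE).

The decoder couples three ingredients:

* a from-scratch soft-margin linear SVM (primal objective
  ``J(w) = 1/2 ||w||^2 + C sum_i xi_i`` subject to
  ``y_i (w'x_i + b) >= 1 - xi_i``), solved in the dual by SMO;
* one-vs-rest aggregation over the K sound categories, with the per-voxel
  ranking criterion ``sum_c w_{c,j}^2`` (summed squared discriminative
  weights over the K binary models);
* recursive elimination that halves the active voxel set each iteration
  (ceil rounding, floor at one voxel), recording a leave-one-run-out
  cross-validation error at every step; the subset with minimal CV error
  (ties resolved toward fewer voxels) defines the final model.

Features are z-scored per voxel with training statistics only; the test set
never influences standardization or selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._smo import smo_solve
from .datasets import BetaDataset

__all__ = [
    "HyperParams",
    "BinarySvmModel",
    "MultiClassModel",
    "RfeStep",
    "RfeTrace",
    "FitResult",
    "EvalResult",
    "train_binary_svm",
    "decision_function",
    "predict_binary",
    "train_multiclass",
    "decision_function_multiclass",
    "predict_multiclass",
    "ranking_scores",
    "halving_sizes",
    "run_rfe",
    "cross_validate_trace",
    "fit_msvm_rfe",
    "evaluate",
]


@dataclass
class HyperParams:
    """Decoder hyper-parameters.

    C balances training accuracy against margin (fixed, not tuned);
    ``cv_scheme`` names the inner CV used to size the voxel subset
    (leave-one-run-out); ``halving_floor`` is the smallest subset the
    elimination descends to; ``standardize`` toggles per-voxel z-scoring on
    training statistics.
    """

    C: float = 1.0
    cv_scheme: str = "leave-one-run-out"
    halving_floor: int = 1
    standardize: bool = True
    tol: float = 1e-6
    max_iter: int = 2_000_000
    seed: int = 0

    def __post_init__(self):
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.halving_floor < 1:
            raise ValueError("halving_floor must be >= 1")


@dataclass(eq=False)
class BinarySvmModel:
    """One trained soft-margin linear SVM."""

    w: np.ndarray
    b: float
    C: float
    slack: np.ndarray
    objective_value: float
    alpha: np.ndarray = None
    n_iter: int = 0


@dataclass(eq=False)
class MultiClassModel:
    """K one-vs-rest binary SVMs sharing one active voxel set.

    ``mean_``/``scale_`` hold the training z-scoring (None if disabled);
    they are applied inside decision/prediction so the model is
    self-contained.
    """

    class_labels: list
    models: list
    active_voxels: np.ndarray
    mean_: np.ndarray = None
    scale_: np.ndarray = None


def _validate_xy(X, y):
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    y = np.asarray(y, dtype=float)
    if y.shape != (X.shape[0],):
        raise ValueError("y length must match X rows")
    if not np.all(np.isin(y, (-1.0, 1.0))):
        raise ValueError("y must contain only +1/-1")
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present in y")
    return X, y


def train_binary_svm(
    X, y_pm1, C: float = 1.0, tol: float = 1e-6, max_iter: int = 2_000_000, K=None
) -> BinarySvmModel:
    """Fit the soft-margin linear SVM by SMO on the dual.

    ``K`` may supply a precomputed Gram matrix ``X X'`` (shared across the
    one-vs-rest models).  The bias is recovered from the free support
    vectors, or from the midpoint of the KKT-feasible interval when no
    support vector is strictly inside the box.
    """
    X, y = _validate_xy(X, y_pm1)
    if C <= 0:
        raise ValueError("C must be > 0")
    if K is None:
        K = X @ X.T
    alpha, n_iter, _gap = smo_solve(
        np.ascontiguousarray(K, dtype=float), y, float(C), float(tol), int(max_iter)
    )
    w = X.T @ (alpha * y)
    scores = X @ w
    eps = 1e-8 * max(1.0, C)
    free = (alpha > eps) & (alpha < C - eps)
    if np.any(free):
        b = float(np.mean(y[free] - scores[free]))
    else:
        # KKT bounds: alpha=0 -> y(score+b) >= 1 ; alpha=C -> y(score+b) <= 1
        lo, hi = -np.inf, np.inf
        for i in range(len(y)):
            bound = y[i] - scores[i]
            at_c = alpha[i] >= C - eps
            # (y=+1, alpha=0) or (y=-1, alpha=C) force b >= bound;
            # the other two combinations force b <= bound
            if (y[i] > 0) != at_c:
                lo = max(lo, bound)
            else:
                hi = min(hi, bound)
        if not np.isfinite(lo):
            b = float(hi) if np.isfinite(hi) else 0.0
        elif not np.isfinite(hi):
            b = float(lo)
        else:
            b = float((lo + hi) / 2.0)
    slack = np.maximum(0.0, 1.0 - y * (scores + b))
    objective = 0.5 * float(w @ w) + C * float(slack.sum())
    return BinarySvmModel(
        w=w, b=b, C=float(C), slack=slack,
        objective_value=objective, alpha=alpha, n_iter=n_iter,
    )


def decision_function(model: BinarySvmModel, X_new) -> np.ndarray:
    """Signed distance scores ``w'x + b``."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != model.w.shape[0]:
        raise ValueError(
            f"expected {model.w.shape[0]} features, got {X_new.shape[1]}"
        )
    return X_new @ model.w + model.b


def predict_binary(model: BinarySvmModel, X_new) -> np.ndarray:
    """+1 where the score is > 0, -1 where < 0; exact zero maps to +1."""
    s = decision_function(model, X_new)
    return np.where(s >= 0.0, 1.0, -1.0)


def train_multiclass(
    X, y_categorical, params: HyperParams = None,
    class_labels=None, active_voxels=None,
) -> MultiClassModel:
    """One-vs-rest multi-class SVM on (optionally z-scored) features.

    Class order defaults to the sorted unique labels; every class must be
    present in ``y_categorical``.  The Gram matrix is computed once and
    shared by the K binary fits.
    """
    params = params or HyperParams()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y_categorical)
    if class_labels is None:
        class_labels = sorted(pd.unique(y).tolist())
    missing = [c for c in class_labels if not np.any(y == c)]
    if missing:
        raise ValueError(f"classes absent from training data: {missing}")
    if len(class_labels) < 2:
        raise ValueError("need at least 2 classes")
    mean = scale = None
    Z = X
    if params.standardize:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale < 1e-12, 1.0, scale)
        Z = (X - mean) / scale
    K = Z @ Z.T
    models = []
    for c in class_labels:
        yc = np.where(y == c, 1.0, -1.0)
        models.append(
            train_binary_svm(
                Z, yc, C=params.C, tol=params.tol, max_iter=params.max_iter, K=K
            )
        )
    if active_voxels is None:
        active_voxels = np.arange(X.shape[1])
    return MultiClassModel(
        class_labels=list(class_labels),
        models=models,
        active_voxels=np.asarray(active_voxels, dtype=int),
        mean_=mean,
        scale_=scale,
    )


def decision_function_multiclass(model: MultiClassModel, X_new) -> np.ndarray:
    """n x K matrix of one-vs-rest scores (standardization applied)."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if model.mean_ is not None:
        X_new = (X_new - model.mean_) / model.scale_
    return np.column_stack([X_new @ m.w + m.b for m in model.models])


def predict_multiclass(model: MultiClassModel, X_new) -> np.ndarray:
    """Argmax over one-vs-rest scores; ties go to the earlier class label."""
    scores = decision_function_multiclass(model, X_new)
    idx = np.argmax(scores, axis=1)
    return np.asarray([model.class_labels[i] for i in idx])


def ranking_scores(model) -> np.ndarray:
    """Per-voxel discriminative weight: w_j^2 summed over the OVR models."""
    if isinstance(model, BinarySvmModel):
        return model.w ** 2
    return np.sum([m.w ** 2 for m in model.models], axis=0)


def halving_sizes(p: int, floor: int = 1) -> list:
    """Active-set sizes visited by ceil-halving from p down to the floor."""
    if p < 1:
        raise ValueError("p must be >= 1")
    sizes = [int(p)]
    while sizes[-1] > floor:
        sizes.append(max((sizes[-1] + 1) // 2, floor))
    return sizes


@dataclass(eq=False)
class RfeStep:
    """One elimination step: the surviving voxels, their ranking scores from
    the model trained on them, and the step's cross-validated error."""

    active_voxels: np.ndarray
    scores: np.ndarray
    cv_error: float

    @property
    def n(self) -> int:
        return len(self.active_voxels)


@dataclass(eq=False)
class RfeTrace:
    """Nested sequence of active-voxel sets from recursive elimination."""

    steps: list

    @property
    def sizes(self) -> list:
        return [s.n for s in self.steps]


def cross_validate_trace(
    X, y, active_voxels, params: HyperParams = None, groups=None, class_labels=None
) -> float:
    """Leave-one-run-out error of the multi-class SVM on one voxel subset.

    ``groups`` are the per-sample run labels; each unique run is held out
    once, the model is trained (with fold-local standardization) on the
    remaining runs, and the mean misclassification rate over folds is
    returned.
    """
    params = params or HyperParams()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if groups is None:
        raise ValueError("cross-validation requires per-sample run labels")
    groups = np.asarray(groups)
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least 2 runs for leave-one-run-out CV")
    active = np.asarray(active_voxels, dtype=int)
    errors = []
    for g in uniq:
        test = groups == g
        train = ~test
        model = train_multiclass(
            X[np.ix_(train, active)], y[train], params, class_labels=class_labels
        )
        pred = predict_multiclass(model, X[np.ix_(test, active)])
        errors.append(float(np.mean(pred != y[test])))
    return float(np.mean(errors))


def run_rfe(
    X, y, params: HyperParams = None, groups=None, class_labels=None
) -> RfeTrace:
    """Recursive feature elimination with halving.

    At each step the one-vs-rest model is retrained on the survivors, each
    voxel scored by summed squared weights, and the lowest-scoring half
    eliminated (ceil of p/2 survives; score ties eliminate the lower voxel
    index first).  Every step records the leave-one-run-out CV error of its
    active set.  The final step has ``params.halving_floor`` voxels.
    """
    params = params or HyperParams()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1 or X.shape[0] < 1:
        raise ValueError("X must be a non-empty samples x voxels matrix")
    y = np.asarray(y)
    if class_labels is None:
        class_labels = sorted(pd.unique(y).tolist())
    active = np.arange(X.shape[1])
    steps = []
    while True:
        model = train_multiclass(
            X[:, active], y, params, class_labels=class_labels
        )
        scores = ranking_scores(model)
        cv_err = cross_validate_trace(
            X, y, active, params, groups=groups, class_labels=class_labels
        )
        steps.append(
            RfeStep(active_voxels=active.copy(), scores=scores, cv_error=cv_err)
        )
        if len(active) <= params.halving_floor:
            break
        n_keep = max((len(active) + 1) // 2, params.halving_floor)
        # ascending (score, voxel index): lowest scores go first, ties by
        # lower voxel index, so those are eliminated first
        order = np.lexsort((active, scores))
        keep = order[len(active) - n_keep:]
        active = np.sort(active[keep])
    return RfeTrace(steps=steps)


@dataclass(eq=False)
class FitResult:
    """Outcome of one MSVM-RFE fit on a training set."""

    trace: RfeTrace
    selected_voxels: np.ndarray
    final_model: MultiClassModel
    standardization: tuple  # (mean, scale) over selected voxels, or None
    n_features: int


@dataclass(eq=False)
class EvalResult:
    """Test-set accuracy and per-class confusion (rows = true class)."""

    accuracy: float
    confusion: pd.DataFrame


def fit_msvm_rfe(train: BetaDataset, params: HyperParams = None) -> FitResult:
    """Full decoder fit: RFE trace, CV-based subset choice, final model.

    The run label is the CV grouping (for pooled multi-subject training
    sets, a fold holds out the same run index of every subject).  The
    selected subset is the trace step with minimal CV error; ties resolve
    toward the smaller voxel set.
    """
    params = params or HyperParams()
    y = train.labels["category"].to_numpy()
    groups = train.labels["run"].to_numpy()
    class_labels = sorted(pd.unique(y).tolist())
    trace = run_rfe(train.X, y, params, groups=groups, class_labels=class_labels)
    best = trace.steps[0]
    for step in trace.steps[1:]:
        if step.cv_error <= best.cv_error:  # later steps are smaller sets
            best = step
    selected = best.active_voxels
    final = train_multiclass(
        train.X[:, selected], y, params,
        class_labels=class_labels, active_voxels=selected,
    )
    return FitResult(
        trace=trace,
        selected_voxels=selected,
        final_model=final,
        standardization=(final.mean_, final.scale_),
        n_features=train.X.shape[1],
    )


def evaluate(fit: FitResult, test: BetaDataset) -> EvalResult:
    """Apply a fitted decoder to an independent test set.

    Training standardization and voxel selection are applied to the test
    patterns; accuracy is the fraction of correct category predictions, and
    the confusion matrix rows sum to the per-class test counts.
    """
    if test.X.shape[1] != fit.n_features:
        raise ValueError(
            f"test set has {test.X.shape[1]} voxels, fit expects "
            f"{fit.n_features}"
        )
    y_true = test.labels["category"].to_numpy()
    pred = predict_multiclass(fit.final_model, test.X[:, fit.selected_voxels])
    classes = list(fit.final_model.class_labels)
    extra = [c for c in pd.unique(y_true) if c not in classes]
    all_classes = classes + sorted(extra)
    conf = pd.DataFrame(0, index=all_classes, columns=all_classes, dtype=int)
    for t, q in zip(y_true, pred):
        conf.loc[t, q] += 1
    return EvalResult(accuracy=float(np.mean(pred == y_true)), confusion=conf)
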
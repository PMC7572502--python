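"""Nested cross-validated evaluation of sparse logistic-regression classifiers.

The evaluation protocol: the full data set is shuffled; a stratified 5-fold
outer split estimates generalization; within each outer training fold a
stratified 3-fold inner loop picks the inverse regularization strength C of
an L1-penalized logistic regression by ROC-AUC; the selected model is refit
on the outer training fold and scored on the held-out fold. The whole
procedure is repeated on independent full-data shuffles (30 by default) and
summarized as mean AUC, SD across shuffles, and a 95% CI half-width using
the average test-fold size as the effective sample size. Test AUCs below
0.5 are retained as-is — overfit models are not floored. When a feature
regime leaves zero features the degenerate convention applies: AUC is
recorded as exactly 0.5 and no model is trained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    balanced_accuracy_score,
    confusion_matrix,
    matthews_corrcoef,
    roc_auc_score,
)
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.utils import shuffle as _shuffle

from . import stats
from .tables import FeatureTable, ValidationError

__all__ = [
    "CVProtocol",
    "EvaluationResult",
    "nested_cv_l1lr",
    "fold_metrics",
    "summarize",
    "classifier_contract",
    "CLASSIFIER_REGISTRY",
]

SECONDARY_METRICS = ("balanced_accuracy", "mcc", "sensitivity", "specificity", "precision")


@dataclass(frozen=True)
class CVProtocol:
    """Nested cross-validation protocol parameters."""

    outer_folds: int = 5
    inner_folds: int = 3
    c_grid: tuple[float, ...] = (2, 5, 20, 50, 100)
    n_shuffles: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValidationError("outer_folds and inner_folds must be >= 2")
        if not self.c_grid or any(c <= 0 for c in self.c_grid):
            raise ValidationError("c_grid must be non-empty with all entries > 0")
        if self.n_shuffles < 1:
            raise ValidationError("n_shuffles must be >= 1")


@dataclass(frozen=True)
class EvaluationResult:
    """Aggregated nested-CV evaluation output."""

    per_shuffle_auc: tuple[float, ...]
    mean_auc: float
    sd_auc: float
    ci95_halfwidth: float
    secondary: dict = field(default_factory=dict)
    mean_coefficients: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    n_nonzero: int = 0
    avg_test_n: float = 0.0
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.mean_auc <= 1.0) or self.sd_auc < 0:
            raise ValidationError("mean_auc must lie in [0,1] and sd_auc be >= 0")
        if self.degenerate:
            if any(a != 0.5 for a in self.per_shuffle_auc) or len(self.mean_coefficients):
                raise ValidationError("degenerate results must be all-0.5 with empty coefficients")
        if self.n_nonzero > len(self.mean_coefficients):
            raise ValidationError("n_nonzero cannot exceed the number of features")


def summarize(per_shuffle_auc, avg_test_n: float) -> tuple[float, float, float]:
    """Mean, SD and 95% CI half-width of the per-shuffle AUCs.

    The CI half-width is 1.96 * SD / sqrt(avg_test_n): the average test-fold
    size stands in for the sample size to reflect the larger uncertainty of
    small data sets.
    """
    auc = np.asarray(per_shuffle_auc, dtype=float)
    if auc.size == 0:
        raise ValidationError("per_shuffle_auc must be non-empty")
    if avg_test_n < 1:
        raise ValidationError("avg_test_n must be >= 1")
    mean = float(auc.mean())
    sd = float(auc.std(ddof=1)) if auc.size > 1 else 0.0
    return mean, sd, 1.96 * sd / np.sqrt(avg_test_n)


def fold_metrics(y_true, y_score, y_pred) -> dict:
    """ROC-AUC plus confusion-matrix metrics for one test fold.

    Hard-label metrics use the model's 0.5-probability threshold predictions
    supplied in ``y_pred``. Precision is NaN when nothing is predicted
    positive.
    """
    y_true = np.asarray(y_true)
    if np.unique(y_true).size < 2:
        raise ValidationError("fold_metrics needs both classes in y_true")
    tn, fp, fn, tp = confusion_matrix(y_true, y_pred, labels=[0, 1]).ravel()
    return {
        "auc": float(roc_auc_score(y_true, y_score)),
        "balanced_accuracy": float(balanced_accuracy_score(y_true, y_pred)),
        "mcc": float(matthews_corrcoef(y_true, y_pred)),
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "precision": tp / (tp + fp) if tp + fp else float("nan"),
    }


def _degenerate_result(protocol: CVProtocol, avg_test_n: float) -> EvaluationResult:
    aucs = tuple(0.5 for _ in range(protocol.n_shuffles))
    return EvaluationResult(
        per_shuffle_auc=aucs, mean_auc=0.5, sd_auc=0.0, ci95_halfwidth=0.0,
        secondary={m: float("nan") for m in SECONDARY_METRICS},
        mean_coefficients=pd.Series(dtype=float), n_nonzero=0,
        avg_test_n=avg_test_n, degenerate=True,
    )


def nested_cv_l1lr(
    table: FeatureTable,
    protocol: CVProtocol = CVProtocol(),
    regime: "stats.RegimeSpec | None" = None,
) -> EvaluationResult:
    """Evaluate L1-regularized logistic regression under nested CV.

    When ``regime`` is a within-fold regime (significant_only /
    top_k_significant), per-feature significance is recomputed on each outer
    training fold and the regime applied before fitting, so the held-out
    fold never influences feature selection. Non-fold regimes
    (nonsignificant_only and friends) must be applied to the table before
    calling, since their significance source is the complete data set.

    Deterministic given (table, protocol): shuffle i uses seed + i.
    """
    y = np.asarray(table.labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValidationError("nested_cv_l1lr requires binary labels")
    if counts.min() < protocol.outer_folds:
        raise ValidationError(
            f"each class needs >= {protocol.outer_folds} samples for stratified outer folds")
    n = table.n_samples
    avg_test_n = n / protocol.outer_folds
    if table.n_features == 0:
        return _degenerate_result(protocol, avg_test_n)
    if regime is not None and not regime.within_fold and regime.kind != "all":
        raise ValidationError(
            "only within-fold regimes may be passed to nested_cv_l1lr; apply "
            f"{regime.kind!r} to the table beforehand")

    X = table.values
    fids = table.feature_ids
    per_shuffle_auc: list[float] = []
    fold_rows: list[dict] = []
    coef_sum = np.zeros(table.n_features)
    n_models = 0

    for i in range(protocol.n_shuffles):
        Xi, yi = _shuffle(X, y, random_state=protocol.seed + i)
        outer = StratifiedKFold(n_splits=protocol.outer_folds)
        fold_aucs: list[float] = []
        for tr, te in outer.split(Xi, yi):
            cols = np.arange(Xi.shape[1])
            if regime is not None and regime.within_fold:
                sig = stats.significance_table(Xi[tr], yi[tr], fids)
                keep = set(stats.select_feature_ids(sig, regime))
                cols = np.flatnonzero([fid in keep for fid in fids])
            if cols.size == 0:
                # degenerate fold: AUC recorded as 0.5, training stopped
                fold_aucs.append(0.5)
                n_models += 1
                continue
            # l1_ratio=1 selects the pure L1 penalty
            base = LogisticRegression(
                l1_ratio=1, solver="liblinear", tol=1e-4, max_iter=500,
                intercept_scaling=1, random_state=protocol.seed + i,
            )
            clf = GridSearchCV(
                base, {"C": list(protocol.c_grid)},
                cv=StratifiedKFold(n_splits=protocol.inner_folds),
                scoring="roc_auc", refit=True,
            )
            clf.fit(Xi[np.ix_(tr, cols)], yi[tr])
            score = clf.predict_proba(Xi[np.ix_(te, cols)])[:, 1]
            pred = clf.predict(Xi[np.ix_(te, cols)])
            m = fold_metrics(yi[te], score, pred)
            fold_aucs.append(m.pop("auc"))
            fold_rows.append(m)
            coef_sum[cols] += clf.best_estimator_.coef_[0]
            n_models += 1
        per_shuffle_auc.append(float(np.mean(fold_aucs)))

    mean_auc, sd_auc, ci = summarize(per_shuffle_auc, avg_test_n)
    secondary = {
        k: (float(np.nanmean([r[k] for r in fold_rows])) if fold_rows else float("nan"))
        for k in SECONDARY_METRICS
    }
    mean_coef = pd.Series(coef_sum / max(n_models, 1), index=pd.Index(fids, name="feature_id"))
    return EvaluationResult(
        per_shuffle_auc=tuple(per_shuffle_auc),
        mean_auc=mean_auc, sd_auc=sd_auc, ci95_halfwidth=ci,
        secondary=secondary, mean_coefficients=mean_coef,
        n_nonzero=int((mean_coef != 0).sum()), avg_test_n=avg_test_n,
        degenerate=False,
    )


CLASSIFIER_REGISTRY: dict[str, object] = {"l1lr": nested_cv_l1lr}

# Classifiers the evaluation harness knows of but does not implement.
_KNOWN_UNIMPLEMENTED = ("plsda", "rf", "svm", "knn", "nb")


def classifier_contract(name: str, table: FeatureTable, protocol: CVProtocol = CVProtocol(),
                        regime: "stats.RegimeSpec | None" = None) -> EvaluationResult:
    """Run a registered classifier through the shared nested-CV harness."""
    if name in CLASSIFIER_REGISTRY:
        return CLASSIFIER_REGISTRY[name](table, protocol, regime)
    if name in _KNOWN_UNIMPLEMENTED:
        raise NotImplementedError(
            f"classifier {name!r} is recognised but not implemented; available: "
            f"{sorted(CLASSIFIER_REGISTRY)}")
    raise ValidationError(f"unknown classifier {name!r}; available: {sorted(CLASSIFIER_REGISTRY)}")
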
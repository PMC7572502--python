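"""Per-feature rank testing, FDR control, enrichment, and feature regimes.

Feature selection is a leakage hazard: choosing features with any influence
from the test partition inflates measured performance. The significance
machinery here is therefore designed to be called *inside* the training
loop — :func:`significance_on_training_fold` sees only the training split —
except for the non-significant-feature regimes, which deliberately remove
the features found significant on the complete data set before any
cross-validation (removing information can only make the remaining task
harder, so this direction carries no optimistic leakage).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .adducts import ExplanationMap
from .tables import FeatureTable, ValidationError

__all__ = [
    "SIGNIFICANCE_Q",
    "RegimeSpec",
    "REGIME_KINDS",
    "mwu_test",
    "bh_fdr",
    "enrichment_factor",
    "significance_table",
    "significance_on_training_fold",
    "select_feature_ids",
    "apply_regime",
]

SIGNIFICANCE_Q = 0.05

REGIME_KINDS = (
    "all",
    "significant_only",
    "top_k_significant",
    "nonsignificant_only",
    "nonsignificant_no_satellites",
)


@dataclass(frozen=True)
class RegimeSpec:
    """A feature-selection regime applied before model fitting."""

    kind: str
    k: int | None = None
    explanation_map: ExplanationMap | None = None

    def __post_init__(self) -> None:
        if self.kind not in REGIME_KINDS:
            raise ValidationError(f"unknown regime kind {self.kind!r}")
        if self.kind == "top_k_significant" and (self.k is None or self.k <= 0):
            raise ValidationError("top_k_significant requires k > 0")
        if (self.kind == "nonsignificant_no_satellites") != (self.explanation_map is not None):
            raise ValidationError(
                "explanation_map must be given exactly when kind is nonsignificant_no_satellites")

    @property
    def within_fold(self) -> bool:
        """Whether the regime recomputes significance inside each training fold."""
        return self.kind in ("significant_only", "top_k_significant")


def mwu_test(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of control values ``x`` vs case values ``y``.

    Exact enumeration when both groups have <= 8 observations and there are
    no ties; normal approximation with tie and continuity correction
    otherwise. Returns (U statistic of ``x``, two-sided P).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and no_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    p = float(res.pvalue)
    if np.isnan(p):  # all values tied: zero-variance normal approximation
        p = 1.0
    return float(res.statistic), min(p, 1.0)


def _mwu_matrix(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise MW-U over a feature matrix, choosing the branch per column."""
    if x.shape[0] <= 8 and y.shape[0] <= 8:
        out = [mwu_test(x[:, j], y[:, j]) for j in range(x.shape[1])]
        u, p = map(np.asarray, zip(*out))
        return u, p
    res = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic", axis=0)
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    return np.asarray(res.statistic, dtype=float), np.minimum(p, 1.0)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values (Q-values).

    ``q_i = min_{j >= rank(i)} p_(j) * m / j`` clipped to 1; input order
    preserved.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrichment_factor(x, y) -> float:
    """Case-mean over control-mean ratio; NaN (not an error) when undefined."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mx = x.mean()
    if mx == 0:
        return float("nan")
    return float(y.mean() / mx)


def significance_table(values: np.ndarray, labels: np.ndarray,
                       feature_ids) -> pd.DataFrame:
    """Per-feature MW-U + BH-FDR significance table.

    Columns: ``u_stat``, ``p_value``, ``q_value``, ``enrichment``,
    ``significant`` (q < 0.05); indexed by feature_id.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValidationError("significance requires exactly two classes present")
    x = values[labels == classes[0]]
    y = values[labels == classes[1]]
    u, p = _mwu_matrix(x, y)
    q = bh_fdr(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        ctrl_mean = x.mean(axis=0)
        enr = np.where(ctrl_mean == 0, np.nan, y.mean(axis=0) / np.where(ctrl_mean == 0, 1, ctrl_mean))
    return pd.DataFrame(
        {"u_stat": u, "p_value": p, "q_value": q, "enrichment": enr,
         "significant": q < SIGNIFICANCE_Q},
        index=pd.Index(feature_ids, name="feature_id"),
    )


def significance_on_training_fold(train: FeatureTable) -> pd.DataFrame:
    """Significance table computed on a training partition only.

    This is what the within-fold regimes consume; test samples never
    influence it.
    """
    return significance_table(train.values, train.labels, train.feature_ids)


def select_feature_ids(sig: pd.DataFrame, spec: RegimeSpec) -> np.ndarray:
    """Feature ids surviving a regime, given a significance table.

    For ``top_k_significant``, the k smallest-q significant features are
    kept (ties broken lexicographically by feature_id); if fewer than k are
    significant, all of them are used.
    """
    if spec.kind == "all":
        return sig.index.to_numpy()
    if spec.kind == "significant_only":
        return sig.index[sig["significant"]].to_numpy()
    if spec.kind == "top_k_significant":
        cand = sig[sig["significant"]].copy()
        cand = cand.sort_values(["q_value", "feature_id"], kind="mergesort")
        keep = set(cand.index[: spec.k])
        return sig.index[[fid in keep for fid in sig.index]].to_numpy()
    if spec.kind == "nonsignificant_only":
        return sig.index[~sig["significant"]].to_numpy()
    if spec.kind == "nonsignificant_no_satellites":
        explained = spec.explanation_map.explained_ids
        mask = (~sig["significant"]).to_numpy() & ~np.isin(
            sig.index.to_numpy().astype(str), list(explained))
        return sig.index[mask].to_numpy()
    raise ValidationError(f"unknown regime kind {spec.kind!r}")  # pragma: no cover


def apply_regime(table: FeatureTable, sig: pd.DataFrame, spec: RegimeSpec) -> FeatureTable:
    """Restrict a table to the features surviving a regime.

    An empty result is legal: downstream evaluation records the AUC = 0.5
    degenerate convention for empty feature sets.
    """
    if not np.array_equal(sig.index.to_numpy(), table.feature_ids):
        raise ValidationError("significance table must be aligned to the table's features")
    return table.select_features(select_feature_ids(sig, spec))
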
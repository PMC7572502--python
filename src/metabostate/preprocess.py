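"""Preprocessing: intensity floor + binary log, percentile normalization
against controls, prevalence filtering, data-set combination, one-vs-one
multiclass reduction, replicate dropping.

Percentile normalization is the rank-based batch correction in which every
sample's value for a feature becomes the percentile of that value within the
batch's *control* distribution for the feature. It is invariant to any
strictly increasing transform of the raw intensities and bounds all output
in [0, 100], which makes heterogeneous batches and platforms comparable.
"""

from __future__ import annotations

from dataclasses import replace
from itertools import combinations

import numpy as np
import pandas as pd

from .tables import FeatureTable, NormalizedTable, ValidationError

__all__ = [
    "floor_and_log",
    "percentile_normalize",
    "prevalence_filter",
    "combine_datasets",
    "one_vs_one_splits",
    "drop_replicates",
]

FLOOR_LOG_STEP = "floor_log"
NORMALIZE_STEP = "percentile_normalize"


def floor_and_log(table: FeatureTable) -> FeatureTable:
    """Floor intensities below 1 (incl. missing 0s) to 1, then apply log2.

    One-shot: a provenance flag blocks accidental double application, which
    would silently re-floor already-logged values.
    """
    if FLOOR_LOG_STEP in table.provenance:
        raise ValidationError("floor_and_log already applied (provenance guard)")
    if table.values.size and table.values.min() < 0:
        raise ValidationError("intensities must be non-negative")
    out = np.log2(np.maximum(table.values, 1.0))
    return replace(table, values=out, provenance=table.provenance + (FLOOR_LOG_STEP,))


def _control_percentiles(values: np.ndarray, is_control: np.ndarray) -> np.ndarray:
    """Mean-rank percentile of every sample within the control distribution.

    For query q against n controls: 100 * (#{c < q} + 0.5 * #{c == q}) / n.
    Ties are averaged; queries below all controls map to 0, above all to 100;
    a control scored against an all-tied control set maps to 50.
    """
    n, p = values.shape
    nc = int(is_control.sum())
    out = np.empty((n, p))
    for j in range(p):
        ctrl = np.sort(values[is_control, j])
        less = np.searchsorted(ctrl, values[:, j], side="left")
        leq = np.searchsorted(ctrl, values[:, j], side="right")
        out[:, j] = 100.0 * (less + 0.5 * (leq - less)) / nc
    return out


def percentile_normalize(table: FeatureTable, per_batch: bool = True) -> NormalizedTable:
    """Transform each value to its percentile within the batch's controls.

    Each batch is normalized separately and the batches concatenated; with
    ``per_batch`` off or no batch metadata the whole table is one batch.
    Controls are scored against the control set including themselves.
    """
    if NORMALIZE_STEP in table.provenance:
        raise ValidationError("percentile_normalize already applied (provenance guard)")
    is_control = table.labels == 0
    out = np.empty_like(table.values, dtype=float)
    if per_batch and table.batches is not None:
        for batch in pd.unique(table.batches):
            rows = table.batches == batch
            ctrl = rows & is_control
            if ctrl.sum() < 2:
                raise ValidationError(f"batch {batch!r} has fewer than 2 control samples")
            out[rows] = _control_percentiles(table.values[rows], ctrl[rows])
    else:
        if is_control.sum() < 2:
            raise ValidationError("table has fewer than 2 control samples")
        out = _control_percentiles(table.values, is_control)
    return NormalizedTable(
        values=out,
        sample_ids=table.sample_ids,
        labels=table.labels,
        features=table.features,
        batches=table.batches,
        provenance=table.provenance + (NORMALIZE_STEP,),
    )


def prevalence_filter(table: FeatureTable, min_fraction: float = 0.05) -> FeatureTable:
    """Drop features detected (intensity >= 1) in <= ``min_fraction`` of samples.

    Applied to raw (pre-floor) intensities; feature order is preserved.
    """
    if not 0.0 <= min_fraction <= 1.0:
        raise ValidationError("min_fraction must lie in [0, 1]")
    detected = (table.values >= 1.0).mean(axis=0)
    return table.select_features(detected > min_fraction)


def combine_datasets(tables: list[FeatureTable], names: list[str] | None = None) -> FeatureTable:
    """Concatenate feature matrices across data sets sharing samples.

    Samples are matched by sample_id (intersection); each individual's
    per-data-set feature vectors are combined into one row. Feature ids are
    prefixed with the source data-set name to stay unique.
    """
    if not tables:
        raise ValidationError("no tables to combine")
    if names is None:
        names = [f"ds{i}" for i in range(len(tables))]
    shared = set(tables[0].sample_ids)
    for t in tables[1:]:
        shared &= set(t.sample_ids)
    if not shared:
        raise ValidationError("empty sample intersection across data sets")
    order = sorted(shared)
    label_of: dict[str, int] = {}
    for t in tables:
        for sid, lab in zip(t.sample_ids, t.labels):
            if sid in shared:
                if sid in label_of and label_of[sid] != lab:
                    raise ValidationError(f"conflicting labels for sample {sid!r}")
                label_of[sid] = lab
    parts, fmetas = [], []
    for name, t in zip(names, tables):
        sub = t.select_samples(np.array(order, dtype=object))
        parts.append(sub.values)
        fm = sub.features.copy()
        fm.index = pd.Index([f"{name}:{fid}" for fid in fm.index], name="feature_id")
        fmetas.append(fm)
    return FeatureTable(
        values=np.hstack(parts),
        sample_ids=np.array(order, dtype=object),
        labels=np.array([label_of[s] for s in order], dtype=int),
        features=pd.concat(fmetas),
        batches=None,
        provenance=tables[0].provenance + ("combine",),
    )


def one_vs_one_splits(table: FeatureTable) -> list[FeatureTable]:
    """Reduce a k-class table to its k(k-1)/2 binary one-vs-one tables.

    Within each pair the lower class code becomes 0 and the higher 1.
    A 2-class table is returned as a single-element list unchanged.
    """
    classes = sorted(np.unique(table.labels))
    if len(classes) < 2:
        raise ValidationError("one_vs_one_splits needs at least 2 classes")
    if len(classes) == 2:
        return [table]
    out = []
    for lo, hi in combinations(classes, 2):
        keep = np.isin(table.labels, [lo, hi])
        sub = table.select_samples(keep)
        relabeled = (sub.labels == hi).astype(int)
        out.append(replace(sub, labels=relabeled))
    return out


def drop_replicates(table: FeatureTable, replicate_map: dict) -> FeatureTable:
    """Keep exactly one sample per individual (first by sorted sample_id)."""
    missing = [s for s in table.sample_ids if s not in replicate_map]
    if missing:
        raise ValidationError(f"replicate_map missing samples: {missing[:5]}")
    keep: dict = {}
    for sid in sorted(table.sample_ids):
        indiv = replicate_map[sid]
        keep.setdefault(indiv, sid)
    chosen = set(keep.values())
    return table.select_samples(np.array([s in chosen for s in table.sample_ids]))
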
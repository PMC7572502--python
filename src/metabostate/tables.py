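"""Feature-table containers and their CSV/JSON serialization.

The universal currency between pipeline stages is a samples x features
intensity matrix with per-sample labels (0 = control, 1 = case, or small
integers for multiclass), optional per-sample batch identifiers, and
per-feature mass-to-charge ratio (``mz``, Daltons) and retention time
(``rt``, seconds) metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ValidationError", "FeatureTable", "NormalizedTable", "write_table", "read_table"]


class ValidationError(ValueError):
    """Raised when a container or config violates its invariants."""


@dataclass(frozen=True)
class FeatureTable:
    """A samples x features peak-intensity matrix with metadata.

    Parameters
    ----------
    values:
        Non-negative intensities (raw MS counts) or, after floor/log or
        normalization, the transformed values. Shape (n_samples, n_features).
    sample_ids:
        Unique sample identifiers, length n_samples.
    labels:
        Per-sample integer class codes aligned to ``sample_ids``.
    features:
        DataFrame indexed by unique feature_id with columns ``mz`` and ``rt``.
    batches:
        Optional per-sample batch identifiers.
    provenance:
        Ordered record of processing steps already applied; guards against
        double application of one-shot transforms.
    """

    values: np.ndarray
    sample_ids: np.ndarray
    labels: np.ndarray
    features: pd.DataFrame
    batches: np.ndarray | None = None
    provenance: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "sample_ids", np.asarray(self.sample_ids, dtype=object))
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=int))
        if self.batches is not None:
            object.__setattr__(self, "batches", np.asarray(self.batches, dtype=object))
        n, p = self.values.shape
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise ValidationError("sample_ids/labels length must match the number of rows")
        if self.batches is not None and len(self.batches) != n:
            raise ValidationError("batches length must match the number of rows")
        if len(self.features) != p:
            raise ValidationError("features metadata must match the number of columns")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("sample_ids must be unique")
        if self.features.index.has_duplicates:
            raise ValidationError("feature ids must be unique")
        for cls in np.unique(self.labels):
            if not np.any(self.labels == cls):  # pragma: no cover - tautology kept for clarity
                raise ValidationError(f"class {cls} has no samples")

    # -- convenience -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def feature_ids(self) -> np.ndarray:
        return self.features.index.to_numpy()

    def select_features(self, keep: np.ndarray) -> "FeatureTable":
        """Return a copy restricted to feature columns ``keep`` (ids or bool mask)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {fid: i for i, fid in enumerate(self.features.index)}
            idx = np.array([pos[k] for k in keep], dtype=int)
        return replace(self, values=self.values[:, idx], features=self.features.iloc[idx])

    def select_samples(self, keep: np.ndarray) -> "FeatureTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {sid: i for i, sid in enumerate(self.sample_ids)}
            idx = np.array([pos[k] for k in keep], dtype=int)
        return replace(
            self,
            values=self.values[idx],
            sample_ids=self.sample_ids[idx],
            labels=self.labels[idx],
            batches=None if self.batches is None else self.batches[idx],
        )

    def with_provenance(self, step: str) -> "FeatureTable":
        return replace(self, provenance=self.provenance + (step,))

    def to_frame(self) -> pd.DataFrame:
        """Samples x features DataFrame with mz/rt encoded in the column names."""
        cols = [f"mz_{m:.4f}_rt_{r:.1f}" for m, r in zip(self.features["mz"], self.features["rt"])]
        df = pd.DataFrame(self.values, index=pd.Index(self.sample_ids, name="sample_id"), columns=cols)
        df.insert(0, "label", self.labels)
        df.insert(1, "batch", self.batches if self.batches is not None else "")
        return df


@dataclass(frozen=True)
class NormalizedTable(FeatureTable):
    """A percentile-normalized table; values are percentile scores in [0, 100]."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.values.size and (self.values.min() < 0 or self.values.max() > 100):
            raise ValidationError("normalized values must lie in [0, 100]")


def write_table(table: FeatureTable, csv_path: str | Path, sidecar_path: str | Path | None = None,
                extra_sidecar: dict | None = None) -> None:
    """Write a table as CSV plus a JSON sidecar with feature metadata.

    CSV rows are samples; the first columns are sample_id, label, batch and
    the remaining columns are named ``mz_<mz>_rt_<rt>``.
    """
    csv_path = Path(csv_path)
    table.to_frame().to_csv(csv_path)
    if sidecar_path is None:
        sidecar_path = csv_path.with_suffix(".json")
    meta = {
        "features": [
            {"feature_id": str(fid), "mz": float(row.mz), "rt": float(row.rt)}
            for fid, row in table.features.iterrows()
        ],
        "provenance": list(table.provenance),
    }
    if extra_sidecar:
        meta.update(extra_sidecar)
    Path(sidecar_path).write_text(json.dumps(meta, indent=1))


def read_table(csv_path: str | Path, sidecar_path: str | Path | None = None) -> FeatureTable:
    """Read a table written by :func:`write_table`.

    Without a sidecar, feature ids and mz/rt are parsed from the column names.
    """
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path, index_col=0)
    labels = df.pop("label").to_numpy(dtype=int)
    batch_col = df.pop("batch")
    batches = None if batch_col.isna().all() or (batch_col.astype(str) == "").all() else batch_col.to_numpy()
    if sidecar_path is None and csv_path.with_suffix(".json").exists():
        sidecar_path = csv_path.with_suffix(".json")
    if sidecar_path is not None:
        meta = json.loads(Path(sidecar_path).read_text())
        features = pd.DataFrame(meta["features"]).set_index("feature_id")[["mz", "rt"]]
        provenance = tuple(meta.get("provenance", ()))
    else:
        mzs, rts = [], []
        for col in df.columns:
            parts = col.split("_")
            mzs.append(float(parts[1]))
            rts.append(float(parts[3]))
        features = pd.DataFrame({"mz": mzs, "rt": rts}, index=pd.Index(df.columns, name="feature_id"))
        provenance = ()
    return FeatureTable(
        values=df.to_numpy(dtype=float),
        sample_ids=df.index.to_numpy(),
        labels=labels,
        features=features,
        batches=batches,
        provenance=provenance,
    )
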
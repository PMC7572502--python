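"""Isotope/adduct explanation of non-significant features.

Significant features are assumed to be the protonated ([M+H]+) or
deprotonated ([M-H]-) monoisotopic ion; any other feature eluting within a
retention-time gate whose mass is heavier by an amount inside one of a small
set of characteristic windows is flagged as a putative isotope or adduct of
that parent. Windows are mode-specific: both ionization modes carry the one-
and two-heavy-carbon isotopologue windows; positive mode adds sodium and
potassium adducts, negative mode adds chloride and water loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tables import FeatureTable, ValidationError

__all__ = [
    "MassWindow",
    "ExplanationMap",
    "window_registry",
    "explain_features",
    "fraction_explained",
    "planted_link_recall",
]


@dataclass(frozen=True)
class MassWindow:
    """A closed interval [low, high] of positive mass offsets in Daltons."""

    label: str
    low: float
    high: float
    mode: str  # "positive", "negative" or "both"

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValidationError(f"window {self.label}: low must be < high")

    def contains(self, delta: float) -> bool:
        # epsilon far below printed window precision absorbs float subtraction error
        return self.low - _MZ_EPS <= delta <= self.high + _MZ_EPS


_MZ_EPS = 1e-9


# Mass-difference windows relative to the [M+H]+ / [M-H]- ion.
_ISOTOPE_WINDOWS = (
    MassWindow("1x13C", 0.994, 1.012, "both"),
    MassWindow("2x13C", 1.998, 2.016, "both"),
)
_POSITIVE_WINDOWS = (
    MassWindow("Na+", 21.975, 21.985, "positive"),
    MassWindow("K+", 37.954, 37.962, "positive"),
)
_NEGATIVE_WINDOWS = (
    MassWindow("H2O_loss", 18.006, 18.016, "negative"),
    MassWindow("Cl-", 35.969, 35.985, "negative"),
)


def window_registry(mode: str) -> list[MassWindow]:
    """Return the mass-difference windows for an ionization mode.

    Each mode exposes exactly four pairwise-disjoint windows: the two 13C
    isotopologue windows plus two mode-specific adduct/loss windows.
    """
    if mode == "positive":
        windows = list(_ISOTOPE_WINDOWS + _POSITIVE_WINDOWS)
    elif mode == "negative":
        windows = list(_ISOTOPE_WINDOWS + _NEGATIVE_WINDOWS)
    else:
        raise ValidationError(f"unknown ionization mode: {mode!r}")
    ordered = sorted(windows, key=lambda w: w.low)
    for a, b in zip(ordered, ordered[1:]):
        assert a.high < b.low, f"windows {a.label} and {b.label} overlap"
    return windows


@dataclass(frozen=True)
class ExplanationMap:
    """Directed parent -> child links explaining non-significant features.

    ``links`` are (parent_id, child_id, window_label) triples where the parent
    is significant and the child non-significant at map-build time. A child
    may be linked by several parents; ``explained_ids`` deduplicates children.
    """

    links: tuple[tuple[str, str, str], ...]
    explained_ids: frozenset[str] = field(default=frozenset())
    fraction_explained: float = 0.0

    def __post_init__(self) -> None:
        children = frozenset(link[1] for link in self.links)
        object.__setattr__(self, "explained_ids", children)
        if not 0.0 <= self.fraction_explained <= 1.0:
            raise ValidationError("fraction_explained must lie in [0, 1]")


def explain_features(
    table: FeatureTable,
    significant_ids: "np.ndarray | set | list",
    mode: str,
    rt_gate_s: float = 15.0,
) -> ExplanationMap:
    """Link non-significant features to significant parents by mass window.

    A child is linked to a significant parent iff their retention times are
    strictly less than ``rt_gate_s`` apart, the mass difference
    ``mz_child - mz_parent`` is non-zero, and it falls inside one of the
    mode's windows (inclusive bounds). Only positive offsets can match: a
    feature lighter than the parent is never its isotope/adduct here.
    """
    feats = table.features
    if "mz" not in feats.columns or "rt" not in feats.columns:
        raise ValidationError("feature metadata must carry mz and rt")
    if feats[["mz", "rt"]].isna().any().any():
        raise ValidationError("feature metadata must carry mz and rt for every feature")
    windows = window_registry(mode)
    sig = set(map(str, significant_ids))
    ids = feats.index.to_numpy().astype(str)
    mz = feats["mz"].to_numpy(dtype=float)
    rt = feats["rt"].to_numpy(dtype=float)
    sig_mask = np.isin(ids, list(sig))
    nonsig_idx = np.flatnonzero(~sig_mask)

    links: list[tuple[str, str, str]] = []
    for p in np.flatnonzero(sig_mask):
        if nonsig_idx.size == 0:
            break
        close = nonsig_idx[np.abs(rt[nonsig_idx] - rt[p]) < rt_gate_s]
        delta = mz[close] - mz[p]
        for w in windows:
            hits = close[(delta >= w.low - _MZ_EPS) & (delta <= w.high + _MZ_EPS) & (delta != 0.0)]
            for c in hits:
                links.append((ids[p], ids[c], w.label))
    links.sort()
    n_nonsig = int(nonsig_idx.size)
    explained = {c for _, c, _ in links}
    frac = len(explained) / n_nonsig if n_nonsig else 0.0
    return ExplanationMap(links=tuple(links), fraction_explained=frac)


def fraction_explained(emap: ExplanationMap, n_nonsignificant: int) -> float:
    """Fraction of non-significant features explained as isotopes/adducts."""
    k = len(emap.explained_ids)
    if n_nonsignificant < k:
        raise ValidationError("n_nonsignificant cannot be below the number explained")
    return k / n_nonsignificant if n_nonsignificant else 0.0


def planted_link_recall(
    emap: ExplanationMap,
    planted_links: "list[tuple[str, str, str]]",
    significant_ids: "set | np.ndarray | list",
) -> float:
    """Recall of planted parent->satellite links over the map's domain.

    The map only ever relates significant parents to non-significant
    children, so recall is computed over planted links whose parent fell in
    the significant set and whose child did not (1.0 if no link is eligible).
    """
    sig = set(map(str, significant_ids))
    eligible = [
        (str(p), str(c)) for p, c, _ in planted_links if str(p) in sig and str(c) not in sig
    ]
    if not eligible:
        return 1.0
    found = {(p, c) for p, c, _ in emap.links}
    return sum(1 for pc in eligible if pc in found) / len(eligible)
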
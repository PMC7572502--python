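"""Synthetic case/control LC/GC-MS feature tables with planted structure.

The generator works on the binary-log scale: each feature's log2 intensity
is Gaussian around a feature-specific baseline, so that the pipeline's
floor-and-log transform recovers additive effects. Planted structure:

* **markers** — a minority of features whose case mean is shifted by
  ``marker_effect`` log2 units;
* **satellites** — isotope/adduct companions of markers: each satellite's
  log intensity is its parent's log intensity plus a feature-specific
  constant plus independent noise, its mz sits inside a named
  mass-difference window above the parent, and its rt is within a small
  jitter of the parent's;
* **diffuse signal** — a fraction of background features carrying a weak
  shift of random sign, emulating signal spread over many features;
* **batch effects** — multiplicative (additive in log space) per-batch,
  per-feature offsets;
* **missingness** — intensities are reported as 0 when masked or when the
  linear-scale value falls below 1, exercising the floor-and-log rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .adducts import window_registry
from .tables import FeatureTable, ValidationError

__all__ = ["GeneratorConfig", "GroundTruth", "generate_table", "theoretical_auc"]

_MZ_RANGE = (85.0, 950.0)
_RT_RANGE = (30.0, 1100.0)
_BASELINE_LOG2_RANGE = (8.0, 22.0)
_MARKER_MZ_SPACING = 45.0  # > any window offset; prevents cross-marker window collisions


def theoretical_auc(delta: float, sigma: float) -> float:
    """Bayes-optimal single-feature ROC-AUC for a Gaussian location shift.

    For equal-variance Gaussians whose means differ by ``delta`` (log2 units)
    with within-class SD ``sigma``, the optimal rule's AUC is
    ``Phi(delta / (sigma * sqrt(2)))``.
    """
    if sigma <= 0:
        raise ValidationError("sigma must be > 0")
    return float(norm.cdf(delta / (sigma * np.sqrt(2.0))))


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic feature-table generator.

    All effects and SDs are on the log2-intensity scale.
    """

    n_controls: int = 50
    n_cases: int = 50
    n_features: int = 500
    n_markers: int = 5
    marker_effect: float = 1.0
    n_satellites_per_marker: int = 0
    satellite_window_labels: tuple[str, ...] | None = None
    satellite_noise_sd: float | None = None  # default 0.1 * noise_sd
    diffuse_signal_fraction: float = 0.0
    diffuse_effect: float = 0.0
    n_batches: int = 1
    batch_effect_sd: float = 0.0
    noise_sd: float = 1.0
    missing_rate: float = 0.0
    ionization_mode: str = "positive"
    rt_jitter_max_s: float = 10.0
    clear_background_mz: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_controls", "n_cases", "n_features", "n_markers",
                     "n_satellites_per_marker", "n_batches"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.n_controls + self.n_cases == 0:
            raise ValidationError("n_controls + n_cases must be positive")
        n_planted = self.n_markers * (1 + self.n_satellites_per_marker)
        if n_planted > self.n_features:
            raise ValidationError("n_features too small for n_markers and their satellites")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValidationError("missing_rate must lie in [0, 1]")
        if not 0.0 <= self.diffuse_signal_fraction <= 1.0:
            raise ValidationError("diffuse_signal_fraction must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        if self.satellite_noise_sd is not None and self.satellite_noise_sd < 0:
            raise ValidationError("satellite_noise_sd must be >= 0")
        if self.rt_jitter_max_s < 0:
            raise ValidationError("rt_jitter_max_s must be >= 0")
        valid = {w.label for w in window_registry(self.ionization_mode)}
        if self.satellite_window_labels is not None:
            bad = set(self.satellite_window_labels) - valid
            if bad:
                raise ValidationError(
                    f"satellite_window_labels invalid for {self.ionization_mode} mode: {sorted(bad)}")


@dataclass(frozen=True)
class GroundTruth:
    """The generator's planted structure, for downstream verification."""

    marker_ids: frozenset[str]
    satellite_links: tuple[tuple[str, str, str], ...]  # (parent_id, satellite_id, window_label)
    diffuse_ids: frozenset[str]
    theoretical_auc: float

    def __post_init__(self) -> None:
        sats = {c for _, c, _ in self.satellite_links}
        parents = {p for p, _, _ in self.satellite_links}
        if not parents <= set(self.marker_ids):
            raise ValidationError("satellite parents must be markers")
        if sats & set(self.marker_ids):
            raise ValidationError("satellites must be disjoint from markers")
        if not 0.5 <= self.theoretical_auc <= 1.0 + 1e-12:
            raise ValidationError("theoretical_auc must lie in [0.5, 1]")

    def to_dict(self) -> dict:
        return {
            "marker_ids": sorted(self.marker_ids),
            "satellite_links": [list(l) for l in self.satellite_links],
            "diffuse_ids": sorted(self.diffuse_ids),
            "theoretical_auc": self.theoretical_auc,
        }


def _sample_marker_mz(rng: np.random.Generator, n: int) -> np.ndarray:
    """Marker mz values separated by more than any window offset.

    Stratified placement: one marker per equal-width stratum of the usable
    mz range, jittered within the slack left after reserving the spacing, so
    adjacent markers are always >= the spacing apart.
    """
    if n == 0:
        return np.array([])
    lo, hi = _MZ_RANGE
    span = (hi - 40.0) - lo  # leave headroom for satellite offsets above the top marker
    width = span / n
    if width < _MARKER_MZ_SPACING:
        raise ValidationError("n_markers too large to place with the required mz spacing")
    starts = lo + width * np.arange(n)
    return starts + rng.uniform(0.0, width - _MARKER_MZ_SPACING + 1e-9, size=n)


def _clear_of_windows(mz: float, parent_mz: np.ndarray, windows) -> bool:
    if parent_mz.size == 0:
        return True
    delta = mz - parent_mz
    for w in windows:
        if np.any((delta >= w.low) & (delta <= w.high)):
            return False
    return True


def generate_table(config: GeneratorConfig) -> tuple[FeatureTable, GroundTruth]:
    """Generate a feature table and its planted ground truth.

    Deterministic: the same config (including seed) yields byte-identical
    output. One RNG stream per table; no global RNG state is touched.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_controls + config.n_cases
    p = config.n_features
    n_mark = config.n_markers
    n_sat = config.n_markers * config.n_satellites_per_marker
    n_bg = p - n_mark - n_sat

    labels = np.concatenate([np.zeros(config.n_controls, int), np.ones(config.n_cases, int)])
    sample_ids = np.array([f"S{i:04d}" for i in range(n)], dtype=object)
    feature_ids = np.array([f"F{j:04d}" for j in range(p)], dtype=object)
    windows = window_registry(config.ionization_mode)
    by_label = {w.label: w for w in windows}
    sat_labels = (tuple(config.satellite_window_labels)
                  if config.satellite_window_labels is not None
                  else tuple(w.label for w in windows))
    sat_noise = (config.satellite_noise_sd
                 if config.satellite_noise_sd is not None
                 else 0.1 * config.noise_sd)

    # --- feature metadata ------------------------------------------------
    mz = np.empty(p)
    rt = np.empty(p)
    marker_idx = np.arange(n_mark)
    sat_idx = np.arange(n_mark, n_mark + n_sat)
    bg_idx = np.arange(n_mark + n_sat, p)

    mz[marker_idx] = _sample_marker_mz(rng, n_mark)
    rt[marker_idx] = rng.uniform(*_RT_RANGE, size=n_mark)

    links: list[tuple[str, str, str]] = []
    sat_parent = np.empty(n_sat, dtype=int)
    for k, j in enumerate(sat_idx):
        parent = marker_idx[k // max(config.n_satellites_per_marker, 1)]
        w = by_label[sat_labels[k % len(sat_labels)]]
        sat_parent[k] = parent
        mz[j] = mz[parent] + rng.uniform(w.low, w.high)
        jit = config.rt_jitter_max_s
        rt[j] = max(0.0, rt[parent] + (rng.uniform(-jit, jit) if jit > 0 else 0.0))
        links.append((str(feature_ids[parent]), str(feature_ids[j]), w.label))

    planted_mz = mz[np.concatenate([marker_idx, sat_idx])] if (n_mark + n_sat) else np.array([])
    for j in bg_idx:
        if config.clear_background_mz:
            for _attempt in range(10_000):
                cand = rng.uniform(*_MZ_RANGE)
                if _clear_of_windows(cand, planted_mz, windows):
                    mz[j] = cand
                    break
            else:  # pragma: no cover - astronomically unlikely
                raise ValidationError("could not place background mz clear of all windows")
        else:
            mz[j] = rng.uniform(*_MZ_RANGE)
        rt[j] = rng.uniform(*_RT_RANGE)

    # --- log2-scale intensities ------------------------------------------
    baseline = rng.uniform(*_BASELINE_LOG2_RANGE, size=p)
    log2x = baseline[None, :] + rng.normal(0.0, config.noise_sd, size=(n, p))

    case = labels == 1
    log2x[np.ix_(case, marker_idx)] += config.marker_effect

    # satellites track their parent's (possibly shifted) log intensity
    if n_sat:
        sat_offset = rng.normal(-1.5, 0.5, size=n_sat)  # satellites dimmer than parents
        eps = rng.normal(0.0, sat_noise, size=(n, n_sat)) if sat_noise > 0 else 0.0
        log2x[:, sat_idx] = log2x[:, sat_parent] + sat_offset[None, :] + eps

    diffuse_ids: list[str] = []
    if config.diffuse_signal_fraction > 0 and bg_idx.size:
        n_diff = int(round(config.diffuse_signal_fraction * bg_idx.size))
        chosen = rng.choice(bg_idx, size=n_diff, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_diff)
        log2x[np.ix_(case, chosen)] += signs[None, :] * config.diffuse_effect
        diffuse_ids = [str(feature_ids[j]) for j in sorted(chosen)]

    batches = None
    if config.n_batches > 1:
        # round-robin within each class so every batch holds controls and cases
        batch_of = np.empty(n, dtype=int)
        for cls in (0, 1):
            rows = np.flatnonzero(labels == cls)
            batch_of[rows] = np.arange(rows.size) % config.n_batches
        offsets = rng.normal(0.0, config.batch_effect_sd, size=(config.n_batches, p))
        log2x += offsets[batch_of]
        batches = np.array([f"B{b}" for b in batch_of], dtype=object)

    intens = np.exp2(log2x)
    intens[intens < 1.0] = 0.0
    if config.missing_rate > 0:
        intens[rng.random(size=(n, p)) < config.missing_rate] = 0.0

    features = pd.DataFrame({"mz": mz, "rt": rt}, index=pd.Index(feature_ids, name="feature_id"))
    table = FeatureTable(values=intens, sample_ids=sample_ids, labels=labels,
                         features=features, batches=batches, provenance=("synth",))
    truth = GroundTruth(
        marker_ids=frozenset(str(feature_ids[j]) for j in marker_idx),
        satellite_links=tuple(links),
        diffuse_ids=frozenset(diffuse_ids),
        theoretical_auc=theoretical_auc(abs(config.marker_effect), config.noise_sd) if n_mark else 0.5,
    )
    return table, truth
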
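#!/usr/bin/env python
"""Compare feature-selection regimes under nested cross-validation.

On the reference cohort: all features vs within-fold significant-only vs
top-k (k = 5, 10, 50, 100) most significant features, each evaluated with
the 5-fold outer / 3-fold inner stratified nested CV and L1 logistic
regression. Five full-data shuffles keep this driver quick; the protocol
default is 30.
"""

from pathlib import Path

from metabostate.model import CVProtocol
from metabostate.pipeline import ExperimentConfig, top_k_sweep

import importlib.util

ROOT = Path(__file__).resolve().parents[1]
spec = importlib.util.spec_from_file_location("cohort", ROOT / "analysis" / "01_generate_cohort.py")
cohort_mod = importlib.util.module_from_spec(spec)
spec.loader.exec_module(cohort_mod)

OUT = ROOT / "results" / "regimes"


def main() -> None:
    config = ExperimentConfig(
        input=cohort_mod.COHORT,
        regimes=("all",),  # top_k_sweep adds significant_only and the k grid
        protocol=CVProtocol(n_shuffles=5, seed=0),
        dataset_id="reference_cohort",
    )
    report = top_k_sweep(config, ks=(5, 10, 50, 100))
    report.save(OUT)
    cols = ["regime", "mean_auc", "sd_auc", "ci95", "n_features_used",
            "fraction_significant_used", "meets_k"]
    print(report.rows[cols].to_string(index=False))
    print("\ndelta AUC (all - regime):")
    for name, d in report.deltas.items():
        print(f"  {name}: {d:+.4f}")
    print(f"\nreport written to {OUT}")


if __name__ == "__main__":
    main()
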
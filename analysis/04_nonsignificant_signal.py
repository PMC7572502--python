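#!/usr/bin/env python
"""Where does non-significant-feature performance come from?

Runs the two satellite-accounting study conditions: one where all predictive
signal is confined to significant markers and their isotope/adduct
satellites (removing explained satellites should collapse performance), and
one where weak diffuse signal is spread across many background features
(satellite removal should barely matter). Writes both evaluations and the
AUC drops.
"""

import json
from pathlib import Path

from metabostate import scenarios

OUT = Path(__file__).resolve().parents[1] / "results" / "nonsignificant"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = {}
    for diffuse, tag in [(False, "confined"), (True, "diffuse")]:
        res = scenarios.satellite_accounting(diffuse=diffuse, n_shuffles=10, seed=0)
        rows[tag] = res
        print(f"{tag} signal:")
        print(f"  planted-link recall: {res['recall']:.3f}; "
              f"fraction of non-significant features explained: {res['fraction_explained']:.3f}")
        print(f"  AUC non-significant-only: {res['auc_nonsignificant']:.3f}")
        print(f"  AUC after satellite removal: {res['auc_no_satellites']:.3f} "
              f"(drop {res['auc_drop']:+.3f})")
    (OUT / "satellite_accounting.json").write_text(json.dumps(rows, indent=1))
    print(f"\nwritten to {OUT / 'satellite_accounting.json'}")


if __name__ == "__main__":
    main()
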
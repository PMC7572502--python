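# metabostate

Health-state prediction from untargeted metabolomics feature tables, with a
focus on the statistics that make such predictions honest: batch-aware
percentile normalization, leakage-avoiding significance-based feature
selection, isotope/adduct accounting of "non-significant" predictive
features, and nested cross-validated evaluation of sparse logistic
regression. Intended for computational metabolomics researchers who want to
study how feature-selection choices and selection leakage shape reported
classifier performance, with every claim checkable against planted ground
truth from the built-in synthetic-data generator.

## The method

An untargeted LC/GC-MS **feature** is a triple (mz, rt, intensity); a study
is a samples × features intensity matrix *X* with binary labels *y*
(0 control, 1 case) and optional batch labels.

1. **Preprocessing.** Intensities below 1 (including missing values) are
   floored to 1, then log2-transformed. Each feature is then *percentile
   normalized* per batch: a sample's value becomes the mean-rank percentile
   of its log-intensity within that batch's **control** distribution,

   `p = 100 · (#{c < x} + ½·#{c = x}) / n_controls ∈ [0, 100]`,

   which is invariant to any strictly increasing transform of the raw
   intensities and removes multiplicative batch effects.
2. **Per-feature statistics.** Two-sided Mann–Whitney U per feature with
   Benjamini–Hochberg FDR correction; Q < 0.05 defines *significant*. The
   enrichment factor is mean(case)/mean(control) of the normalized values.
3. **Feature regimes.** Models are trained on: all features; only the
   features significant *within each training fold* (recomputed per fold so
   the held-out fold never informs selection); the top-k of those by
   smallest Q; only features non-significant on the complete data set; and
   the latter with putative isotopes/adducts of significant features
   additionally removed.
4. **Isotope/adduct explanation.** A non-significant feature is explained by
   a significant parent (assumed [M+H]+ or [M−H]−) if their retention times
   are < 15 s apart and the mass difference (child − parent) is non-zero and
   inside one of the mode's windows: 1×¹³C [0.994, 1.012], 2×¹³C
   [1.998, 2.016] (both modes); Na+ [21.975, 21.985], K+ [37.954, 37.962]
   (positive); Cl− [35.969, 35.985], −H₂O−H [18.006, 18.016] (negative).
5. **Evaluation.** Stratified 5-fold outer / 3-fold inner nested CV; the
   inner loop selects the inverse regularization strength C ∈ {2, 5, 20,
   50, 100} of an L1-penalized logistic regression (liblinear, tol 1e-4,
   max 500 iterations) by ROC-AUC; the protocol repeats on 30 independent
   full-data shuffles. Reported: mean AUC, SD across shuffles, 95% CI
   half-width 1.96·SD/√(mean test-fold size), balanced accuracy, MCC,
   sensitivity, specificity, precision, and fold/shuffle-averaged
   coefficients. An empty feature set records AUC exactly 0.5; test AUCs
   below 0.5 are retained as-is.

The synthetic generator plants known structure — markers with a log2-scale
case shift, correlated isotope/adduct satellites at window mass offsets,
weak diffuse signal, batch offsets, missingness — and returns the ground
truth, including the closed-form Bayes AUC Φ(Δ/(σ√2)) of a single marker.

## Worked example

The numbered drivers under `analysis/` run the reference experiments and
write their tables under `results/`:

```bash
python analysis/01_generate_cohort.py
python analysis/02_significance_and_adducts.py
python analysis/03_regime_comparison.py
python analysis/04_nonsignificant_signal.py
```

`01` builds a 60/60 case-control cohort (500 features, 8 markers with two
satellites each, 10% weak diffuse background, two batches, 5% missingness)
and prints its planted truth, e.g. `theoretical single-marker AUC: 0.8556`.
`02` finds all 8 markers significant (22 significant features total) and
explains 15 non-significant features as isotopes/adducts with planted-link
recall 1.000. `03` compares regimes under nested CV (5 shuffles):

```
               regime  mean_auc   sd_auc     ci95  n_features_used  fraction_significant_used
                  all  0.978333 0.007645 0.003059              486                   0.045267
     significant_only  0.929722 0.020117 0.008049               41                   0.536585
  top_k_significant_5  0.921667 0.020165 0.008068                9                   1.000000
 top_k_significant_10  0.968611 0.013271 0.005309               16                   1.000000
```

The all-features model wins (delta AUC +0.049 over significant-only)
because part of the planted signal is diffuse and individually
sub-threshold. `04` shows where "non-significant" performance comes from:
with signal confined to markers and satellites, the non-significant-only
model reaches AUC 0.562 and collapses to 0.375 once explained satellites
are removed (drop 0.187); with diffuse signal the drop is 0.028.

The same machinery is scriptable: `metabostate synth --config gen.yaml
--out table.csv`, `metabostate explain --table table.csv --mode positive
--out links.csv`, `metabostate run --config exp.yaml --out-dir out/`.

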
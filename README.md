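# radepi

3D radiomics pipeline for predicting the type (generalized vs. focal) of
tumor-related epilepsy from a T2-like MRI volume and tumor mask, exercised
end-to-end on synthetic phantom cohorts.

The package implements:

* **Synthetic cohorts** (`radepi.synthetic`) — reproducible ellipsoid-plus-
  texture phantoms with clinical records and a planted, tunable logistic
  feature–label effect, so every downstream stage is testable without
  patient data.
* **Feature extraction** (`radepi.features`) — the exact 734-feature radiomic
  vector per volume+mask+AC triple: 6 location features (polar coordinates
  and city-block/Chebyshev/Euclidean distances from the anterior commissure
  to the tumor centroid), 17 first-order statistics, 8 shape features,
  26 GLCM + 16 GLRLM + 16 GLSZM + 5 NGTDM texture features (13-direction /
  26-connectivity 3D conventions, 32 equal-width gray levels), and
  640 wavelet features (the 5 intensity families recomputed on each of the
  8 sub-bands of a one-level Coiflet-1 3D transform). The full name
  catalogue is a versioned registry (`radepi.features.registry`).
* **Signature building** (`radepi.selection`) — train-cohort z-score
  normalization, univariate screening (Pearson p < 0.05 AND oriented
  AUC > 0.6), L1-penalized logistic regression with the penalty tuned by
  leave-one-out cross-validated classification error, and the intercept-free
  linear signature.
* **Evaluation** (`radepi.evaluation`) — ROC/AUC with DeLong 95% CIs,
  Hosmer–Lemeshow calibration, decision-curve analysis, backward AIC
  selection of the multivariable clinical model, nomogram point scales, and
  Table-1-style cohort comparisons (t-test / Fisher's exact).
* **Orchestration** (`radepi.pipeline`, `radepi.cli`) — chronological 1:1
  cohort split, ICC-gated dual-rater mask reconciliation, and a resumable,
  seeded end-to-end run with per-stage artifacts.

## CLI

```bash
# generate a phantom cohort (NIfTI volumes/masks + manifest CSV)
radepi simulate --config config.json --seed 17 --out cohort/

# extract the 734-feature table from a manifest
radepi extract --manifest cohort/manifest.csv --out features.csv

# run the whole pipeline (generate -> reconcile -> extract -> split ->
# select -> evaluate), resumable per stage
radepi run --config config.json --seed 17 --out run/
radepi run --config config.json --seed 17 --out run/ --resume

# summarize a finished run (Markdown + SVG plots)
radepi report --run-dir run/
```

The config file is JSON (or YAML) mirroring `radepi.pipeline.RunConfig`;
all fields are optional, e.g.:

```json
{
  "synthetic": {"n_patients": 205, "grid_shape": [64, 64, 32], "seed": 17},
  "quantization": {"n_levels": 32},
  "seed": 17
}
```

A run directory contains `manifest.csv`, `features.csv` (n x 734),
`screening.csv`, `signature_model.json`, `evaluation.json`, calibration /
decision-curve / nomogram CSVs, a Table-1-style `cohort_comparison.csv`,
and `provenance.json`.

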
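# nirsmark

Prefrontal fNIRS hemodynamic biomarker pipeline for two-group (healthy vs.
TBI) classification studies. Implements, end to end:

1. **Synthetic cohorts** (`nirsmark.synth_cohort`) — jittered event
   schedules (5-s trials, 5–7 s ISIs), double-gamma HRF responses with
   group/channel/condition-dependent amplitudes, physiological oscillations
   (0.01–0.1 Hz), drift, noise and motion-artifact trials, pushed through a
   forward modified Beer–Lambert model to raw dual-wavelength (730/850 nm,
   16-channel, 2 Hz) intensities with known ground truth.
2. **Optical preprocessing** (`nirsmark.optics_preproc`) — baseline
   intensity normalization, optical-density conversion, age/wavelength
   differential-pathlength factors, MBLL inversion to HbO/HbR (µM),
   10th-order 0.1 Hz Butterworth low-pass, piecewise-linear detrending.
3. **Trial QC** (`nirsmark.trial_qc`) — 11-s post-onset trial extraction,
   three-criterion rejection (HbO/HbR anticorrelation, HbO mean dominance,
   positive HbO mean), ≥ 80 % channel pruning, subject pruning, block
   averaging.
4. **Features** (`nirsmark.hemo_features`) — activity-curve detection and
   the 11 features: HM, HV, HK, HS, CSL, CSR, CA, CF (FWHM), CP, CAS, and
   HDFT (DFT magnitudes at 0.01–0.1 Hz), at subject (channel-averaged) or
   per-channel level.
5. **Wrapper feature selection** (`nirsmark.wrapper_select`) — exhaustive
   search over all 2047 subsets of the 11 features, scored by repeated
   stratified 70/30 random-subsampling classification (Decision Tree; LDA
   and polynomial SVM for comparison), vertically averaged ROC/AUC, and
   per-task-load comparison.
6. **Spatial maps** (`nirsmark.spatial_maps`) — per-channel single-feature
   classification tolerating missing (QC-dropped) channels, population
   activity maps, hemisphere contrasts.

## CLI

Each stage is a console script; outputs are plain CSV/TSV/JSON.

```bash
synth-cohort --n-healthy 31 --n-tbi 30 --seed 42 --out raw/
preprocess   --in raw/ --out hemo/
trialqc      --in hemo/ --condition HighComplexity --out qc/   # --no-reject for the control analysis
features     --in hemo/ --mode temporal --out features.csv
wrapper-search --features features.csv --classifier decision_tree \
               --n-runs 1000 --seed 42 --out search/
features     --in hemo/ --mode spatiotemporal --out long.csv
spatial      --features long.csv --out spatial/
```

`wrapper-search` writes ranked subsets, per-size optima, a classifier
comparison, averaged ROC points and AUC; `spatial` writes per-feature
metrics, activity maps and hemisphere contrasts.

## Notes

- The three-criterion QC, the ≥ 80 % channel rule (inclusive boundary) and
  the all-channels subject rule are exercised at their exact boundaries in
  `tests/test_acceptance.py`.
- HDFT is computed on the full-length filtered HbO series (a 22-sample
  averaged trial cannot resolve 0.01 Hz); it counts as one feature in the
  subset enumeration and expands to its 3 magnitude columns for training.
- All randomness is seeded; cohorts are bit-identical for a fixed seed.
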
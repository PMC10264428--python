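# remhf

Discriminating REM sleep from wakefulness in mouse EEG using
high-frequency (80–500 Hz) band-power features and a kernel naive Bayes
classifier — implemented as a tested, reusable pipeline with a synthetic
polysomnography generator so every stage runs without animal data.

## What it does

- **`remhf.synthetic`** — seeded generator of 23-h-scale EEG/EMG recordings
  with ground-truth hypnograms: 4-s epochs, three vigilance states
  (≈47 % wake / ≈5 % REM), light/dark circadian modulation of state
  probabilities, state-conditioned spectra (NREM delta, REM theta,
  wake-elevated power above 80 Hz), REM muscle atonia in the EMG, and
  sporadic movement artifacts during wake.
- **`remhf.scoring`** — threshold-based reference scoring from EMG RMS plus
  delta/theta band power, with micro-state smoothing (runs shorter than
  3 epochs are absorbed).
- **`remhf.features`** — artifact excision (peak ± 50 ms, linear
  interpolation), 4-s epoching, per-epoch periodogram, average power in
  nine bands spanning 0.1–500 Hz, iterative Grubbs outlier replacement,
  per-band z-scores, hourly state percentages.
- **`remhf.classify`** — kernel naive Bayes (Gaussian KDE per
  class/feature, Silverman bandwidth, log-space posteriors) written from
  scratch, plus Gaussian-NB, QDA and k-NN comparators (SVM delegated to
  scikit-learn).
- **`remhf.evaluate`** — repeated shuffled 75/25 splits,
  accuracy/sensitivity/specificity, ROC/AUC, single-band ablation by false
  negative ratio, hourly Pearson correlations with Fisher-z confidence
  intervals, Mann–Whitney U and one-sample Wilcoxon signed-rank tests.
- **`remhf.edf` / `remhf.io` / `remhf.pipeline` / `remhf.cli`** — EDF and
  CSV/YAML/JSON formats, schema-checked pipeline configuration, and the
  command-line surface.

## CLI

```sh
remhf simulate --seed 3 --out-dir out/                    # EDF + hypnogram CSV
remhf score --edf out/recording.edf \
    --calibrate-hypno out/hypnogram.csv --out out/scored.csv
remhf features --edf out/recording.edf --hypno out/scored.csv \
    --out out/feats.csv
remhf train --features out/feats.csv --out out/model.json
remhf evaluate --features out/feats.csv --shuffles 1000 \
    --seed 7 --report out/report.json
remhf ablate --features out/feats.csv --report out/fnr.json
remhf run --config pipeline.yaml --seed 1 --out-dir out/  # end to end
```

`remhf run` accepts a YAML pipeline config (unknown keys are rejected);
the config and seed are embedded in every report so results can be
regenerated bit-identically.

## Notes

- REM is the positive class everywhere: sensitivity = TP/(TP+FN) over REM
  epochs, FNR = 100 − sensitivity.
- "Average power" defaults to band-integrated power divided by bandwidth
  (µV²/Hz); pass `band_power_mode="integrated"` for raw band integrals.
- Priors are empirical class frequencies by default; with ~5 % REM this
  matters, and `priors="uniform"` is available.
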
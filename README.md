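# appraisal-decode

Decoding of emotion-antecedent appraisal checks (novelty, intrinsic
pleasantness, goal conduciveness, control, power) from epoched EEG and
facial-EMG signals, with a synthetic-data generator standing in for real
recordings.

The package implements the full analysis chain:

| module | role |
| --- | --- |
| `appraisal_decode.synthgen` | synthetic factorial EEG/EMG epoch sets: class-dependent Gaussian-in-time components, 1/f background, white noise, participant gain, latency jitter; raw-mode 1024 Hz oscillatory EMG |
| `appraisal_decode.designs` | packaged study designs (oddball 2×3, 25 participants, ~1:3.5 imbalance; gambling 2×2×2, 24 participants, ~1:3 imbalance) and probe designs for calibration |
| `appraisal_decode.preprocess` | EMG conditioning (20–400 Hz band-pass → rectify → 40 Hz smooth → 256 Hz), baseline correction, EEG artifact rules (75 µV abs / 100 µV range / 100 ms flat / 50 µV step, plus a ±110 µV-only variant), range-based EMG outlier removal (2 × P75, >50 % participant drop) |
| `appraisal_decode.trials` | factorial-cell → check-label projection, trial averaging for T ∈ {1,2,3,4,5,10,20,all} with remainder discard, named channel sets (3/13/64 and 4/16/64) |
| `appraisal_decode.features` | static spectro-temporal vectors: log-spaced triangular filter-bank log-amplitudes + RMS per full segment and sliding window (200 ms/50 % for EEG over the first 1000 ms → 9 windows; 400 ms/50 % for EMG → 7 windows) plus 6 full-segment descriptors — 96 features per EEG channel, 94 per EMG region, up to 6144 for 64 channels |
| `appraisal_decode.decode` | participant-independent nested 3-fold cross-validation: train-statistics standardization, whole-set minority upsampling, linear SVM with C tuned on validation over {1e-5 … 1e-1}, retrain on train+val, test set + 9 bootstrap resamples per fold (30 evaluation sets) |
| `appraisal_decode.stats` | unweighted average recall, exact inverse-binomial empirical chance levels, diffUAR, one-tailed one-sample t-tests |
| `appraisal_decode.container` | HDF5 epoch container + TSV manifests and rejection reports |
| `appraisal_decode.pipeline` | end-to-end glue used by the CLI and the acceptance script |

## CLI

Generate a synthetic epoch container (packaged design or YAML config), then
decode one configuration:

```bash
appraisal-decode generate --design study1 --seed 1 --out scratch/study1.h5
appraisal-decode run --epochs scratch/study1.h5 --check novelty \
    --avg 5 --channels study1-set1 --seed 1 --out scratch/novelty_t5
```

`run` writes `predictions.tsv` (per evaluation set), `report.json` (UAR
distribution, empirical chance, diffUAR, t-test), and `run.log`.
`--channels` accepts a named set (`study1-set1`, `study2-set2`, …) or a
comma-separated label list; `--avg` accepts 1, 2, 3, 4, 5, 10, 20 or `all`.

Synthetic effect amplitudes are free parameters, so accuracies on synthetic
data characterize the pipeline, not any real recordings.

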
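# enoselab

Electronic-nose skin-odor analysis pipeline: synthetic sensor-sweep cohorts,
representative-curve preprocessing, time-domain and wavelet feature
extraction, and four cross-validated classification procedures with a
reproducible end-to-end report.

Raw inputs are conductance-vs-heater-temperature sweeps of a three-layer
metal-oxide gas sensor (long-format CSV: `subject_id, group, sweep, layer,
temperature_c, conductance`). Because no public recordings exist for this
study design, a first-class synthetic cohort generator emulates it: two
groups of subjects, 10 sweeps per subject, 3 layers, temperatures 195-355 °C,
smooth unimodal baselines with subject-level random effects, sweep-level
noise, and a group-dependent shift localized in a configurable temperature
window on one layer.

## Pipeline stages

1. **simulate** (`enoselab.cohort`) — seeded, bit-reproducible cohort
   generation from a `CohortSpec`.
2. **preprocess** (`enoselab.preprocess`) — linear interpolation onto an
   equidistant grid and per-subject/per-layer averaging into
   `RepresentativeCurve`s.
3. **extract** — feature tables:
   * time domain (`enoselab.features_time`): total areas `AS{L}`, 10 °C and
     40 °C subareas `A{w}S{L}_{k}`, and 3/5-point steepest slopes
     `Max_slope_{p}_S{L}` / `Tmax_slope_{p}_S{L}` (75 indices on the default
     160 °C span);
   * frequency domain (`enoselab.features_freq`): continuous wavelet
     transform (Daubechies, in-package implementation in `enoselab._cwt`),
     power summed over 6 scale packages × 16 temperature windows × 3 layers
     → 288 indices `W{A..P}{1..6}_S{1..3}`.
4. **classify** (`enoselab.classify`) — four procedures:
   * **A** PCA on concatenated curves + LDA/QDA,
   * **B** PCA on features + LDA,
   * **C** forward-stepwise discriminant analysis (Wilks' lambda partial F),
   * **D** RBF-SVM (`K = exp(-||x-y||²/(2σ²))`): (C, σ) grid search, then
     greedy forward index selection by cross-validated accuracy with a
     cumulative sensitivity/specificity/accuracy `SelectionTrace`.

   Selection runs on the full dataset by default (the original protocol);
   `nested_stepwise_da_eval` / `nested_greedy_svm_eval` redo selection inside
   every training fold — the unbiased variant, which stays at chance level
   under a null effect.
5. **report** (`enoselab.report`) — end-to-end run producing a method
   comparison table (percent, one decimal), per-step trace CSV, and a
   checksummed manifest for exact replay.

## CLI

```bash
enoselab simulate   --config cohort.yaml --out sweeps.csv --seed 1
enoselab preprocess --in sweeps.csv --grid 195:355:1 --out curves.csv
enoselab extract    --curves curves.csv --domain both --out features.csv
enoselab classify   --features features.csv --method D --out trace.csv --report report.json
enoselab run        --config experiment.yaml --out results/
```

`experiment.yaml` example:

```yaml
cohort:
  n_per_group: 20
  effect_layer: 2
  effect_window: [90.0, 100.0]
  effect_size: 3.0
  seed: 1
classifier:
  C: 10.0
  sigma: 20.0
  max_indices: 10
  cv: loo
domains: [time, freq]
```

Omit `C`/`sigma` to run the grid search (C 1-1000 logarithmic, σ 0.1-50
mixed log-linear; both configurable) before the greedy selection.

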
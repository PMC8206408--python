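# lgnenc

Visual encoding models of thalamic (LGN) spiking activity, end to end:
stimulus generation, synthetic population simulation, spike-train
preprocessing, neuron characterization, a dual-branch temporal-convolution
firing-rate encoder with ablations, a Poisson GLM baseline, and
cross-validated evaluation.

## What's inside

| module | purpose |
| --- | --- |
| `lgnenc.stimulus` | Binary pixel movies on a coarse (default 4×8) grid: single-pixel, balanced checkerboard, full-field, and full-resolution geometric shapes with projection to the grid. All protocols use 200 ms ON / 300 ms OFF trial blocks (2 Hz). |
| `lgnenc.simulate` | Linear–nonlinear–Poisson population simulator: Gaussian spatial receptive fields, ON/OFF polarity, transient/sustained temporal kernels, tunable stimulus locking (`snr`), optional pairwise spike coupling, and a 25 kHz raw-trace renderer for the sorting stage. |
| `lgnenc.preprocess` | Spike detection (3× robust noise SD threshold), trough alignment, PCA + K-means unit sorting, firing-rate binning (10/50 ms), PSTH/raster. |
| `lgnenc.characterize` | Responsiveness index (dB power at the 2 Hz stimulus frequency and harmonics), transient–sustained ratio (threshold 0.5), spike-triggered-average receptive fields, ON/OFF classification, responsiveness-adjusted correlation. |
| `lgnenc.cnn` | The dual-branch encoder: per branch, length-preserving 1D temporal convolution → PReLU → max pooling (×1 at w=50 ms, ×3 at w=10 ms) → flatten; concatenation; 2-layer fully connected PReLU head. Variants `V-FH`, `V`, `FH`. Pure-numpy backprop trained with Adam (lr 0.001) on RMSE, Xavier-uniform init. |
| `lgnenc.glm` | Poisson GLM baseline: log-linear intensity from lagged pixel intensities (lags 0..L) and lagged population spike counts (lags 1..L), fitted per neuron by L-BFGS on the exact likelihood with optional ridge. |
| `lgnenc.evaluate` | 5-fold cross-validation (per-trial or per-pattern splits), per-trial prediction correlations, correlation matrices, peak-rate and trial-variability regressions, Beta fits, checkerboard→shapes generalization. |
| `lgnenc.io` / `lgnenc.cli` | Text-based formats (event tables, dense stimulus matrices + JSON sidecars, YAML configs), model serialization, and the pipeline driver. |

## CLI

```sh
# full pipeline from a YAML config (stimulus + population + model + splits)
lgnenc run --config demo.yaml --out out/

# individual stages
lgnenc simulate --kind checkerboard --neurons 12 --seed 7 --out out/
lgnenc sort out/trace.txt --k 5 --units 2
lgnenc characterize --stimulus out/stimulus --spikes out/spikes.tsv
lgnenc train --stimulus out/stimulus --spikes out/spikes.tsv --variant V-FH --w 50
lgnenc evaluate --stimulus out/stimulus --spikes out/spikes.tsv --scheme per_pattern --folds 5
```

A minimal config:

```yaml
seed: 7
w_ms: 50
folds: 5
scheme: per_pattern
stimulus: {kind: checkerboard, n_patterns: 32, pixels_per_pattern: 4, trials: 20}
population: {n: 12, snr_range: [0.2, 1.0]}
model: {kind: cnn, variant: V-FH, epochs: 50}
```

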
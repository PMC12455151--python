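# uncflow

Synthetic-ground-truth re-implementation of an EEG spatial-cueing analysis
pipeline: behavioural signal detection, Morlet time–frequency power,
cluster-based permutation statistics, LCMV/DICS beamforming on synthetic
leadfields, and a neural-network (non)linear-MVAR effective-connectivity
estimator with time-shifted-surrogate significance testing. No external data
is needed — every stage runs on generators with fully known ground truth.

## Modules

| module | contents |
|---|---|
| `uncflow.synthetic` | trial tables (3 conditions × 2 validity, 256 trials/block, 25 % valid), oscillatory burst epochs on a 1/f floor, order-p (non)linear MVAR sources, spherical leadfields |
| `uncflow.behavior` | 55 % accuracy screening, strict 100–2000 ms RT filter, d′ with 1/(2N) extreme-rate correction, two-way within-subject ANOVA (partial η²), paired contrasts, paired-t power analysis |
| `uncflow.timefreq` | epoching, 5-cycle complex Morlet power (unit-energy kernels, edge invalidation), −200–0 ms baseline subtraction, band/window averaging (theta 4–7, alpha 8–12 Hz) |
| `uncflow.cbpt` | neighbour graphs, paired cluster-mass permutation test (sign-flip null, max statistic), trial-level permutation variant, Bonferroni |
| `uncflow.beamform` | band CSD (0–600 ms), DICS source power, LCMV filters (unit gain), common filters across conditions, top-5 % masks, ROI time courses |
| `uncflow.ncreann` | Hamming-sinc FIR theta filter, AIC/SBC VAR order selection, one-hidden-layer autoregressive network (incremental backprop, momentum, adaptive rate, early stopping, permuted 10-fold CV), linear/nonlinear connectivity decomposition, time-shifted surrogate nulls, group t/Wilcoxon comparisons |
| `uncflow.pipeline` | YAML-config-driven end-to-end runs with deterministic per-stage seeding |

## CLI

```bash
uncflow run -c config.yaml -o outdir          # full pipeline report bundle
uncflow cbpt --epochs-a A --epochs-b B -o res # cluster permutation test
uncflow connectivity --signals roi --order 10 --n-surrogates 100 -o conn
```

`uncflow run` with no `-c` uses defaults; an example config:

```yaml
seed: 7
eeg:
  n_subjects: 10
  effect_preset: paper_like   # or "null"
connectivity:
  n_subjects: 4
  n_surrogates: 0
```

Array containers are raw little-endian float64 `.bin` files with a JSON
sidecar (shape, axes, sampling rate, time origin, channel names/coords);
trial tables are plain CSV.

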
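# cortexdyn

Parcel-level analysis of large-scale cortical dynamics: extraction of six
neural-dynamics parameters from resting-state time series, construction of
group difference maps, and the spatial-pattern statistics that relate them.

The six per-parcel parameters are:

| parameter | meaning |
|---|---|
| `exponent` | aperiodic (1/f) decay `chi` of the PSD model `10^b / (k + f^chi)` |
| `knee_frequency` | `k^(1/chi)` in Hz (missing when the knee-free fit is used) |
| `auc` | summed aperiodic model power over 1–65 Hz |
| `hurst` | DFA scaling exponent of the alpha-band amplitude envelope |
| `alpha_power` | periodic-minus-aperiodic log10 power at the alpha peak |
| `alpha_frequency` | alpha peak frequency (Hz) |

Modules:

- `cortexdyn.synthetic` — parcel geometries (Fibonacci sphere lattice with an
  anatomical affine embedding), spatially autocorrelated Gaussian fields,
  exact fractional Gaussian noise, spectrally structured time series with a
  controllable envelope Hurst exponent, and full synthetic cohorts with
  embedded group-difference patterns and symptom couplings.
- `cortexdyn.spectral` — Welch PSD on a 0.1 Hz grid, line-noise
  interpolation, aperiodic + Gaussian-peak spectral model fit (with
  automatic knee-free fallback), reference-constrained alpha extraction.
- `cortexdyn.dfa` — zero-phase FIR alpha envelope and detrended
  fluctuation analysis.
- `cortexdyn.maps` — hemisphere averaging, z-scoring, group-difference and
  within-subject drug-effect maps.
- `cortexdyn.spatial` — Spearman map correlations with spin-rotation
  (spatial autocorrelation preserving) permutation nulls, anatomical-axis
  polynomial fits with nested F-tests, Moran's I, percentile bootstrap.
- `cortexdyn.cca` — canonical correlation analysis between two
  parcels x parameters map sets via the QR + SVD construction, explained
  covariance fractions, loadings, spin-based significance, reproducibility
  across splits.
- `cortexdyn.similarity` — per-subject signature vectors, similarity to
  reference effect maps, symptom coupling, and a drug-by-symptom-dimension
  double-dissociation permutation test.
- `cortexdyn.classify` — balanced-subsample RBF-SVM group classification
  with PCA to 95% variance, leave-one-out CV, label-permutation
  significance, F1 and pair-counting ROC-AUC with percentile CIs.

## CLI

A single `cortexdyn` entry point with stage subcommands:

```sh
cortexdyn synth cohort --n-parcels 180 --seed 1 --out cohort/
cortexdyn features spectral --in ts_dir/ --out spectral.tsv
cortexdyn features dfa --in ts_dir/ --out hurst.tsv
cortexdyn maps signature --clinical clin.tsv --control ctrl.tsv --out sig.tsv
cortexdyn stats spin --map-a sig.tsv --map-b ref.tsv --geometry geometry.tsv --n 10000 --seed 1
cortexdyn cca fit --x sig.tsv --y drug.tsv --geometry geometry.tsv --spin 1000 --seed 1
cortexdyn classify run --features features.tsv --label-col group --seed 1
```

All file formats are plain tab-separated text (see `cortexdyn.io`); time
series are one-column text files with a `# fs=<rate>` header.

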
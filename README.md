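# voltet

Voltammetric electronic-tongue calibration for simultaneous quantification of
three benzodiazepines (diazepam, flunitrazepam, lorazepam) in ternary
mixtures.

Benzodiazepines share a reducible 4,5-azomethine core, so their cyclic
voltammograms overlap heavily and no single electrode can resolve a mixture.
An electronic tongue sidesteps this: an array of six partially selective
electrodes (bare graphite-epoxy, Cu/Pt/CuO/WO3 nanoparticle-modified
composites, and a Pt disk) records six complementary voltammograms per
sample, and a multivariate model inverts the pooled fingerprint into the
three concentrations.

`voltet` implements that pipeline end to end, with a synthetic
voltammogram simulator standing in for the instrument so every stage is
reproducible and testable:

1. **Design** — 3-level/3-factor full factorial over 0–30 ppm (27 standards),
   rotated 45° about each axis and refit to the domain cube, plus 9 uniform
   random external test mixtures (75%/25% split).
2. **Measurement** — six-sensor cyclic voltammetry, −1.5 → +1.5 → −1.5 V,
   752 points per cycle, 6 × 752 = 4512 currents per sample (simulated:
   Gaussian reduction peaks with Michaelis-type saturating amplitudes
   S·c/(1 + c/K + Σ G·c), capacitive baseline, seeded Gaussian noise).
3. **Compression** — per-sensor discrete wavelet transform (Daubechies-3,
   periodized, depth 5) keeping the 24 approximation coefficients per sensor:
   4512 → 144 values (96.8% compression).
4. **Modelling** — a from-scratch 144-5-3 feed-forward network (satlins
   hidden layer, tansig output) trained by full-batch quasi-Newton MSE
   minimization; an exhaustive search over hidden sizes 2–9 × five transfer
   functions (hardlims, satlins, purelin, logsig, tansig) in both layers
   (200 configurations) selects the minimum cross-validated NRMSE.
5. **Evaluation** — obtained-vs-expected regression lines (slope, intercept,
   r, R²) per analyte and combined NRMSE
   `sqrt(Σ(obtained − expected)² / Σ expected²)` for train and test subsets,
   plus a PCA score-plot diagnostic of sensor complementarity.

## Worked example

`examples/` contains one short script per capability. The full study
(`python examples/05_train_and_evaluate.py`) prints:

```
subset       analyte     r  r_squared  slope  intercept_ppm  nrmse
 train      diazepam 0.998      0.997  0.981          0.284  0.025
 train flunitrazepam 1.000      0.999  0.991          0.131  0.012
 train     lorazepam 0.999      0.998  0.984          0.243  0.018
  test      diazepam 0.996      0.992  0.954         -0.163  0.071
  test flunitrazepam 0.982      0.965  0.969         -0.127  0.090
  test     lorazepam 0.966      0.933  0.954          0.508  0.107
 train      combined                                         0.019
  test      combined                                         0.090

combined NRMSE: train 0.019, test 0.090
```

Each row is one analyte's obtained-vs-expected regression: an ideal
calibration has slope 1, intercept 0 ppm and r = 1. The combined rows pool
all three analytes' residuals into a single relative error — about 2% on the
27 training standards and 9% on the 9 unseen test mixtures here, the usual
train < test ordering of a healthy model.

The same run is available as a shell one-liner:

```sh
voltet run-all --seed 1 --out runs/demo
```

which writes the design table, raw voltammograms, feature matrix, search
report, model JSON and results CSV, all bit-reproducible for a fixed seed.

## Library layout

| module | contents |
| --- | --- |
| `voltet.simulate` | potential grid, sensor bank, voltammogram/sample simulation |
| `voltet.design` | factorial design, 45° tilt, random test set |
| `voltet.dwt` | db3 periodized compression, feature vectors |
| `voltet.ann` | transfer functions, MLP, training, architecture search |
| `voltet.pca` | PCA and the sensor-complementarity report |
| `voltet.evaluate` | NRMSE, regression lines, model evaluation |
| `voltet.pipeline` | end-to-end orchestration, CSV ingestion, run config |
| `voltet.fixtures` | deterministic canonical datasets (hash-stamped) |
| `voltet.cli` | thin `voltet` command-line front end |

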
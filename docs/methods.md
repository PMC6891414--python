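# Methods

This note records the models, conventions and numerical choices behind
`voltet`, and what the synthetic study does and does not demonstrate.

## The voltammogram simulator

The simulator is deliberately phenomenological. Each sensor *s* responds to
analyte *a* with a Gaussian peak in potential and a saturating amplitude law:

```
I_s(E) = b0_s·d(E) + b1_s·E
       + Σ_a  A_sa · g_s(E) · exp(−(E − E0_sa)² / 2w_sa²)
A_sa   = S_sa·c_a / (1 + c_a/K_sa + Σ_b G_ab·c_b)
```

where `d(E) = ±1` follows the scan direction (capacitive baseline flips sign
between the forward and return sweep), `g_s(E)` is 1 on the cathodic
(descending) half and `anodic_fraction_s` on the ascending half, `S` is the
initial sensitivity (µA/ppm), `K` a Michaelis-type saturation constant
(ppm), and `G` a symmetric zero-diagonal cross-suppression matrix (ppm⁻¹)
coupling co-present analytes. Additive Gaussian noise with standard
deviation `sigma_abs + sigma_rel · max|I_clean|` is drawn from a stream
derived by stable hashing of (master seed, sample id, sensor index), so a
run is bit-reproducible and individual traces are independently perturbed.

This captures the statistical structure that matters for calibration —
partially selective sensors, heavy peak overlap, mild nonlinearity and
analyte interaction that defeat a purely linear model — while modelling no
electrochemistry (no Butler–Volmer kinetics, diffusion, fouling or
cycle-to-cycle drift). Consequences for interpretation: passing tests show
the *pipeline* can invert fingerprints with this structure at realistic
noise; they say nothing about matrix effects, drift or inter-session
variability of real instruments.

### Grid convention

The sweep is −1.5 → +1.5 → −1.5 V sampled as two equally spaced monotone
halves of 376 points (752 per cycle, implied step ≈ 8.0 mV). 752 points per
sensor is the length consistent with a 4512-value six-sensor fingerprint,
and is the constant the rest of the pipeline (wavelet coefficient counts,
network input width) is built on.

### Default sensor bank

Six parameter sets (package constants, chosen once for physical
plausibility, not fitted to any instrument): reduction peaks between −1.30
and −0.62 V — the flunitrazepam column systematically less negative,
mimicking its additional nitro-group reduction — widths 0.12–0.16 V so peaks
overlap strongly within a trace, sensitivities 0.5–1.6 µA/ppm arranged so
the 6 × 3 sensitivity matrix has full column rank and condition number < 50,
saturation constants 40–60 ppm (30–75% amplitude loss at the domain edge),
shared interaction matrix with 0.004–0.006 ppm⁻¹ off-diagonal terms.
Default noise is `sigma_rel = 0.005` (0.5% of full scale), with 0 and 2%
variants registered as fixtures to bracket the study conditions.

## Experimental design

Training standards: 3³ full factorial on [0, 30] ppm, rotated by
Rx(45°)·Ry(45°)·Rz(45°) about the domain centroid, then one uniform scale
(capped at 1 so an already-fitting cloud is never inflated) and a minimal
per-axis shift place the bounding box inside the domain cube. The tilt is a
similarity map — pairwise distance ratios are preserved — and spreads each
analyte over 15–23 distinct levels per axis instead of 3, improving coverage. Rotation
order and refit convention are package conventions; any fixed choice
preserves the design's intent, but they are stated here because they change
the exact coordinates. Coincident tilted points raise an error rather than
being silently deduplicated (cannot occur at the defaults). The external
test set draws each coordinate uniformly on [0, 30] ppm and is used for
nothing except final validation.

## Wavelet compression

Per-sensor discrete wavelet transform, Daubechies-3, periodized boundary,
depth 5, keeping only approximation coefficients. Periodization halves the
length with ceiling at every level (752 → 376 → 188 → 94 → 47 → 24), the
only standard boundary mode that yields exactly 24 coefficients per sensor
and hence 144 per sample. The exact compression is 100·(1 − 144/4512) =
96.81%. Transforms are applied per sensor (not to the concatenated
4512-vector) so each 24-block summarizes one electrode. Orthonormality
gives Parseval energy bounds and perfect reconstruction when details are
kept; both are exercised in the test suite.

## Neural calibration model

Single hidden layer, 144-5-3 by default, hidden satlins (symmetric
saturating linear clamp) and output tansig — the configuration selected by
the exhaustive search. The five transfer functions are hardlims, satlins,
purelin, logsig and tansig; logsig completes the conventional MATLAB-style
set of five.

**Scaling.** Targets are scaled per analyte to [−1, 1] from training
min/max; test data always use training parameters. Inputs are scaled by a
*single shared* affine map to [−1, 1] fitted to the global min/max of the
training feature matrix. All 144 coefficients share one unit (µA), and with
only 27 training samples a per-channel stretch would amplify near-constant
channels (potential regions with no faradaic signal) into full-range noise
inputs; measured on the default study this inflates external-test NRMSE by
roughly a factor of three. The shared map preserves relative coefficient
magnitudes — the same centering-only/no-autoscaling reasoning applied in the
PCA stage. Zero-variance columns map to 0 and invert to their constant.

**Training.** Full-batch minimization of mean squared error on the scaled
targets with L-BFGS over an analytic backpropagation gradient
(`scipy.optimize.minimize`); subgradients at the satlins kinks are taken as
1 inside (−1, 1) and 0 outside, and hardlims has zero gradient everywhere —
hardlims-hidden configurations therefore stay at their initialization and
are simply never selected, but remain in the search grid. Defaults:
5000 iterations, ftol 1e−12, gtol 1e−10, weights initialized uniform
(−0.5, 0.5)/√fan-in from seeded streams, 5 restarts keeping the lowest
final loss. Everything is deterministic given the seed, and the final loss
never exceeds the initial loss of the winning restart.

**Architecture search.** Hidden sizes 2–9 × 5 hidden × 5 output transfer
functions = 200 configurations, ranked by pooled 3-fold cross-validated
NRMSE on the training standards only (the external test set never touches
selection). Ties go to the first configuration in scan order. Per-candidate
training uses a lighter budget (300 iterations, 1 restart) — ranking needs
consistency, not polish — and the winner is refit with the full budget. At
zero simulator noise the search prefers a purelin-head configuration and
the refit model recovers test concentrations with per-analyte R² > 0.999;
the fixed satlins/tansig network plateaus near R² ≈ 0.96 there because its
tanh head must chase exact ±1 scaled targets at the design corners.

## Evaluation

NRMSE is the residual 2-norm over the reference 2-norm,
`sqrt(Σ(obtained − expected)² / Σ expected²)`, pooled over all included
entries; the combined value per subset pools all three analytes into one
ratio rather than averaging per-analyte values. A range-normalized variant
(RMSE / reference range) is available via `nrmse(..., normalization="range")`.
Obtained-vs-expected lines are ordinary least squares of predicted on
reference; both r and R² are reported because conventions differ on which
is quoted. Evaluation refuses overlapping train/test id sets.

## PCA complementarity diagnostic

Five replicates of each single analyte at 25 ppm on all six sensors, one
row per (sensor, replicate) voltammogram, column-mean centering only (all
variables are µA). Components come from a full SVD with the sign convention
that each component's largest-magnitude loading is positive. The report
gives per-(sensor, compound) score centroids on PC1/PC2 and the mean
silhouette of the 18 groups; at default noise the silhouette is ≈ 0.99 and
centroids sit far from the origin — every electrode contributes
discriminating information.

## Problem sizes and reproducibility

The canonical study is 36 samples × 6 sensors × 752 points with 27/9
train/test rows; a full seeded run (simulate, compress, train, evaluate)
takes a few seconds on one CPU, and the stochastic checks use the median of
five consecutive seeds. Fixtures regenerate bit-identically from
(name, seed) and are hash-stamped; pipeline artifacts are written with 17
significant digits and parsed in round-trip mode, so write → read is exact
and two runs with the same config and seed produce byte-identical CSVs.

## Known limitations

- The simulator's peak shapes, amplitudes and noise are package constants,
  not reproductions of any instrument; absolute currents are arbitrary.
- No replicate-cycle, drift, fouling or real-matrix (urine/serum) effects;
  conclusions transfer to real data only at the level of pipeline
  correctness and statistical behavior.
- The tanh-head calibration cannot predict outside the training target box;
  test mixtures beyond the training range per axis are clipped toward it.
- Model selection quality is bounded by the light per-candidate training
  budget; pathological near-ties between configurations may resolve
  differently under a larger budget.
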
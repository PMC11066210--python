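# Methods

This note documents the models, parameter choices and numerical decisions
behind `swaylab`, and states what the synthetic validation does and does
not demonstrate.

## Problem setting

The m-CTSIB scores standing balance under four conditions (EOSS, ECSS,
EOFS, ECFS: eyes open/closed × stable/foam surface) by tracing the center
of pressure (COP) on a force platform. Two scores summarise each ~11 s
condition: path length PL (inches), the discrete Euclidean arc length of
the COP trace, and average velocity AV = PL / elapsed time (inches/second).
The package estimates AV from eight body-worn tri-axial accelerometers
sampled at 128 Hz, using one regression model across all four conditions.
AV is the estimation target (rather than PL) because the two are nearly
proportional within a condition and AV is duration-normalized.

## Synthetic cohort model

No participant-level recordings are distributed with the method, so the
package ships a generator whose outputs carry exactly the statistical
structure the analysis depends on. It is a data-generating stand-in, not a
biomechanical model.

**Sway.** Each condition's COP is a pair of independent ML/AP discretised
Ornstein–Uhlenbeck processes, x[i+1] = x[i](1 − θΔt) + σ√Δt·η with
η ~ N(0,1), started at the origin. θ (default 1 s⁻¹) keeps the trace
stationary around the stance point; σ (the *sway scale*, inches·s^-1/2)
controls the expected AV. Because the recursion is linear and starts at
zero, AV is exactly proportional to σ, so calibration reduces to
regressing the scale→AV line through the origin from one seeded 500-trace
batch at σ = 1 and setting σ_c = target_c / slope. Default per-condition
AV targets are the study-condition means 0.33 / 0.63 / 0.70 / 1.94 in/s;
a fresh calibrated batch reproduces each to well within 5 %, and the
condition difficulty ordering ECFS > EOFS > ECSS > EOSS by construction.

**Subjects.** Each subject carries one log-normal ability multiplier
(mean 1, CV 0.5 — matching the roughly half-the-mean dispersion of the
per-condition AV scores) applied to all four condition scales. A single
shared multiplier is the simplest structure that induces the strong
within-subject correlation of AV across conditions seen in practice; the
generator targets that qualitative structure, not specific printed
coefficients. Handedness is assigned deterministically as
round(fraction × n) left-handers (default 3 of 34), so dominance
relabeling is always exercised.

**Sensors.** Site acceleration per horizontal axis is
gain × Δ²COP × fs² + N(0, noise_sd²); the vertical axis is noise only.
The second finite difference is the minimal lever-arm abstraction of
"a body segment accelerates with the sway it is rigidly coupled to".
Default gains rank lumbar (1.0) ≈ ankle (0.95) > sternum (0.6) >
wrist (0.25) > arm (0.12), with distal noise SDs (10 vs 3, arbitrary
g-scaled units) chosen so the proximal-versus-distal informativeness
ordering is recoverable but not degenerate. Only relative structure
matters to the features; no absolute accelerometric calibration is
attempted. Device axes follow the wearing convention: X=ML, Y=AP, Z=VT
everywhere except the upper arm, where the mounting swaps X and Y.

**Sessions.** Each subject's per-sensor stream is a lead-in pad (2 s),
the four condition blocks in fixed test order with jittered durations
(11 ± 1.5 s uniform, rounded to whole samples), 1 s gaps, and a lead-out
pad. Cue timestamps mark block boundaries; the in-memory and on-disk
pipelines both recover segments through the same cue-segmentation code.

**What the generator does not emulate:** inverted-pendulum dynamics,
muscle control, foam-surface mechanics beyond a scale change, gyroscope
channels, sensor drift or orientation error, and realistic distal-limb
idiosyncrasy. Consequently the synthetic estimation problem is *much
easier* than the real one: proximal features are nearly noise-free images
of sway, and cross-validated r approaches 1 where real-cohort studies
report r ≈ 0.9–0.96. Passing the pipeline tests demonstrates correctness
of the machinery (segmentation arithmetic, leakage-safe fold protocol,
feature definitions, model plumbing, ranking recovery), not field
performance.

## Preprocessing

Cue intervals are half-open [start, stop), so boundary samples are never
double-counted; segmentation and trimming only select samples, never
modify them. The edge trim is round(0.5 s × fs) samples per end
(64 at 128 Hz). No resampling or filtering stage exists: all sensors are
assumed delivered at a common 128 Hz, and a mismatch raises a validation
error instead of being silently corrected. Condition segments of unequal
length are allowed; all length-sensitive features are normalized by
construction (means, densities, rates).

## Feature definitions

The 42-feature set is 13 per-axis features × {ML, AP, VT} + 3 zero-lag
cross-axis Pearson correlations. The feature *names* are standard in the
wearable literature but not self-defining; the definitions adopted here
are the most conventional reading of each name, and every threshold is a
keyword argument:

| feature | definition | notes |
| --- | --- | --- |
| sd | sample SD (n−1) | |
| skewness / kurtosis | standardized 3rd moment / Fisher excess | constant input → 0 |
| sparsity | Hoyer (√N − L1/L2)/(√N − 1) | 0 = flat, 1 = one-hot |
| Shannon entropy | 16 equal-width bins on [min, max], bits | affine-invariant |
| sample entropy | SampEn(m=2, r=0.2·sd), Chebyshev, no self-matches | both template lengths use the same N−m start positions; zero counts capped at ln(N−m) |
| spectral entropy, main/secondary freq & power | rectangular-window periodogram, DC excluded | secondary peak skips bins adjacent to the main bin to avoid leakage shoulders |
| difference sum | total variation Σ|Δx| | |
| average jerk | mean|Δx|·fs | first-difference smoothness proxy |

Degenerate inputs (constant/all-zero axes) map to guard value 0 so
downstream design matrices are always finite. The O(N²) sample-entropy
kernel is JIT-compiled via numba, with a vectorised numpy fallback; tests
verify exact agreement with an independent naive pair-counting oracle.

## Modeling and evaluation protocol

Per cross-validation fold, in order and using training rows only:

1. z-score normalization (training mean/SD; zero-SD columns pass through);
2. feature selection for MLR and SVR: keep features with
   |Pearson r(feature, AV)| > 0.7 on the training rows. The absolute value
   is used deliberately — a strongly negative predictor is informative. An
   empty selection falls back to the single best feature with a warning
   rather than aborting small folds. Boosted trees get all features (their
   feature weighting is internal). An optional greedy redundancy pruning
   stage (drop features with mutual |r| > 0.9, strongest-first) is
   available but off by default;
3. hyperparameter grid search on one shuffled 80/20 train/validation
   split: SVR over kernel ∈ {linear, RBF} × C ∈ {0.1, 1, 10} ×
   ε ∈ {0.01, 0.05, 0.1, 0.2}; boosted trees over trees 10–190 step 20 ×
   depth {3, 5, 7, 9} × feature subsample {0.1 … 0.5}. The documented
   continuous ranges are discretised to small grids spanning them. Ties
   break toward the least complex model (fewer trees, then shallower;
   smaller C, then larger ε);
4. refit the winning configuration on the full training fold and predict
   the held-out subjects.

Both protocols group by subject: leave-one-subject-out (one fold per
subject, four test rows each) and grouped 5-fold (subjects shuffled by
seed into near-equal groups). Test r is computed on predictions pooled
across folds — with four points per LOSO fold, per-fold correlation is not
meaningful — while MAE is averaged across folds with its SD. Per-condition
MAPE is reported as a fraction, with zero-truth rows excluded (they cannot
occur in calibrated simulations). Multi-placement evaluation concatenates
sensor feature blocks horizontally with placement-role-prefixed names.

The MLR solver is written from first principles as an orthogonal-
decomposition least-squares problem, returning the minimum-norm solution
with a warning when the design is rank-deficient (as happens when the
fallback path or small cohorts leave more features than rows). SVR and
boosted trees are delegated to scikit-learn and xgboost; the package owns
the normalization/selection/splitting contract around them, and all fits
are deterministic given the seed.

## Numerical choices and degenerate inputs

* Correlation guards: constant inputs yield r = 0 in feature selection and
  cross-correlation, and NaN (undefined) in the evaluation metric.
* Trim/segment arithmetic is exact in samples; timestamps are binary
  fractions at 128 Hz, so cue boundaries round-trip exactly through CSV.
* Recording CSVs are written at 17 significant digits and read with
  round-trip float parsing, making write→read lossless.
* Seeds: every stochastic component (simulation, calibration batch,
  shuffles, tree fitting) derives from explicit integer seeds; identical
  configuration implies bit-identical output.

## Problem sizes used in the shipped checks

The test-suite and acceptance-script runs use the study-sized default
cohort (34 subjects × 4 conditions × 8 sensors, ~11 s segments at 128 Hz),
500-trace calibration batches, and 20 independent cohort seeds for the
sensor-ranking sweep; these sizes are the package's standard validation
configuration and keep a full run to a few minutes on one CPU.

## Known limitations

* The synthetic task understates real-world difficulty (see above); error
  magnitudes reported on it are not comparable to clinical studies.
* Feature definitions follow conventional readings of the published
  feature names; other groups may implement sparsity or difference sum
  differently, which would change feature values but not the pipeline
  contracts.
* The grid-search validation split is a single 80/20 shuffle per fold (by
  design, matching the documented protocol), so hyperparameter choice has
  higher variance than nested k-fold tuning would give.
* Gyroscope channels, audio cue detection and clock-drift correction are
  out of scope; cue timestamps are taken as manifest input.
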
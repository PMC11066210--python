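# swaylab

Estimating standing-balance test scores from body-worn accelerometers.

The modified Clinical Test of Sensory Interaction on Balance (m-CTSIB) asks
a person to stand still under four conditions that progressively remove
sensory input — eyes open/closed (EO/EC) crossed with a stable/foam surface
(SS/FS): EOSS, ECSS, EOFS, ECFS. A force platform scores each condition by
the center-of-pressure (COP) path length PL (inches) and its average
velocity AV = PL / duration (inches/second); higher AV means less stable.
`swaylab` implements, as a tested and reusable pipeline, the regression
approach of estimating AV directly from wearable tri-axial accelerometers
worn at eight body sites (both ankles, lumbar spine, sternum, both wrists,
both upper arms), so balance can be assessed without the platform. It is
aimed at digital-health and movement-science researchers who want to study
the method, its feature set, or its validation protocol on controlled
synthetic cohorts.

## What the pipeline does

1. **Synthetic cohort generation** (`swaylab.sway_synthesis`). Because the
   analysis needs subject data, the package simulates it: COP sway per
   condition as a pair of mean-reverting Gaussian random walks
   (x[i+1] = x[i](1 − θΔt) + σ√Δt·η), calibrated per condition so the mean
   AV matches the study targets 0.33 / 0.63 / 0.70 / 1.94 in/s for
   EOSS / ECSS / EOFS / ECFS; accelerometers as gain-scaled second
   differences of COP plus sensor noise, with strong coupling at proximal
   sites (lumbar, ankle) and weak coupling distally (wrist, arm); and a
   shared log-normal ability multiplier per subject that correlates AV
   across conditions.
2. **Preprocessing** (`swaylab.preprocessing`). Vocal-cue timestamps cut
   each session stream into the four condition segments; 0.5 s is trimmed
   from each edge; device axes are relabelled to body axes ML/AP/VT (the
   upper-arm mounting swaps its horizontal axes); left/right sensors become
   dominant/non-dominant via handedness.
3. **Feature extraction** (`swaylab.features`). 42 features per recording:
   13 per axis (SD, skewness, kurtosis, Hoyer sparsity, Shannon entropy,
   sample entropy, spectral entropy, main/secondary frequency and power,
   difference sum, average jerk) × 3 axes + 3 cross-axis correlations.
4. **Modeling** (`swaylab.models`). Fold-wise z-scoring and
   correlation-threshold feature selection (|r| > 0.7 with AV, training
   rows only), then multiple linear regression (Y = β₀ + Σβᵢxᵢ + ε, solved
   from first principles), support-vector regression (linear/RBF,
   C ∈ [0.1, 10], ε ∈ [0.01, 0.2]) or gradient-boosted trees
   (10–200 trees, depth 3–9, feature subsampling 0.1–0.5), with grid search
   on a shuffled 80/20 train/validation split.
5. **Evaluation** (`swaylab.evaluation`). Subject-wise leave-one-out and
   grouped 5-fold cross-validation; MAE, pooled Pearson r, per-condition
   MAE and MAPE.

## Worked example

```python
import numpy as np
from swaylab import SimConfig, simulate_cohort
from swaylab.features import features_from_cohort
from swaylab.evaluation import evaluate_pipeline

records = simulate_cohort(SimConfig(seed=1))          # 34 subjects
table = features_from_cohort(records, placements=["lumbar"])
res = evaluate_pipeline(table, "lumbar", "gbt", cv_kind="loso", seed=1)
print(f"pooled r = {res.test_r:.3f}")
print(f"test MAE = {res.test_mae_mean:.3f} in/s")
print({c: round(m, 3) for c, m in res.per_condition_mape.items()})
```

Output:

```
pooled r = 0.993
test MAE = 0.043 in/s
{'EOSS': 0.063, 'ECSS': 0.041, 'EOFS': 0.039, 'ECFS': 0.051}
```

`pooled r` is the Pearson correlation between predicted and true AV pooled
over all 34 left-out subjects × 4 conditions; `test MAE` is the mean
absolute prediction error in inches/second (the cohort's AV values span
roughly 0.1–4 in/s); the last line is the per-condition mean absolute
percentage error as a fraction. On this synthetic cohort the proximal
sensors carry a nearly noise-free image of sway, so recovery is almost
exact — see `docs/methods.md` for what that does and does not say about
real data.

The same flow is available from the shell:

```sh
swaylab simulate --n-subjects 34 --seed 7 --out data/
swaylab extract  --data data/ --out features.csv
swaylab evaluate --features features.csv --model gbt --placement lumbar \
                 --cv loso --seed 7 --out results.json
swaylab report   --results results.json
```

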
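# stresskit

Classification of five graded stress states from peripheral biosignals
— photoplethysmography (PPG), electrodermal activity (EDA) and skin
temperature (SKT) — with a kernel extreme learning machine (K-ELM).

The toolkit is aimed at physiological-computing and affective-computing
work where a subject performs a sequence of sessions (baseline, mild,
moderate and severe mental stress, recovery) while wearable-grade
signals are recorded, and the question is whether short signal epochs
carry enough autonomic information to tell the sessions apart.

## What it computes

Each 240 s session is filtered, trimmed of its first 35 s, and cut into
6 s epochs (34 per session, 170 per subject). Every epoch becomes a
24-dimensional feature vector:

- **15 HRV features** from the pulse-to-pulse (NN) intervals of the
  band-passed PPG: HRavg, NNavg, SDNN, SDSD, RMSSD, pNN20, pNN50 (time
  domain); normalized LF and HF power and LF/HF from a Burg
  autoregressive spectrum of the cubic-spline NN tachogram (frequency
  domain); ApEn, SampEn (m = 2, r = 0.2·SDNN), Poincaré SD1, SD2,
  SD1/SD2 (nonlinear).
- **6 EDA features** after deconvolving skin conductance into tonic
  (SCL) and phasic (SCR) components against a Bateman kernel with a
  non-negative sparse driver: SCavg, SCLavg, SCLslope, SCRavg, SCRmax,
  SCRpeak.
- **3 SKT features**: SKTavg, SKTslope, SKTstd.

The classifier is the kernel ELM: ridge-regularized one-hot regression
in a reproducing kernel space, trained by a single symmetric
positive-definite solve

    f(x) = [k(x, x₁), …, k(x, x_N)] (I/C + Ω)⁻¹ T,
    k(x, x′) = exp(−γ ‖x − x′‖²),

evaluated by within-subject leave-one-out cross-validation with
per-fold feature standardization, (C, γ) selected on a decade grid.
The explicit-hidden-layer ELM (random weights, closed-form output
layer) is included and unit-tested against the kernel form. Around the
classifier sit one-way ANOVA with Tukey HSD for per-feature session
effects, and a batch self-organizing map with k-means (k = 5) neuron
clustering for unsupervised structure.

Because no public recordings accompany this protocol, the package
ships a first-class synthetic generator (`stresskit.synth`) producing
per-subject, per-session PPG/EDA/SKT with the autonomic stress
gradient built in (faster, less variable heartbeats; more sudomotor
activity; shifted temperature; asymmetric recovery). Every downstream
stage is tested against its ground truth. See `docs/methods.md` for
the model and its limits.

## Worked example

```python
import stresskit as sk
from stresskit.evaluation import loocv

cohort = sk.generate_cohort(n_subjects=3, seed=42, separability="high")
table = sk.extract_cohort_features(cohort)
print(f"{len(table)} epochs x {len(sk.FEATURE_COLUMNS)} features")

result = loocv(table, C=100.0, gamma=0.1, feature_set="IT")
print(result.confusion.to_frame().round(2).to_string())
print(f"mean accuracy: {result.mean_accuracy:.2f}%")
```

prints

```
510 epochs x 24 features
        BA-S  MIS-S  MOS-S  SES-S   RE-S
BA-S   96.08   1.96   0.98    0.0   0.98
MIS-S   0.00  96.08   1.96    0.0   1.96
MOS-S   0.00   2.94  97.06    0.0   0.00
SES-S   0.00   0.00   0.00  100.0   0.00
RE-S    0.98   4.90   0.00    0.0  94.12
mean accuracy: 96.67%
```

Rows are the true session, columns the predicted one, in percent of
each row's 102 held-out epochs (3 subjects × 34). The severe-stress
session is easiest (its autonomic signature is most extreme); the
residual confusion concentrates between baseline, mild stress and
recovery, the three least-aroused states. `feature_set` accepts
`"HRV"`, `"SC"`, `"SKT"` or `"IT"` (all 24), and
`stresskit.evaluation.grid_search` sweeps (C, γ) and returns the full
accuracy surface with its argmax.

The same pipeline is scriptable from the shell:

```
stresskit simulate --subjects 12 --seed 1 --separability high --out data/
stresskit extract  --data data/ --out features.csv
stresskit loocv    --features features.csv --set IT --c 100 --gamma 0.1
stresskit gridsearch --features features.csv --set IT --coarse
```

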
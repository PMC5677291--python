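# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `stresskit`. It is written for a reader who wants to
understand *why* the toolkit computes what it computes, not just how to
call it.

## Problem setting

A subject performs five consecutive sessions — baseline (BA-S), mild
(MIS-S), moderate (MOS-S) and severe (SES-S) mental-arithmetic stress,
then recovery (RE-S) — while three peripheral signals are recorded at
400 Hz: a photoplethysmogram (PPG), electrodermal activity (EDA, µS) and
skin temperature (SKT, °C). Each session lasts 240 s. Stress shifts the
sympathetic/parasympathetic balance of the autonomic nervous system,
which expresses itself as faster heartbeats with less beat-to-beat
variability, more frequent and larger skin-conductance responses on a
higher tonic level, and altered peripheral temperature. The toolkit
turns each 6-second epoch of the three signals into a 24-dimensional
feature vector and classifies which of the five sessions it came from.

## Signal conditioning and epoching

The PPG is band-pass filtered to 0.5–4 Hz with a 4th-order zero-phase
Butterworth filter (second-order sections, forward–backward). The band
isolates the cardiac fundamental: slow motion artifacts sit below
0.1 Hz, respiration below 0.4 Hz. Zero-phase filtering matters because
beat times are read directly off the filtered peaks.

Each session drops its first 35 s (stabilization) and is cut into
consecutive, non-overlapping 6 s epochs; a trailing remainder shorter
than one epoch is discarded. A 240 s session therefore yields 34 epochs,
a subject 170, and a 12-subject cohort 2040.

Pulse peaks are local maxima of the filtered PPG above an adaptive
threshold — the larger of (median + 0.5·IQR) and 20% of the 98th
amplitude percentile — with a 0.3 s refractory period (caps heart rate
at 200 bpm; the larger of two close candidates wins). The percentile
floor exists because filter ripple between sparse pulses can clear a
purely IQR-based threshold. Peaks are detected per epoch by default;
a `whole_session_peaks` flag switches to one detection pass per session
with epochs reading the peaks that fall inside them. Successive peak
times give the normal-to-normal (NN) intervals in ms.

## The 24-feature panel

**Heart-rate variability (15).** Time domain: HRavg (bpm), NNavg, SDNN,
SDSD, RMSSD (ms), pNN20, pNN50. The pNNx denominator is the *total
number of NN intervals* in the epoch; a `pnn_denominator="pairs"` flag
switches to the more common successive-pairs denominator. All standard
deviations use the sample (n−1) convention. Frequency domain: the NN
series is anchored at each closing beat, cubic-spline resampled at 4 Hz
(the NN tachogram), mean-centred, and fitted with an autoregressive
model by Burg's method (default order 16, capped at ⌊len/2⌋−1 on short
epochs). LF (0.04–0.15 Hz) and HF (0.15–0.40 Hz) powers are trapezoidal
integrals of the AR spectrum; the features are the normalized shares
LF/(LF+HF), HF/(LF+HF) and the LF/HF ratio (capped at 100 when HF
integrates to zero). Nonlinear: approximate entropy (self-matches
included) and sample entropy (excluded), both with m = 2,
r = 0.2·SDNN of the epoch, Chebyshev template distance; and the
Poincaré descriptors SD1, SD2, SD1/SD2.

A caveat stated once and meant seriously: a 6 s epoch holds ~5–9 NN
intervals. The 0.04 Hz edge of the LF band corresponds to a 25 s period
and is formally unresolvable at that window length, and entropies on
<10 samples are extremely coarse. These features are computed anyway —
the epoch length is part of the protocol being implemented — but they
should be read as short-window surrogates. On synthetic data they carry
almost no class information, and the tests reflect that: classification
is carried by the level and dispersion features.

**Electrodermal (6).** The skin-conductance trace is decomposed per
session (the deconvolution needs more context than 6 s) into tonic
(SCL) and phasic (SCR) components; epochs read their slice of the
session decomposition. Features: SCavg (mean of the raw trace), SCLavg,
SCLslope (max − min of the tonic curve over the window — an excursion,
not a rate; the name follows common usage in this feature set, and a
least-squares µS/s variant is available), SCRavg, SCRmax, and SCRpeak
(count of phasic maxima ≥ 0.01 µS, a conventional amplitude criterion).

**Skin temperature (3).** SKTavg, SKTslope (max − min), SKTstd.

Epochs whose features cannot be computed (too few beats, no spectral
support, no entropy matches) carry NaN markers which are imputed from
the subject-session median (falling back to subject, then column
median, then zero for a feature undefined on every row). This keeps the
classifier input rectangular without silently fabricating variation: an
everywhere-undefined feature becomes a constant column that per-fold
standardization passes through as zeros.

## Skin-conductance decomposition

The model is the standard sparse-driver convolution view of
electrodermal activity: SC(t) = SCL(t) + (driver ⊛ Bateman)(t), with
the Bateman impulse response e^(−t/τ2) − e^(−t/τ1) (unit-peak
normalized), τ1 = 0.75 s rise and τ2 = 2 s decay by default, and a
non-negative sudomotor driver.

The implementation:

1. decimate to a 4 Hz working grid by bin means (EDA content is well
   below 1 Hz; this makes the deconvolution a ~1000-variable problem);
2. estimate the tonic curve: subtract a least-squares line (so pure
   trends stay tonic), take a rolling minimum over a 5·τ2 window,
   smooth with the same window, add the line back, and re-anchor on the
   5th percentile of the residual (undoing the minimum's downward bias);
3. solve min ‖K d − phasic_target‖² + λ²‖d‖² subject to d ≥ 0 by
   non-negative least squares (K the kernel Toeplitz matrix, λ = 0.05),
   then drop driver mass below 1% of the maximum (a ridge artifact) and
   fold the corresponding signal back into the tonic component;
4. re-place the driver at the input rate: each cluster of coarse-grid
   mass is refined by comparing a rigidly sub-bin-shifted render
   against a single impulse with closed-form amplitude on a fine onset
   grid, keeping whichever leaves the smaller local squared residual.

Step 4 exists because the coarse grid quantizes SCR onsets to ±0.125 s,
which against the steep Bateman rise leaves spiky reconstruction
residuals; refinement brings zero-noise single-event reconstruction
from ~14% to <1% of signal range. On zero-noise fixtures with
well-separated events the decomposition recovers the exact event count
and reconstructs tonic + phasic within 5% max-abs of the signal range.

Known limitation: slow tonic *wander* (time constants near the rolling
-minimum window) partially leaks into the phasic component, and under
heavy wander an event's mass can be mis-attributed. The decomposition
is a functional equivalent of the deconvolution family of EDA methods,
not a re-implementation of any specific toolbox, and equivalence to any
of them is not claimed.

## Kernel extreme learning machine

An ELM is a single-hidden-layer network whose input weights W (uniform
on [−1, 1]) and biases b (uniform on [0, 1]) are random and fixed;
only the output weights are trained, in closed form, by ridge
regression against one-hot targets T:

    B̂ = Hᵀ (I/C + H Hᵀ)⁻¹ T,     H_ij = g(w_jᵀ x_i + b_j),

with sigmoid g and regularization coefficient C. When L < N the
algebraically identical L-side form (I/C + HᵀH)⁻¹HᵀT is used (smaller
solve); the equivalence is unit-tested. As C → ∞ the solution tends to
the Moore–Penrose least-squares solution H†T.

The kernel variant replaces the explicit hidden map by a Mercer kernel,
Ω_ij = k(x_i, x_j), giving

    f(x) = [k(x, x₁), …, k(x, x_N)] (I/C + Ω)⁻¹ T,

with the RBF kernel k(x, x′) = exp(−γ‖x − x′‖²) as default. Training is
one symmetric positive-definite solve (Cholesky; never an explicit
inverse — the inverse appears only in test oracles). Decisions take the
argmax of the score vector; exact ties resolve to the lowest class
index. Features are z-scored inside each training fold by default,
using training statistics only; zero-variance columns are centred, not
divided. One-hot {0,1} target coding throughout.

## Evaluation protocol

Leave-one-out cross-validation runs *within subject*: each of a
subject's 170 epochs is held out once against the remaining 169.
Cohort confusion matrices pool counts over subjects (epoch-weighted);
per-subject accuracies are also reported so a subject-weighted summary
is available. Rows of the percent view sum to 100.

Grid search evaluates the mean LOOCV accuracy over a (C, γ) grid. The
default grids are the 15-decade sets {10⁻⁸, …, 10⁶} for both axes
(225 cells); an extended C grid adding 10⁷ is provided because the
integrated feature set's optimum tends to sit at very weak
regularization. Ties at the maximum resolve to the smallest C, then
the smallest γ. Deliberately, hyperparameter selection reuses the same
LOOCV folds that report accuracy — this replicates the evaluation
protocol being modelled, and is optimistic; treat the selected cell's
accuracy as an in-protocol number, not a generalization estimate.

Feature statistics use the classic one-way ANOVA decomposition
(F = MS_between / MS_within) with Tukey's HSD post hoc: q = |m_i − m_j| /
√(MS_within/n), p-values from the studentized range distribution.
Tukey requires equal group sizes and refuses otherwise. Degenerate
inputs (zero within-group variance with unequal means) report a capped
infinite F with a flag rather than dividing by zero.

The packaged questionnaire fixture (per-subject age and per-session
state-anxiety STAI Y-1 and visual-analogue stress scores for 12
subjects) is summarized with means and sample SDs; report rounding is
half-up (banker's rounding would flip a .x5 mean down).

## Self-organizing map

A batch SOM on a 10×10 hexagonal grid (odd-r offset layout): per epoch
every input is assigned to its best-matching unit and every neuron's
weight becomes the Gaussian-neighborhood-weighted mean of all inputs.
The neighborhood radius decays linearly from half the grid dimension to
0.5 over 30 epochs. Batch updates make training deterministic given the
seeded initialization (a random sample of inputs plus small jitter).
Inputs are z-scored by default — the 24 features span bpm, ms, µS and
°C, and an unscaled Euclidean assignment would be dominated by the
large-magnitude columns. The U-matrix maps each neuron to its mean
weight distance over existing hex neighbors (six in the interior, two
to three at corners); k-means (k-means++, 10 restarts, seeded) on the
neuron weights labels the map's regions, with k = 5 matching the five
stress states.

## The synthetic cohort

No public recordings accompany the protocol, so the generator is the
test bed; it is first-class, tested code. Per session it draws:

- **RR intervals**: mean_rr + sd_rr·z_i + rsa·sin(2π·0.25 Hz·t), z an
  AR(1) process (φ = 0.3) of unit marginal variance, clipped to
  [300, 2000] ms. The sinusoid models respiratory sinus arrhythmia.
- **PPG**: a Gaussian lobe (σ = 75 ms) at each cumulative RR time, a
  0.05 Hz baseline wander, white noise. Morphology is deliberately
  minimal — peaks are what the pipeline consumes.
- **EDA**: tonic level + linear drift + slow Ornstein–Uhlenbeck wander
  (τ = 60 s), plus Bateman-shaped events from a homogeneous Poisson
  process (rate per session) with log-normal peak amplitudes.
- **SKT**: level + drift + OU wander + white noise.

All randomness derives from one master seed through per-subject,
per-session, per-channel streams (CRC-based, process-stable), so
cohorts are bit-reproducible. Subjects get small seeded offsets in mean
RR, tonic level and temperature (individual physiology).

Session parameters follow the autonomic stress gradient: from baseline
to severe stress, mean RR falls (870→530 ms at high separability),
RR variability and RSA amplitude fall (vagal withdrawal), SCR rate and
amplitude rise, tonic EDA rises, temperature rises. Recovery is
modelled as *asymmetric*: mean heart rate is back near baseline while
vagally mediated variability remains suppressed, sudomotor activity
remains elevated, and skin temperature lags with thermal inertia. This
is the standard picture of post-stress recovery running at different
speeds in different effector systems, and it is also what makes the
recovery session identifiable at all — a recovery that merely replays
baseline on every axis is indistinguishable from it.

A `separability` knob ({low, medium, high}) scales session contrasts
about their grand mean, sensor noise, and (separately, less
aggressively) the physiological wander. The `high` setting is
calibrated so that the full pipeline — generation, feature extraction,
within-subject LOOCV with the kernel ELM at grid-searched (C, γ) —
lands where the real-data protocol reports its results: integrated
features ≥ 90% (measured ≈ 96%), above each single-signal set, with
the heart-derived set strongest (≈ 90%), electrodermal next (≈ 83%) and
temperature weakest (≈ 79%), and label-permuted accuracy at chance.

What the generator does **not** emulate: realistic PPG morphology
(dicrotic notch, pulse-shape variability), motion artifacts, ectopic
beats, respiration as a separate channel, non-stationary stress
responses within a session, and any coupling between channels beyond
the shared session label. Passing tests on this cohort therefore
demonstrate that the pipeline's algorithms are implemented correctly
and recover planted structure — not that the accuracy figures transfer
to real recordings.

## Numerical choices, briefly

- Sample (n−1) SDs everywhere a convention is needed; Poincaré
  identities are tested under the matching convention.
- Butterworth filtering in second-order sections (the polynomial form
  is numerically fragile for a narrow low-frequency band at 400 Hz).
- SPD solves by Cholesky with an lstsq fallback on singularity.
- The LF/HF ratio caps at 100 instead of reporting infinity.
- Burg's recursion maintains the full coefficient vector with a leading
  one; driving variance updates as E·(1−k²) per reflection coefficient.
- Epoch boundaries are half-open: epoch i covers
  [35 + 6i, 35 + 6(i+1)) seconds.
- Report-table rounding is half-up, two decimals for confusion
  percentages, one for questionnaire means.

## Problem sizes used by the shipped checks

The test suite and the acceptance script run the full-size protocol
(12 subjects × 5 sessions × 240 s at 400 Hz, 2040 epochs) for the
pipeline checks, with the hyperparameter grid reduced to a 5×5 decade
sub-grid {10⁻⁴…10⁷} × {10⁻⁵…10³} spanning the useful region of the
full surface; unit-level checks use short, low-rate sessions where the
quantity under test does not depend on scale. Calibration simulations
(ANOVA type-I rate) use 10⁴ replicates; entropy oracles compare 200
series up to length 50.
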
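# Methods

## Problem

Dynamic oxygen uptake (VO₂, L/min) during incremental exercise is the
reference measure of cardiorespiratory load, but measuring it requires a
breath-gas analyzer.  `oxyflux` implements a wearable-sensor surrogate:
predict per-10-second VO₂ from a wrist accelerometer (10 Hz), a chest-strap
heart rate (1 Hz) and six static anthropometric/resting features, using
CNN-LSTM sequence models with optional attention, evaluated strictly
subject-wise.

## Synthetic cohort generator

No public CPET dataset accompanies the method, so the package ships a
generator whose output has the statistical structure the models assume.
It is first-class, tested code, not a fixture.

**Subjects.**  Anthropometrics are drawn from sex-specific truncated
normals (males: age 24 ± 3 y, height 1.76 ± 0.08 m, weight 70.6 ± 13.3 kg,
body fat 16.2 ± 5.8%; females: 25 ± 3, 1.63 ± 0.05, 52.3 ± 6.0,
23.7 ± 3.4).  BMI is recomputed from the sampled height and weight rather
than drawn.  Resting HR is 62 ± 8 beats/min and resting VO₂ scales with
body mass (≈3.5 mL/kg/min ± 10%), both truncated to normal adult ranges;
neither is part of the anthropometric table, so these are the package's
own choices.  VO₂max is parameterised physiologically: a relative-fitness
draw (males 48, females 40 mL/kg/min, residual SD 3) shifted down by
excess body fat (−0.4 per % above the sex mean) and by elevated resting
heart rate (−0.5 per beat/min above 62 — athlete bradycardia), multiplied
by body mass, truncated so the absolute value stays in 2.0–4.5 L/min.
The truncation is applied to the *draw*, not as a clamp, to avoid piling
probability mass at the bounds.  These couplings matter: they are what
make an unseen subject's VO₂ scale inferable from the static features, the
premise on which wearable VO₂ prediction rests.  Cohorts use a 2:1
male:female ratio (subject *i* is male iff *i* mod 3 < 2).

**Sessions.**  The ramp protocol starts at 4 km/h (walking) and adds
1 km/h per minute at 0% incline, capped at 15 min.  The latent drive is
the intensity fraction u(t) = speed(t)/peak-speed, clipped to [0, 1],
where each subject's peak speed grows with relative fitness
(10.5 + 0.18·(rel − 40) km/h ± 0.5).  Heart rate and VO₂ follow
first-order (mono-exponential) kinetics toward ramp-dependent targets,

    x'(t) = (target(t) − x(t)) / τ,
    HR-target = HRrest + (HRmax − HRrest)·u,   τ_HR ~ U(25, 45) s
    VO₂-target = VO₂rest + (VO₂max − VO₂rest)·u, τ_VO₂ ~ U(20, 40) s

with HRmax = 208 − 0.7·age.  This is the simplest dynamic consistent with
the classic mono-exponential on-kinetics of both signals: a slow initial
rise and a plateau near individual maxima.  The session terminates when
HR reaches 90% of HRmax (the usual CPET criterion; the gas-exchange and
perceived-exertion criteria are not simulated) or at the duration cap,
and the length is rounded down to a whole 10-s gas-analyzer interval.

Observations add Gaussian noise (HR σ = 1.5 beats/min at 1 Hz; VO₂
σ = 0.05 L/min on the 10-s breath averages).  Accelerometer axes are
rhythmic oscillations at an arm-swing cadence rising with speed
(1.2 + 0.12·speed Hz), amplitude 0.15 + 0.55·u g, plus Gaussian noise
whose σ grows with intensity (0.03 + 0.12·u g) and an onset transient
(0.2·e^{−t/30} g) while the gait settles; the z-axis carries a 1 g
gravity offset.  A single `noise_scale` multiplies every observation σ
(0 gives noiseless streams whose VO₂ is exactly the first-order filter of
intensity), and `missing_frac` (default 2%) removes interior heart-rate
samples and whole accelerometer seconds to exercise window-mean
imputation downstream.

All latents (noiseless HR/VO₂ trajectories, τs, peak speed, VO₂max) stay
on the session object so recovery tests can score against ground truth.

**What the generator does not emulate.**  Biomechanical gait structure,
HR variability and drift, breath-by-breath noise spectra, the VO₂ slow
component above the lactate threshold, respiratory-quotient or
perceived-exertion termination, and sensor clock drift.  Passing tests
therefore show that the pipeline and models are implemented correctly and
can recover a known mapping of the assumed form — not that any accuracy
figure transfers to real cohorts.

## Preprocessing

Each accelerometer axis is filtered independently with a scalar
random-walk Kalman filter (A = H = 1, Q = 0.01 g², R = 0.10 g²,
P₀ = 1 g², initialised at the first measurement).  Its steady-state gain
has the closed form K∞ = (P* + Q)/(P* + Q + R) with
P* = (−Q + √(Q² + 4QR))/2 ≈ 0.0270, giving K∞ ≈ 0.2702 — a useful
independent check of the recursion.  Filtered axes are downsampled to
1 Hz by per-second averaging (the standard block anti-alias choice; the
method itself only requires "downsampling"), the vector magnitude
VM = √(ax² + ay² + az²) is computed on the 1 Hz series, and the five
dynamic features (HR, ax, ay, az, VM) are joined on integer seconds over
the overlap of the streams.  Empty seconds surface as NaN.

Windows are 10 s, non-overlapping, one per VO₂ sample; the VO₂ timestamp
marks the *end* of its window, since gas analyzers report breath-averaged
values over the preceding interval.  Missing cells are replaced by the
window's per-feature mean; a window missing an entire feature is dropped
and counted.  Z-scoring uses population σ per feature (dynamic features
pooled over windows and time steps; static features separately); labels
are never standardized.  The scaler is fit on training folds only by
default (`scaler_scope="train_only"`) to avoid leakage; `"all"`
reproduces fitting on the pooled sample.

## Models

All five variants share one skeleton: dynamic 10×d block → (optionally)
1-D convolution over time with 64 filters, kernel 3, stride 1, same
padding, ReLU → (optionally) attention on the 10×64 map → one LSTM layer
with 128 tanh units → final hidden state concatenated with the 6 static
features → one linear output unit (VO₂, L/min).  Kernel size, layer
counts and the fusion point are the package's choices where the
architecture description leaves them open; the single-linear-unit fusion
implies the static features act *additively* on the prediction, which is
worth knowing when reasoning about what the models can express.

Attention blocks operate on C×W maps (C = 10 time steps, W = 64 feature
maps):

* **TAM** (temporal, squeeze-excitation): Z_C = mean over W;
  S = σ(W₂·ReLU(W₁·Z)) with reduction ratio r = 2 (bottleneck 5; r must
  divide C = 10); F′_C = S_C·F_C.  The bottleneck carries no bias terms,
  the standard form of this gate.
* **SAM** (spatial, CBAM-style): average- and max-pool over C, stack to
  2×W, shared same-padded 1-D convolution (kernel 7, with bias) → σ →
  per-feature weights broadcast over time.
* **STAM**: cascade, default SAM then TAM (the CLSTA naming order; the
  order is a config enum because the two descriptions of the cascade
  disagree, and `tam_first` reproduces the alternative).

Sigmoid gating means every attention weight lies strictly in (0, 1), so
attention only rescales; zero-parameter blocks scale inputs by exactly
0.5 (0.25 for the cascade) — handy exactness checks.

Training: MSE loss, Adam (lr 0.001, β = 0.9/0.999), batch 32, maximum
200 epochs with early stopping (patience 20) on validation RMSE and
restoration of the best-validation weights.  No explicit regularization
is used, faithful to the method's reported near-perfect training fits;
overfitting is expected and visible in the histories.  Everything is
seeded: parameter init (Glorot uniform) and batch order derive from the
config seed, so training is bit-reproducible.

The networks run on a small in-package reverse-mode autodiff engine over
numpy (`oxyflux._autodiff`).  The models involved are tiny, and a
dependency-free float64 engine keeps the whole stack inspectable and
exactly reproducible on any CPU; analytic gradients are verified against
finite differences in the test suite.

**A known hazard: tiny validation sets.**  With subject-wise splits, a
3-subject validation fold can be unrepresentative; we have observed runs
where validation RMSE bottoms within a few epochs (selecting a badly
underfit checkpoint) while held-out test R² keeps improving for dozens
more.  Six-fold cross-validation averages this out across folds; for
single-split experiments the package's own tests validate on six
subjects.  Users making single splits should prefer ≥6 validation
subjects.

## Evaluation

RMSE, MAE and R² = 1 − SS_res/SS_tot are computed exactly from their
defining formulas (R² is not clamped; a model worse than the mean
predictor reports negative).  Errors are stratified by ACSM intensity
zone — absolute cutoffs [0, 1.80), [1.80, 2.51), [2.51, ∞) L/min, or
relative <46%, [46%, 64%), ≥64% of VO₂max.  The printed absolute bands
leave a 2.47–2.51 gap; the moderate/high boundary is set at 2.51 because
"≥2.51" is the only inclusive high-zone statement.  Zone reports include
per-zone mean signed error (prediction − truth) to expose the
over/under-estimation pattern across intensities; empty zones report
n = 0 with null metrics.

## Cross-validation protocol

Three subjects are held out (seeded) as a fixed test set; the remaining
18 are split into six subject-level folds.  Each fold's model trains on
five groups and validates on one; per-split metrics are reported per
fold, as the mean over folds, and pooled over folds (both aggregations,
since either could be meant by a fold-averaged table).  The reported test
prediction per window is the mean over the six fold models.

## Problem sizes used by the shipped runs

The package's own test suite and `scripts/acceptance.py` run the full
21-subject cohort (~800 windows) for preprocessing contracts and
cross-validation, with CV epoch budgets of 40 (patience 10) and recovery
runs up to 200 epochs (patience 25); the structural-comparison sweep uses
12-subject cohorts over 5 seeds at 40 epochs.  These sizes are the
package's choices for a repeatable desk-scale study; all of them are
ordinary config parameters.

## Limitations

Synthetic-only validation (see the generator's non-goals); no
hyperparameter search; no regularization; single conv/LSTM layers by
design; additive static-feature fusion limits cross-subject scaling
interactions; accuracy on any real cohort must be established on that
cohort.
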
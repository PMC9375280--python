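# Methods

## The problem

A cardiopulmonary exercise test (CPET) produces a multivariate time series —
oxygen uptake (V̇O2), carbon dioxide output (V̇CO2), minute ventilation (VE),
heart rate, respiratory rate, tidal volumes and treadmill work rate — sampled
as averaged breath intervals (30 s here) across three protocol phases: rest,
an incremental treadmill ramp, and recovery. Clinicians interpret the test
with branching flowcharts over two summary quantities: peak V̇O2 and the
anaerobic threshold (AT), each judged against normal-value references. This
package implements that baseline plus three statistical/neural alternatives
that consume the whole series, and a harness that compares all of them under
stratified 5-fold cross-validation on a two-condition cohort
(heart failure vs metabolic syndrome).

## Synthetic cohort generator

The generator exists so every downstream stage is testable without patient
data. It emulates the mechanistic couplings that make CPET interpretable:

* **V̇O2 kinetics.** The work-rate fraction w(t) rises linearly over the ramp.
  V̇O2 relaxes toward `vo2_rest + (peak − vo2_rest)·w` by a first-order lag
  (τ = 0.5 min), saturating at the archetype's peak. A lag is the minimal
  mechanism producing realistic ramp and recovery shapes; no richer kinetic
  model is claimed.
* **V-slope structure.** V̇CO2 is piecewise linear in V̇O2 with slope 0.82
  below the AT and 1.35 above it, the break sitting at
  `at_fraction_of_peak × peak V̇O2`. RER = V̇CO2/V̇O2 therefore starts near
  0.82 and crosses 1.0 past the threshold.
* **Ventilatory coupling.** VE = (VE/V̇CO2 slope)·V̇CO2 + 3 L/min; RR scales
  linearly with VE between resting and maximal rates; VTex = VE/RR and
  VTin = 1.05·VTex. HR lags toward rest + reserve·w (τ = 0.75 min).
* **Noise.** Additive Gaussian noise on the primary channels (V̇O2, V̇CO2,
  VE, HR, RR), SD = 2% of each channel's dynamic range by default, clipped
  at physiologic floors (e.g. V̇O2 ≥ 0.15 L/min). Derived channels (RER,
  VE/V̇O2, VE/V̇CO2, METS, V̇O2/kg, tidal volumes) are recomputed from the
  noisy primaries, so definitional identities hold exactly at every noise
  level.

The default condition archetypes encode the classic contrasts: heart failure
with peak V̇O2 14 mL/min/kg, AT at 45% of peak, VE/V̇CO2 slope 38, HR max
130, 85 kg; metabolic syndrome with peak 28 mL/min/kg, AT at 60%, slope 27,
HR max 165, 98 kg. Per-patient jitter is limited to body mass (±10%) and HR
max (±8 bpm). The default protocol is 3 min rest + 10 min ramp + 3 min
recovery at 0.5-min sampling (32 rows/patient).

**What the generator does not emulate:** breath-level variability inside the
averaging window, test-termination variability (all synthetic tests run to
protocol end), sensor drift/artifacts, protocol differences between
diagnostic groups (configurable in principle, off by default), and the
overlap between real clinical populations. Because the default archetypes
are widely separated, near-perfect cross-validated accuracy on synthetic
cohorts demonstrates that the pipelines recover a real contrast — not that
they would achieve those numbers on patients.

## Stage segmentation and validation

Stages are recovered from the treadmill channels: rest is the maximal
stationary prefix (speed ≤ 0.1 mph, elevation as tiebreak for grade-only
ramps), test runs through the last moving row, recovery is the remainder.
The validation report (never raising) flags non-monotone time, non-positive
gas-exchange values, |RER − V̇CO2/V̇O2| > 0.05, and RER outside [0.5, 1.5].

## Flowchart baseline

* **Peak V̇O2** = highest 30-s rolling mean over the test stage.
* **AT by V-slope**: test-stage (V̇O2, V̇CO2) points ordered by V̇O2; every
  split with ≥ 3 points per side is scored by the summed SSE of two
  independent least-squares lines, subject to upper slope > lower slope
  (the candidate grid has one-sampling-interval resolution). The reported AT
  is the intersection of the winning pair of lines, clamped into the winning
  grid cell. If the best two-segment fit improves on a single line by less
  than 5% relative SSE, the AT is reported undetected — a deliberate
  conservative default, since a breakpoint fitted to noise is worse than a
  missing one.
* **Decision rule**: heart failure iff measured peak V̇O2 is below its lower
  limit AND the AT is below its lower limit or undetected; otherwise
  metabolic syndrome. Every branch is recorded in a decision trace.
* **Norms**: Hansen-style linear predicted-peak equations (men:
  mass·(50.72 − 0.372·age) mL/min; women: (mass + 43)·(22.78 − 0.17·age))
  with lower limits 0.84×predicted (peak) and 0.40×predicted (AT); or a
  FRIEND-style sex × age-decade percentile table (50th percentile as
  predicted, 20th as the peak lower limit). The embedded numbers are
  defaults approximating the published sources and are fully overridable
  from YAML; they are not reproductions of either reference.

## Latent-feature classifiers

Eight modeling channels (METS, HR, V̇O2, V̇CO2, RER, VE, VTex, VTin) are
standardized with mean/SD pooled over *training-fold* breaths only. Two
latent projections to 3 dimensions are provided:

* **PCA**, fitted separately per stage on the pooled standardized stage
  observations — the channel correlation structure genuinely differs at
  rest, under load and in recovery. Components are the top eigenvectors of
  the stage sample covariance (computed via SVD; a covariance
  eigendecomposition serves as the independent test oracle), with signs
  fixed so each axis' largest-magnitude loading is positive.
* **Autoencoder**: a single global 8→6→3→6→8 network (tanh hidden layers,
  linear output) trained to minimize the reconstruction MSE of the pooled
  training breaths with mini-batch (32) Adam, epoch cap 500 and a plateau
  stop; deterministic given the seed. One global encoder (not three
  per-stage ones) matches the single-autoencoder architecture; stage
  structure re-enters through the aggregation below. With identity
  activations its reconstruction error approaches the PCA(3) optimum, which
  the tests assert within 10%.

Each patient is summarized by the interquartile range (linear-interpolation
quantile convention) of each latent component within each stage: 9
volatility features, stage-major order. A logistic regression (L2, C = 1,
decision threshold 0.5, heart failure as the positive class) maps features
to a probability. Everything — standardization, projection, logistic — is
fitted inside each training fold; the leakage-guard test mutates held-out
patients and asserts no fitted parameter moves.

## CNN classifier

Each patient is resampled by piecewise-linear interpolation onto a uniform
256-point grid spanning rest-start to recovery-end, standardized per channel
with training-fold statistics, and presented as an 8×256 array. The network
is six 1-D convolution blocks with two-sided kernels
(lengths 7,7,5,5,3,3; filters 16,16,32,32,64,64; strides 1,1,2,1,2,1; ReLU;
'same' padding), global max pooling, and fully connected layers 64→32→2 with
softmax; no dropout or batch normalization anywhere. Training: Adam at
learning rate 1e-4, batch size 4, cross-entropy, early stopping when
validation loss fails to improve by 0.01 for 15 consecutive epochs
(best-validation weights restored), epoch cap 300, with a stratified 25%
validation split carved from the training fold. The kernel/filter/stride and
FC-width choices are engineering defaults chosen so ≥ 8 temporal positions
survive to the pooling layer; all are configurable. The forward/backward
passes and Adam are implemented directly on numpy — at tens of patients and
256 samples there is nothing for an accelerator to do — and backprop is
verified against finite differences in the tests.

## Evaluation harness

Stratified 5-fold cross-validation (simple random folds on a 15+15 cohort
risk single-class test folds); trainable methods are cloned and refitted per
fold, their held-out predictions pooled across folds before computing
per-condition precision/recall/F1 and one accuracy per method (micro
pooling; a per-fold-averaged mode exists but per-fold test sets of 6 make
fold-level ratios unstable). Rule-based flowcharts are fold-independent and
applied to every patient directly. Conventions: precision/recall are 0 on a
zero denominator, F1 is 0 when both are 0, report cells round half-up at 2
decimal places with accuracy as an integer percent.

## Problem sizes and numerical choices

Tests and the acceptance script use the default cohort (30 patients, 32 rows
each) and the default CNN grid (256), which keeps a full five-method 5-fold
benchmark under a few minutes on one CPU while leaving every method enough
signal to reach its documented behaviour. Degenerate inputs are rejected
early with named errors: zero-variance channels, single-class training sets,
series under 3 rows, protocols with non-integer row counts, kernels longer
than the surviving sequence. Ties in the V-slope grid resolve to the first
minimal-SSE split; PCA sign ties cannot occur once a largest-|loading|
channel exists.

## Known limitations

Binary classification only; treadmill protocols only; V-slope is the only AT
method (no ventilatory-equivalents or excess-CO2 variants); the flowchart
has exactly two leaves (no pulmonary-vascular, COPD or deconditioning
branches); synthetic cohorts are easier than clinical data by construction,
so cross-validated numbers here bound feasibility, not clinical performance.
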
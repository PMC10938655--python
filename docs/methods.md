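# Methods

## Problem and model

During square-flow volume assist-control ventilation (VACV) the ventilator
delivers a fixed inspiratory flow for a fixed time, so airway pressure (Paw)
is the dependent variable. If the patient's inspiratory muscles are active
while the valve meters a constant flow, the muscle pressure Pmus subtracts
from the passive Paw profile: the waveform develops the concave
"flow-starvation" deformation that clinicians grade visually. flowstarve
grades that deformation automatically in three classes (normal-mild,
moderate, severe) from the inspiratory phase of Paw alone, and relates it to
the esophageal-pressure (Pes) swing, the reference measure of inspiratory
effort.

## Signal conditioning and breath encoding

Raw tracings (time, flow, Paw, optional Pes) are low-pass filtered with a
zero-phase 4th-order Butterworth at 15 Hz (forward-backward, so the
effective order is 8 and no phase delay is introduced — phase shifts would
bias trigger-onset timing) and decimated to 40 Hz by polyphase resampling.
Breaths are segmented on the flow channel: an insufflation is a run of flow
above max(2 L/min, 5% of peak) sustained ≥ 100 ms, ending where flow falls
through 2% of that breath's peak; breath boundaries tile the recording.

A breath is patient-triggered when Paw dips at least 0.5 cmH2O (the typical
ventilator pressure-trigger setting; configurable) below the end-expiratory
baseline — the median Paw over the final 250 ms of the preceding expiration
— within the 300 ms before valve opening. The comparison is ≥, so a dip of
exactly the sensitivity counts. The classifier input window runs from the
trigger-dip onset through the end of insufflation (a switch restricts it to
the insufflation proper), linearly interpolated to 80 samples with endpoints
preserved. Vectors stay in raw cmH2O; per-breath standardization is an
option and is off by default.

## Expert-label aggregation

Each breath carries five expert votes in {normal-mild, moderate, severe,
wrong/confusing}. Exclusion rules run first: (a) ≥ 2 wrong/confusing flags
(technical invalidity trumps any majority — a breath voted W,W,S,S,S is
excluded), and (b) the polarized 2 normal-mild / 1 moderate / 2 severe
pattern, the only all-severity multiset that is excluded (verified by
exhaustive enumeration in the tests). Otherwise a 3-of-5 plurality labels
the breath; anything left routes to senior adjudication, represented as a
pre-recorded data field so aggregation stays a pure, order-invariant
function of the vote multiset. Fleiss' (1971) kappa is computed over the
three severity categories on breaths with five severity votes (any
wrong/confusing vote drops the breath from the kappa table, keeping the
rater count constant); the statsmodels implementation is used and is checked
against a from-scratch implementation of the formula to 1e-12.

## Classifiers

Two 3-class sequence classifiers over the 80-sample vector:

* **recurrent** — two stacked LSTM layers of 128 units; the final hidden
  state feeds a fully connected 3-way softmax head (198,531 parameters,
  matching the closed-form count for gated recurrent layers).
* **conv1d** — three 1-D convolution blocks of 16/32/64 filters, kernel 5,
  ReLU, max-pool 2, then a fully connected head. The topology is an
  engineering choice favoring low complexity.

Both are implemented as a compact numpy core (explicit forward passes,
hand-written gradients verified against central differences, Adam). A fixed
affine input scaling (x/20 − 1) is part of both architectures for numerical
conditioning of raw-cmH2O inputs; it is a constant of the network, not
per-breath standardization. Training minimizes multinomial cross-entropy
(Adam, learning rate 1e-3, batch 64, up to 50 epochs) with early stopping on
a 10% inner holdout (patience 5, best weights restored). Everything is
deterministic given the config seed. Ties in the predicted probabilities
break toward the more severe class — the clinically conservative direction.

Evaluation is repeated holdout: per repetition a fresh class-stratified
80/20 train-validation split and a freshly initialized model; metrics
(accuracy, precision, recall, F1, all support-weighted across classes by
default, with macro averaging as an option) are summarized by their median
across repetitions (15 by default). Splits are breath-level; patient-level
splitting is available for leakage-aware evaluation. A per-(patient, class)
cap of 350 breaths guards against overrepresented patients.

## Effort and double triggering

ΔPes is the median Pes over the final 250 ms of the preceding expiration
minus the inspiratory nadir (trigger onset → end of insufflation), floored
at 0; it is invariant to constant Pes offsets. Threshold tables report the
percentage of breaths per severity class with ΔPes strictly above 8, 10 and
15 cmH2O. Double triggering is flagged when the expiratory time between
consecutive insufflations is below 0.5× the running mean inspiratory time
and the first breath is patient-triggered. Feature comparisons across
classes use the Wilcoxon signed-rank test on size-matched random pairings
(the unpaired rank-sum test is an option) at the Bonferroni-corrected level
0.05/6 = 0.0083.

## Synthetic-data generator

Single-compartment linear mechanics: during insufflation
Paw = PEEP + R·F + V/C − Pmus with the square flow F fixed by the
ventilator, so effort appears entirely in Paw — exactly the mechanism being
graded. Expiration is single-exponential with time constant R·C (adequate
for segmentation; not a physiologic expiration model).
Pes = baseline + w·V/C − Pmus with chest-wall fraction w, so the Pes swing
tracks Pmus up to the chest-wall elastic term. Pmus is a half-sine (or
trapezoid) of configurable amplitude and duration. Before valve opening the
effort lowers Paw against the closed valve; the valve opens 120 ms after the
0.5 cmH2O sensitivity is crossed (a realistic trigger latency that also
gives the dip a detectable depth). When the effort still exceeds the
sensitivity after a short expiratory gap (0.3·Ti) and coupling is enabled,
a second stacked insufflation follows: double triggering.

Ground-truth severity comes from the peak-Pmus bands [0, 5), [5, 10) and
[10, ∞) cmH2O. The cohort generator draws per-patient mechanics
(R 8–15 cmH2O·s/L, C 40–60 mL/cmH2O, chest-wall fraction 0.15–0.30, Pes
baseline 3–8 cmH2O) and settings (flow 35–55 L/min, Ti 0.8–1.1 s, PEEP
5–10 cmH2O), and per-breath amplitudes from within-band ranges with margins
(1.5–4, 5.5–9.5, 11–20 cmH2O) so the three deformation grades are the
well-separated patterns experts grade visually. The modest chest-wall share
keeps ΔPes tracking Pmus closely, which gives the class-conditional
threshold table its ordinal structure (severe almost always > 8 cmH2O,
normal-mild essentially never). Effort onset leads the scheduled backup
insufflation by 250 ms so every simulated breath is patient-triggered, as in
tracings selected for assisted breaths. Noise is additive white Gaussian
(default sd 0.5 cmH2O) on Paw and Pes. Default class mix is 0.42/0.24/0.34.

What the generator does **not** emulate: nonlinear resistance, intrinsic
PEEP, leaks, cardiac artifacts on Pes, reverse triggering, ineffective
efforts, or the within-class morphological diversity of real patients.
Passing recovery tests therefore demonstrate that the pipeline and the
classifiers are correct and can learn the deformation-severity mapping, not
that real-world accuracy would match the synthetic figures: real expert-
labeled data remain necessary for clinical performance claims.

## Reference experiments and problem sizes

The synthetic recovery study uses 20 virtual patients × 150 breaths (≈3000
breaths, class mix 0.42/0.24/0.34, noise 0.5 cmH2O), full preprocessing, and
5 holdout repetitions per architecture with a 15-epoch early-stopping budget
— the cohort is cleanly separable, so longer schedules change nothing. The
double-trigger study uses 8 patients × 100 breaths with 8% of severe breaths
coupled. Worked-example metrics are recomputed from the published validation
counts of the original 28-patient study (six-thousand-breath dataset), which
are inputs because the original recordings are not public.

## Numerical choices and edge cases

* Segments are half-open internally; indices 0-based.
* resample_to_fixed_length requires ≥ 2 samples and is the identity on its
  own grid.
* Fleiss' kappa is reported as NaN when all votes fall in one category
  (chance agreement equals 1; the statistic is undefined).
* classification_metrics treats zero-support classes as zero
  precision/recall rather than NaN.
* The moderate row's off-diagonal split in the reconstructed published
  confusion matrices is not printed anywhere; it is divided evenly, and no
  reported quantity depends on it.
* Severity bands are left-closed: an amplitude of exactly 5 cmH2O is
  moderate.
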
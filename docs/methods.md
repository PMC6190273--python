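# Methods

`avfppg` grades arteriovenous fistula (AVF) stenosis from bilateral
photoplethysmography (PPG).  A fistula narrowing on one arm delays and
damps the pulse reaching that hand, so the left and right thumb PPG
channels become asynchronous; the pipeline quantifies this asynchrony and
maps it to one of three clinical severity classes.  This note records the
model, the defaults and the design choices, and what the synthetic data
does and does not establish.

## Severity grading

The degree of stenosis is computed from two vessel diameters read off
B-mode ultrasound or angiography,

    DOS = 1 − (d/D)²,

with `d` the lesion diameter and `D` the normal vessel diameter (any
common length unit).  DOS = 0 is an unnarrowed vessel and DOS = 1 total
occlusion.  The clinical partition is class 1 (DOS ≤ 30 %), class 2
(30 % < DOS ≤ 50 %, may impair dialysis efficiency) and class 3
(DOS > 50 %, usually needs surgical revision).  The band edges are
half-open, closed on the milder class, so grading is a total function;
the edges are arguments of `dos_to_class` for sensitivity analyses.

## Synthetic bilateral PPG

No public bilateral-PPG stenosis corpus exists, so experiments run on a
generator that emulates the statistical structure the classifier relies
on.  Each beat is the sum of two log-normal-shaped lobes: a systolic lobe
(unit height at `rise_time`, log-width 0.30) and a dicrotic lobe of
height `1 − notch_depth` centred at `rise_time + 2.5·notch_delay`
(rise log-width 0.30, decay log-width 0.55).  The asymmetric dicrotic
decay yields the flat diastolic runoff of a real pulse and guarantees an
interior local minimum — the dicrotic notch — between the lobes; the
near-zero rise of a log-normal lobe at τ → 0 gives a well-defined pulse
foot.  Shape defaults: heart rate 75 bpm, systolic amplitude 1 (arbitrary
units), rise time 0.15 s, notch delay 0.12 s, notch depth 0.65, plus a
0.03-unit common-mode respiratory-band (0.25 Hz) baseline drift.

The right channel is perturbed relative to the left by four asymmetry
parameters, each a deterministic monotone function of DOS:

| parameter        | default coupling    | unit |
|------------------|---------------------|------|
| foot delay       | 0.08 · DOS          | s    |
| rise-time skew   | 0.05 · DOS          | s    |
| amplitude ratio  | 1 − 0.4 · DOS       | –    |
| notch shift      | 0.03 · DOS          | s    |

The coupling coefficients are effect sizes chosen once so that the three
class bands are separable but overlap under physiological jitter; they are
exposed in `AsymmetryCoupling`.  Per-subject jitter defaults: beat-period
CV 2 % (shared by both channels — one heart), landmark timing SD 5 ms and
amplitude CV 3 % (independent per beat and channel).  A cohort draws DOS
uniformly within each class band (defaults [0.05, 0.30], (0.30, 0.50],
(0.50, 0.85]) and labels every subject from its drawn DOS through the
grading partition; metadata carries the diameter pair `D = 1`,
`d = √(1 − DOS)`.

The generator also emits ground-truth landmark annotations computed
numerically from the clean rendered waveform (argmin/argmax per beat
window), so detectors can be scored without circular use of the detection
code.

**Noise.**  `add_noise` scales a zero-mean perturbation to an exact target
SNR, defined as `10·log10(P_signal/P_noise)` with powers taken after mean
removal.  Two constructions are provided: white Gaussian samples, and a
*signal surrogate* — the recording's own FFT magnitudes with uniformly
randomized phases.  The surrogate shares the pulse band, so the 20 Hz
low-pass front end cannot remove it; white noise at 1 kHz loses roughly
96 % of its power to that filter, which makes it a very mild stress test.
The robustness protocol therefore defaults to the surrogate.

**What the generator does not emulate:** respiration- and vasomotor-driven
amplitude modulation, motion artifacts, sensor coupling changes, autonomic
heart-rate dynamics beyond white period jitter, and real pulse-morphology
diversity (age, stiffness, damping).  Passing results on synthetic cohorts
show that the pipeline recovers the asynchrony structure it assumes; they
do not certify clinical performance.

## Preprocessing and segmentation

Raw channels are filtered with a second-order Butterworth low-pass at
20 Hz (fs = 1 kHz), causal by default — matching a streaming front end —
with the initial state set to the DC steady state to suppress the start-up
transient.  A zero-phase forward-backward mode is available; bilateral
timing features are unaffected by the choice because both channels share
the same group delay, but single-channel comparisons against ground truth
should use the zero-phase mode (the causal group delay is ≈ 11 ms in the
pulse band, comparable to the landmark tolerances).

Pulse feet are detected with a standard slope-based rule: candidate
upstrokes are maxima of the 25 ms-smoothed first derivative above half the
90th percentile of its positive values, separated by a 250 ms refractory
period; each foot is the signal minimum in the 400 ms window preceding its
upstroke, and feet closer than 0.33 s are rejected as spurious (the
dicrotic upstroke is also suppressed by the derivative threshold, since
its slope is well below half the systolic slope at the default notch
depth).  Within each foot-to-foot window the systolic peak is the interior
argmax and the dicrotic notch the deepest interior local minimum between
the peak and 80 % of the window; damped beats without an interior minimum
carry no notch.  Indices are 0-based; windows half-open `[foot, next_foot)`.

## Features

Per subject, beats are matched across channels by nearest foot times
(within half the left channel's median beat period), and four asymmetry
features are aggregated by the median over matched beats:

- `d1` — |Δ foot time| (s),
- `d2` — |Δ systolic-peak time| (s), the pulse-transit-time asymmetry,
- `d3` — |Δ rise time| (s), rise = peak − foot per channel,
- `d4` — |Δ pulse amplitude| divided by the larger of the two channels'
  median pulse amplitudes (dimensionless).

The d4 scale is a *common* reference deliberately not per-channel:
dividing each channel by its own median would cancel exactly the
attenuation d4 measures.  With this definition d4 is invariant to a common
gain on both channels and equals `1 − r` for an amplitude ratio `r` < 1.
The median aggregation tolerates occasional landmark misdetections.

Cohort-level min-max normalization follows the classical
`(x − min)/(max − min)` per feature, fitted on training rows only and
applied unclipped to held-out rows (values outside [0, 1] are informative);
degenerate columns map to 0 with a warning.

## ECOC one-vs-rest SVM

The three-class decision is decomposed by the fixed code matrix
class 1 → (1,1,1), class 2 → (0,1,0), class 3 → (0,0,1): learner k
separates the classes whose bit k is 1 from the rest.  Each learner is a
soft-margin kernel SVM trained by a self-contained SMO solver (pairwise
analytic updates, Platt working-set heuristics, tolerance 1e−3); the
pairwise updates preserve Σαᵢyᵢ = 0 exactly and the box constraints by
clipping, and the bias is recomputed as the average over margin support
vectors (0 < αᵢ < C).  Kernels: linear `x·z`, quadratic `(x·z + γ)²`
(default, γ = 1) and RBF `exp(−γ‖x − z‖²)` (γ defaults to 1/n_features).
A non-standard RBF variant with `x + z` in the exponent is selectable for
fidelity experiments only; it is not positive definite and is never a
default.  Hyperparameter defaults C = 10, with a small cross-validated
grid-search utility over {0.1, 1, 10, 100}.

Prediction thresholds each margin at 0 (non-negative → bit 1), decodes the
3-bit output code to the nearest codeword in Hamming distance, and breaks
ties — possible only for the code (0,0,0), which is Hamming-1 from both
class 2 and class 3 — by margin-weighted decoding (minimize Σ|mₖ| over
mismatched bits) and then by the lowest class index.

## MLP baseline

The comparison classifier is a 4–36–3 perceptron with log-sigmoid hidden
units and linear outputs, trained by Levenberg–Marquardt on one-hot
targets: solve `(JᵀJ + μI)δ = −Jᵀr`, accept a step only if the SSE
decreases (μ ÷ 10), otherwise μ × 10 and retry; stop on gradient ∞-norm
< 1e−7, μ > 1e10, or 200 epochs.  Weights initialize uniform in
±√(6/(fan_in+fan_out)) from a seeded generator; prediction is the argmax
of the linear outputs with ties to the lowest class index.  A multi-start
utility returns the best of k seeds by final SSE.

## Evaluation

Metrics are one-vs-rest per class — sensitivity TP/(TP+FN), specificity
TN/(TN+FP), precision TP/(TP+FP) — macro-averaged over classes with
defined denominators, plus overall accuracy, all on the 0–100 % scale;
per-class values are always reported so other conventions can be
recomputed.  Cross-validation defaults to leave-one-subject-out with the
min-max scaler fitted inside each training fold; pooled fold predictions
form a single confusion matrix.  CPU time is logged for information only.

The noise-robustness protocol trains once on the clean cohort, keeps the
correctly classified subjects, then for each target SNR and noise seed
corrupts their raw signals, re-runs the whole preprocessing and feature
pipeline, and re-classifies with the fixed clean-trained model, averaging
metrics over seeds.

## Problem sizes and numerical choices

Reference experiments use 66 subjects (22 per class), 10 s records at
1 kHz, and 10 noise seeds per SNR — sizes chosen to match the scale of a
single-center dialysis cohort while keeping every experiment reproducible
on one CPU in minutes.  Ties and degenerate cases are fixed deterministic
conventions throughout: class-band edges closed on the milder class,
decision threshold 0 → bit 1, argmax ties to the lowest index, degenerate
normalization columns to 0.  Seeds enter only through
`numpy.random.default_rng`; identical inputs and seeds give bitwise
identical outputs.

## Known limitations

- The four features assume reliable foot/peak detection; severely damped
  or arrhythmic pulses (not generated here) would need beat-quality
  gating.
- The d1–d4 definitions are one reasonable reading of landmark-based
  bilateral asymmetry (foot, transit time, rise time, amplitude); the
  extraction is isolated behind `extract_features` so alternative
  definitions can be swapped.
- SMO is designed for the small cohorts this problem ships (tens to
  hundreds of subjects); it makes no sparse/caching effort for large n.
- The class bands overlap at their edges by construction, so synthetic
  LOSO accuracy saturates below 100 % — intentional, as perfectly
  separable cohorts would make the classifier comparison vacuous.
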
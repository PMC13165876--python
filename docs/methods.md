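# Methods

`gazecog` implements a screening pipeline for cognitive decline (CD) based
on two behavioral modalities recorded by a head-mounted display: eye
tracking at 120 Hz (two 3-D eye origins, a combined 3-D gaze point, two
pupil diameters in mm — 11 channels) and six facial blend-shape (FBS)
intensities in [0, 1], natively 60 Hz and upsampled to 120 Hz by
nearest-neighbor interpolation. Subjects complete five task paradigms:
visual short-term-memory search (VSST), memory calculation (MCT), pupillary
light reflex (PRT), pro/anti-saccades (ST), and voluntary facial expression
(FET). The study data are private, so the package ships a synthetic cohort
generator that emulates the raw streams and is used by every test.

## Preprocessing

1. **Blink detection.** A sample is a blink when either eye's openness
   value drops below τ = 0.9. The paper's source leaves the binocular
   combining rule open; we flag on *either* eye because a blink corrupts
   gaze and pupil in both channels. The blink mask is applied jointly to
   pupil, gaze-point and eye-origin channels.
2. **Gap repair.** Masked samples are linearly interpolated between the
   flanking valid samples; leading/trailing gaps hold the nearest valid
   value.
3. **Pupil filtering.** A causal 2nd-order Butterworth low-pass (bilinear
   design, cutoff fs/8 = 15 Hz) applied as a plain direct-form recursion
   with zero initial state. Only the pupil diameters are filtered — the
   high-frequency noise motivating the filter lives there; gaze channels
   feed a velocity threshold that tolerates white jitter. The recursion is
   causal, so latency-type features inherit the same group delay in both
   groups; no between-group bias is introduced.
4. **Gaze merging.** Cyclopean origin = midpoint of the eye origins;
   merged endpoint = the recorded combined gaze point. Angular velocity is
   the central-difference angle subtended at the cyclopean origin between
   the endpoints two samples apart, divided by the spanned time (one-sided
   at the edges). The velocity is angular (deg/s), matching the I-VDT
   threshold's units.
5. **Facial smoothing.** Gaussian kernel, σ = 2 samples, truncated at 4σ,
   reflect padding; constant signals pass unchanged.
6. **Standardization.** Model inputs are z-scored per channel with
   statistics estimated on the training split only, to avoid leakage.
   Channels with zero spread are centered only.

## Oculomotor events (I-VDT)

Parameters: velocity threshold 30 deg/s, temporal window 130 ms, dispersion
threshold 2 deg, minimum saccade duration 40 ms. Samples strictly above the
velocity threshold seed saccade runs; runs shorter than the minimum
duration are demoted and merged into flanking fixations. Remaining spans
are split into fixations by a greedy dispersion-window test (dispersion =
maximum pairwise angle from the cyclopean origin, grown incrementally).
Smooth pursuit is collapsed into fixation: all paradigm targets are
stationary, so a third class would never be well populated. Ties at
exactly the velocity threshold classify as fixation. Sub-window residual
spans are absorbed into an adjacent fixation so events always tile the
segment.

## The 27 behavioral features

* **VSST** (8-s search phase): FixROI = ROI fixation time / total fixation
  time × 100; TfROI = onset of the first ROI fixation relative to search
  onset, capped at the phase duration when the ROI is never fixated
  (mirroring the expression-latency fallback); TROI = ROI fixations plus
  saccades that start and end inside the ROI; Sl = median saccade
  amplitude in degrees (the printed unit); TmROI = median ROI fixation
  duration. ROI membership is a spherical test (default radius 0.15 m)
  on 3-D gaze endpoints, standing in for engine-side ray casting.
* **MCT**: Aa = per-sample dwell fraction on the tracked target over the
  search phase × 100; Lc = first fixation on the correct option minus
  option onset, fallback = calculation-phase duration. The source material
  states a 10-s search phase in one place and a 5-s normalization span in
  another; we normalize by the actual segment duration and expose an
  override.
* **PRT**: per eye over the 1-s stimulus window — Rd = max−min diameter;
  constriction onset = first sample more than 3 pre-stimulus SDs below the
  running-mean baseline μ_Tb (the baseline is the arithmetic mean computed
  by the streaming recursion μ ← k/(k+1)·μ + x/(k+1)); T1 = onset latency;
  VCmax / ACmax = peak |first/second difference| over the constriction
  limb; T2 = onset-to-peak-velocity; T3 = onset-to-trough. Eyes averaged,
  then the two trials averaged.
* **ST**: anticipatory saccades (latency < 100 ms) are excluded first.
  Per condition (6 pro-, 6 anti-saccade trials): Ls = mean latency of the
  first admissible saccade per trial; Vm = mean of mean velocities and
  As = mean amplitude over all effective saccades; Vmax = the
  condition-wide maximum peak velocity (a global max, not a per-trial
  mean — "peak value among all effective saccades").
* **FET** per emotion: the left/right cheek channels are combined by their
  mean into one intensity series (the combination rule is not specified in
  the source; the mean is symmetric and keeps the [0, 1] range). I = mean
  intensity over the 5-s phase; T = Δt × count of samples above θ = 0.1;
  L = first supra-θ crossing, 5 s when never crossed. Samples beyond the
  nominal span are ignored, so trailing data cannot change any output.

Missing features (absent task) are NaN and median-imputed within the
training split for the tabular baselines only; the deep model never sees
features.

## The MIL classifier

Per task, the 17-channel sequence (facial channels zero-filled outside
FET) is cut into windows of W = 150 samples with stride S = 50; tails
shorter than a window are discarded. Each window passes through four
parallel 1-D convolutional streams (kernels 3/5/7/9; conv → ReLU →
max-pool → conv → ReLU → global average pooling; output channels 32, 64,
16, 32) concatenated into a 144-dim embedding. The network is pure NumPy
with hand-derived backpropagation (im2col convolutions, argmax-routed
pooling gradients), validated against finite differences in the tests.

**Phase 1** trains encoder + a 144→64→2 MLP head on all windows with
inherited subject labels, Adam (lr 1e-3), batch 32, soft weights
w_i = exp(−γ·loss_i) with γ = 1 refreshed after each epoch from that
epoch's recorded per-instance losses (the refresh schedule is our choice;
the source only states weights derive from loss). The epoch budget is
deliberately restricted. **Phase 2** freezes the encoder and trains gated
attention (e_n = wᵀ(tanh(W_V z_n) ⊙ σ(W_U z_n)), K = 64, a = softmax(e),
Z_bag = Σ a_n z_n) plus a linear bag classifier, one bag per step,
bag-level cross-entropy; when a validation split exists the
best-validation-accuracy epoch's parameters are kept. Subject diagnosis is
the majority of the five task votes; a model abstains when its task
segment is missing, and a post-abstention tie resolves to CD
(screening-conservative).

**Evaluation protocol**: per repeat, 15 + 15 subjects are drawn for
train/validation (split 7:3, stratified), the remaining 5 + 5 are the
independent test set; all splits are re-drawn each of 10 repeats, and
accuracy/precision/recall/F1 (CD positive) are reported as mean ± SD. The
desk-scale training budget used by the tests and examples is 8 phase-1 and
15 phase-2 epochs — enough for the strongly separated synthetic cohort;
the caps are configurable for harder data.

## Tabular baselines and statistics

Logistic regression (L2, C = 1), Gaussian naive Bayes, and an RBF SVM
(γ = "scale", C selected from {0.1, 0.4, 0.7, 1} on the validation split)
are fit on the 40-column table (27 behavioral features + age + sex +
education + 10 MoCA-B items) via scikit-learn, with training-split
standardization and median imputation. Group screening uses the two-sided
Mann-Whitney U test (exact for small tie-free samples, tie-corrected
normal approximation otherwise, per scipy's policy); p-values are reported
unadjusted, matching the source's reporting.

## Synthetic cohort generator

Defaults follow the study conditions: 20 HC + 20 CD; demographics drawn
from the reported group means/SDs (age 70.55 ± 9.01 vs 77.35 ± 11.17,
education 9.45 ± 1.76 vs 8.85 ± 2.06, MoCA-B 25.20 ± 1.32 vs 18.35 ± 4.48,
female 65 % vs 50 %); MoCA-B totals are distributed over ten items with
maxima summing to 30. Task timing: VSST 3 s memorize + 8 s search; MCT 2 ×
(3 + 10 + 5 s); PRT 2 × 5 s fixation whose final second is the light
stimulus; ST 12 × (2 s central + 2 s peripheral), the first six trials
pro-, the last six anti-saccades; FET 2 × 5 s (happy then sad). Two-second
unlabeled gaps separate trials, giving the pupil room to re-dilate before
the next baseline span.

Group effects are injected as latent per-subject targets (HC mean, CD
mean, common SD) realized by construction: scheduled ROI dwell patterns
(VSST/MCT), a minimum-jerk pupillary constriction with latency, amplitude
and rise time plus a mild post-trough redilation ("pupil escape") that
keeps the trough time well defined, minimum-jerk saccades on a
main-sequence duration rule (the same profile used for all scripted gaze
shifts), and smoothstep expression ramps generated natively at 60 Hz.
Directions follow the reported group differences: CD shows reduced ROI
fixation and dwell, delayed first fixations, reduced attention allocation
and slower calculation, delayed/attenuated pupil responses, longer
saccade latencies with lower peak velocities and smaller anti-saccade
amplitudes, and weaker, later, shorter facial expressions. Mean saccade
velocity and pro-saccade amplitude carry no direct injection; pro-saccade
amplitude stays non-significant, while mean velocity co-varies with the
duration scaling.

Three *pervasive* latent dynamics complete the model, because decline
expresses itself continuously in real recordings, not only inside scripted
events: fixational gaze drift (mean-reverting wander of the gaze point,
stationary SD 0.15° HC vs 0.40° CD — oculomotor instability), pupillary
unrest (hippus, 0.2–0.45 Hz oscillation of 0.10 mm HC vs 0.04 mm CD), and
postural head sway (common slow wander of both eye origins, 2 mm HC vs
5 mm CD, with the gaze endpoint world-anchored as vestibulo-ocular
compensation would keep it). These give every sliding window a group
signal, which is what lets windows inherit the subject label in phase 1
without being mostly label noise. All three sit in the effect table, so
the null configuration removes them together with every other shift.

Noise: white gaze jitter (2.5 mm on the target plane ≈ 0.13°), pupil noise
0.015 mm, FBS jitter 0.01, blinks at 10/min (openness dip to 0.15, pupil
dropout 100–250 ms). Raw-signal scales (pupil ≈ 4.2 mm baseline, targets
on a plane 1.5 m ahead, eye origins ±32 mm) are physiologically plausible
choices; the source reports no raw-signal statistics.

**What the generator does not emulate:** measurement nonstationarities
(slippage, calibration decay), anti-saccade direction errors, corrective
saccade chains, expression asymmetries, and any within-CD severity
structure (MCI vs AD). Passing tests therefore demonstrate that the
pipeline recovers the encoded behavioral structure under realistic noise —
not clinical performance on real populations.

## Numerical choices and degenerate inputs

Indexing is 0-based with half-open ranges throughout. Facial upsampling
breaks nearest-neighbor ties toward the earlier sample. Sequences shorter
than one window yield an empty bag (that task model abstains). A fully
masked series cannot be interpolated and raises. Features of a missing
task are NaN-flagged. The Mann-Whitney path returns p = 1 for all-tied or
too-small features. All randomness flows through seeded
`numpy.random.Generator` instances; a fixed seed reproduces cohorts,
training and metrics bit-identically.

## Known limitations

The NumPy training loop is CPU-bound and sized for the 40-subject study
scale, not for large cohorts. Phase-boundary assignment inside a trial
relies on nominal paradigm timing because phase onsets are not logged in
the data layout. The MCT "moving cluster" is emulated with a static target
ROI — the dwell fraction, not target motion, carries the construct. The
evaluation protocol re-draws the independent test set every repeat, so
repeat metrics are correlated through overlapping test subjects.
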
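# gazecog

Digital behavioral biomarkers for cognitive-decline (CD) screening from
multimodal head-mounted-display recordings: 120 Hz eye tracking (3-D eye
origins, combined gaze point, pupil diameters) and facial blend-shape
intensities across five task paradigms — visual short-term-memory search
(VSST), memory calculation (MCT), pupillary light reflex (PRT),
pro/anti-saccades (ST) and voluntary facial expression (FET).

The package is aimed at researchers prototyping behavioral screening
pipelines: it provides the full chain from raw session CSVs to a
subject-level diagnosis, plus a synthetic cohort generator so everything is
runnable and testable without clinical data.

## What it computes

1. **Preprocessing** — blink detection on eye openness (threshold τ = 0.9),
   linear gap interpolation, a causal 2nd-order Butterworth low-pass on
   pupil diameter (cutoff fs/8), cyclopean gaze merging with angular
   velocity, Gaussian smoothing (σ = 2) of facial channels.
2. **Oculomotor events** — I-VDT segmentation into fixations and saccades
   (velocity 30°/s, window 130 ms, dispersion 2°, minimum saccade 40 ms),
   with anticipatory saccades (latency < 100 ms) excluded.
3. **27 behavioral features** — ROI-based search metrics, attention
   allocation and calculation latency, pupillary light-reflex kinematics
   (ACmax, VCmax, Rd, T1–T3 via the running-mean baseline
   μ ← k/(k+1)·μ + x/(k+1)), pro/anti-saccade latency/velocity/amplitude,
   and facial expression intensity I = (1/N)ΣVal, duration
   T = Δt·Σ1(Val > θ) and onset latency L (fallback 5 s).
4. **Classifiers** — tabular baselines (LR, Gaussian NB, RBF SVM) on a
   40-column table (27 features + age/sex/education + 10 MoCA-B items),
   and a multiple-instance deep model: sliding windows (W = 150, S = 50)
   → four parallel 1-D conv streams (kernels 3/5/7/9, 144-dim embedding)
   → two-phase training with soft loss weighting
   w_i = exp(−γ·loss_i) → gated-attention pooling
   e_n = wᵀ(tanh(W_V z_n) ⊙ σ(W_U z_n)) → per-task bag classifiers fused
   by majority vote. The network is implemented in NumPy with
   hand-derived backpropagation.
5. **Statistics** — two-sided Mann-Whitney U screening of every feature.

## Worked example

```bash
python examples/05_train_mil_classifier.py
```

trains the five task models on a 20-subject synthetic cohort (14 training,
6 held-out subjects) and prints held-out subject votes:

```
held-out predictions (CD = 1):
  S008  true=0  fused=0  per-task={'VSST': 0, 'MCT': 0, 'PRT': 0, 'ST': 0, 'FET': 0}
  S009  true=0  fused=0  per-task={'VSST': 0, 'MCT': 0, 'PRT': 0, 'ST': 0, 'FET': 0}
  S010  true=0  fused=0  per-task={'VSST': 0, 'MCT': 0, 'PRT': 0, 'ST': 0, 'FET': 0}
  S018  true=1  fused=1  per-task={'VSST': 0, 'MCT': 0, 'PRT': 1, 'ST': 1, 'FET': 1}
  S019  true=1  fused=1  per-task={'VSST': 1, 'MCT': 1, 'PRT': 1, 'ST': 1, 'FET': 1}
  S020  true=1  fused=1  per-task={'VSST': 1, 'MCT': 1, 'PRT': 1, 'ST': 1, 'FET': 1}
{'accuracy': 1.0, 'precision': 1.0, 'recall': 1.0, 'f1': 1.0}
```

Each line is one test subject: the five per-task votes and the fused
majority decision (3 of 5 needed). `examples/01–04` walk through cohort
simulation, preprocessing/event segmentation, feature extraction, and
group screening; each prints what its numbers mean.

The same functionality is exposed as a thin CLI:

```bash
gazecog simulate --out cohort/ --seed 0
gazecog extract  --cohort cohort/ --out features.csv
gazecog stats    --features features.csv --out stats.csv
gazecog evaluate --cohort cohort/ --seed 7
gazecog train    --cohort cohort/ --out models.npz
gazecog predict  --model models.npz --session cohort/S001.csv
```

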
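# Methods

`edassl` implements a per-subject ("personalized") self-supervised learning
pipeline for ordinal stress regression from raw electrodermal activity
(EDA). This note records the models, the synthetic study conditions, the
numerical choices, and the places where the design was genuinely open.

## The pipeline

For each subject, independently:

1. **Unit scaling.** The raw conductance trace is min–max scaled to [0, 1]
   using the subject's own full-trace extrema. Pre-training consumes the
   entire recording, so the fit region is the whole trace; the same affine
   map is applied to every window downstream. (Forecast RMSEs quoted
   anywhere in the package are on this unit scale.)
2. **Pretext task.** The scaled signal is sliced into overlapping pairs — a
   7000-sample input window and its 40-sample continuation — advancing by a
   100-sample stride, so a signal of length L yields
   `floor((L − 7040)/100) + 1` pairs. A 1-D CNN forecaster (below) is
   trained to minimize the MSE of the 40-sample forecast. Validation RMSE on
   a held-out 10% of pairs monitors progress; the *repeat-last-value*
   forecaster is the natural skill baseline, since at 700 Hz the next 57 ms
   of skin conductance is close to the last observed sample.
3. **Transfer.** The forecaster's four convolution layers are copied
   bit-exactly into the downstream regressor and marked non-trainable; the
   regressor's dense head is freshly initialized.
4. **Downstream task.** Six questionnaire items are modelled separately
   (one head per subject × question). Likert answers 1..4 become ordinal
   regression targets 0.25/0.5/0.75/1.0 (`likert/4`), preserving order and
   uniform spacing. Labelled 7000-sample windows lie entirely inside one
   annotated segment and carry that segment's converted answer.
5. **Benchmark.** The SSL model (frozen conv + fine-tuned head) is compared
   against an identically architected, fully trainable, freshly initialized
   supervised control. Both arms always train on the identical sampled
   windows and are scored on the same held-out test set (paired design;
   every result row carries a hash of the sampled indices so pairing is
   auditable).

## Architectures

Both networks share the convolutional feature extractor: four valid-padding
1-D conv layers with 40, 30, 18 and 30 filters, each followed by a leaky
ReLU (slope 0.01). The forecaster then applies dense layers of 70 and 30
units and a linear 40-unit output; the regressor applies dense layers of
50, 30 and 10 units and a linear scalar output.

The filter counts and dense widths are fixed by the method being
implemented; kernel length, stride, padding and pooling were open choices.
We use kernel 16, stride 4, valid padding and no pooling, giving frame
counts 7000 → 1747 → 433 → 105 → 23 and a 23 × 30 = 690-feature flatten —
deep enough that the last frames still see ~1.8 s of signal, small enough
that the dense head stays tiny. All of these are config-exposed
(`PretextArchitecture` / `DownstreamArchitecture`) and recorded in
checkpoint manifests.

The engine itself is a compact NumPy implementation (`edassl.nn`):
convolutions are lowered to BLAS GEMMs via an im2col matrix (built with a
frame decomposition when the stride divides the kernel), gradients are
exact, parameters are float32, and initialization is He-uniform from a
seeded generator. With a single-threaded BLAS, identical seeds and data
reproduce identical weights bit for bit — the full-protocol determinism
guarantee rests on this.

## Training schedules

*Pretext:* Adam (lr 1e-3), batch 32, a 10% validation split, early stopping
on validation RMSE with best-weight restore. The epoch cap is the caller's
budget; the multi-subject study uses 2 epochs per subject, enough to move well
past the initial transient on these synthetic signals.
An optional `target_metric` stops training as soon as a stated skill level
(e.g. the last-value baseline) is reached.

*Downstream (both arms, identical):* Adam (lr 2e-3), a fixed 10-epoch
budget, full-batch updates when the label budget is ≤ 32 and minibatch 32
otherwise, and the output bias initialized to the training-label mean so no
epochs are spent recentering the output scale. A fixed, shared schedule
keeps the comparison fair — neither arm gets more optimization — and makes
every run's cost deterministic. The 10-epoch budget is a desk-scale choice
that keeps the full 1080-row benchmark (3 subjects × 6 questions ×
6 budgets × 5 resamples × 2 arms) tractable on one CPU; note that any
short shared budget inherently favours the arm that converges faster per
epoch (the frozen-feature head), and with substantially longer budgets the
two arms draw closer on this generator. Larger caps are one config field
away (`TrainConfig.max_epochs`).

## The synthetic subjects

No public recording is required anywhere: the simulator is the study
surface. A subject is

    conductance(t) = tonic(t) + Σ_i a_i · k(t − t_i) + ε(t), clipped at 0,

with a Gaussian-random-walk tonic level around 2 µS (drift 0.01 µS/√s), a
homogeneous-Poisson train of skin-conductance responses per segment at rate
`0.03 + 0.20 × arousal` events/s, each a peak-normalized biexponential kernel
`k(t) ∝ exp(−t/4.0) − exp(−t/0.75)` (peak at 1.545 s) with amplitude
~N(0.3, 0.1²) µS truncated at 0, and white sensor noise (σ = 5 nS). Kernels
spill across segment boundaries — sweat glands do not reset at condition
changes. The default schedule is eight 150 s segments (1200 s total)
alternating low and high arousal; Likert answers track arousal
(≈ 1 + 3·arousal) with subject-specific ±1 jitter on a third of items,
emulating self-report subjectivity without severing the signal–label link.

What the simulator does *not* model: motion artifacts, electrode drift or
detachment, respiration coupling, inter-item questionnaire structure — and,
deliberately, any coupling between the **tonic level and arousal**. The
tonic baseline is a pure label-independent random walk; the only
signal–label pathway is the phasic event *rate*. Two consequences follow,
and both are visible in the benchmark results rather than hidden by them:

* **The information per window is small.** At rates 0.03–0.23 events/s, a
  10 s window contains 0–3 skin-conductance responses, so the arousal
  evidence in a single window is Poisson-limited; no single-window model
  can get far below an RMSE of roughly 0.24 on the 0.25–1.0 target scale
  (the label spread is ~0.29).
* **The pretext and downstream tasks are nearly orthogonal here.**
  Forecasting the next 57 ms rewards features of the last ~1 s of signal;
  the stress label rewards window-scale statistics (event counts, level
  elevation). On real stress recordings the tonic level itself rises under
  stress, so a forecaster's "current level" features double as stress
  features — that mechanism is the plausible carrier of the label-efficiency
  effect on real data, and it is absent from this generator by design.

The multi-subject synthetic benchmark should therefore be read as a *full,
honest exercise of the machinery* — windowing, per-subject pre-training,
bit-exact transfer and freezing, paired sampling and evaluation — under
study conditions where the two arms are expected to be close; the
label-efficiency and stability checks report whatever contrast actually
emerges. The optional WESAD-layout loader (`read_wesad_subject`) is the
documented path for the real-data setting, where the tonic-level pathway
exists.

## The benchmark protocol

Per subject: labelled windows are tiled at a 6000-sample stride (moderate
overlap, 100-window pool from a ~20-minute recording); 20% of windows are
held out as the test set by a seeded uniform split (random mode mirrors the
reference protocol and permits window-overlap leakage; a `block` mode with
disjoint signal coverage is available and recommended for real data). From
the remaining pool, capped at 100 windows, each budget in
{10, 20, 30, 50, 75, 100} is drawn 5 times without replacement ("five
independent samples"); a with-replacement mode is selectable. Both arms
train on each draw and are evaluated on the fixed test set.

Reported aggregates:

* **Label-efficiency crossing** — the smallest budget whose SSL mean RMSE
  (across questions and resamples) is at or below the supervised mean RMSE
  at the largest budget, reported as a percentage of that largest budget;
  the multi-subject study reports the median over subjects.
* **Win rate** — the fraction of paired cells with strictly lower SSL RMSE
  (ties count as non-wins).
* **Stability** — the fraction of (subject, question, budget) cells in which
  the SSL arm's RMSE spread (sd across resamples) is at most the supervised
  arm's; budgets equal to the whole pool are excluded since all draws
  coincide there.

Model-initialization and fit seeds are derived from
(subject, question, budget) only, so the five resamples differ *only* in
which windows were drawn — spread across resamples measures sensitivity to
the labelled sample, not to initialization. When the budget equals the pool
size, all draws coincide and the run is computed once.

## Numerical and degenerate-input choices

* 0-based half-open indexing everywhere; window starts are multiples of the
  stride.
* A flat recording min–max-scales to the constant 0 rather than erroring.
* `floor(n × fraction)` test-set sizing; splits, draws and inits all come
  from explicit 31-bit seeds derived by CRC-32 from structured keys.
* Signals too short for one window yield empty results, not errors; truly
  invalid configurations (non-positive durations, out-of-range Likert
  values, budgets exceeding the pool) raise a validation error naming the
  field.
* The biexponential kernel with equal time constants falls back to its
  analytic limit `(t/τ)·e^{1−t/τ}`.

## Known limitations

* The NumPy engine is CPU-only and single-threaded; it is sized for this
  package's architectures, not a general DL framework.
* Random-mode splits with overlapping windows leak raw samples between
  train and test (by design, for protocol parity); use block mode for
  leakage-free estimates.
* The label-conversion targets assume the four Likert levels are equally
  spaced.
* Per-subject, per-question heads do not share downstream statistical
  strength across questions.
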
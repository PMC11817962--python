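# Methods

This note records the model, the numerical conventions, and the design
choices behind `medetect`, in the spirit of the methods documentation that
simulation and statistics packages keep alongside their API reference.

## Encoding model

Events occur at times `t_s ∈ [0, T]` with classes `s ∈ {0..S−1}` (one-hot at
the math boundary). Each channel owns a finite-support temporal response
`r(t)` sampled on the recording lattice (bin width Δ, default 1 ms) and a
spatial response `φ ∈ ℝ^S`.

* **Spike channels** are inhomogeneous Poisson: `log λ(t) = α + Σ_e r(t −
  t_e) φ[c_e]`. Multiple events superpose **additively in the log-rate**;
  the single-event likelihood is `e^{−Q} Π_m λ(t_m)` with `Q = ∫ λ`.
* **Field channels** are `y(t) = Σ_e r(t − t_e) φ[c_e] + w(t)`, `w ~ N(0,
  σ²)` i.i.d. per bin; superposition is additive in the mean.
* Channels are conditionally independent given the events, so joint
  log-likelihoods add across channels.

Discretization conventions: `Q` is a left-Riemann sum on the bin lattice;
spikes are Bernoulli per bin with probability `min(λΔ, 1)` (valid for `λΔ ≪
1`; the simulator logs a warning above 0.5); event times snap to the nearest
bin center; class labels are 0-based integers internally. Rates are clipped
at 1e−12 spikes/s before logs; likelihoods accumulate in double precision.
Gaussian likelihoods are evaluated over **all** samples of the recording —
the constant terms cancel in every argmax the detector performs.

No spike-history (refractory/self-exciting) terms and no autocorrelated or
non-Gaussian field noise are modeled; the field noise is assumed stationary.

## Detector

Maximizing the joint log-likelihood over `(t_s, s)` is implemented as `S`
matched-filter traces (see README for the formula). Implementation details:

* Convolutions are zero-padded at the boundaries; within one kernel support
  of either recording edge the time-invariance of the offset terms (`Q` and
  the template energy) fails, so detections there carry `edge=True`.
* `Q(s)` and the Gaussian energy are computed once per class, not per bin,
  using the assumption that the kernel support is far shorter than `T`.
* Exact argmax ties across classes resolve to the lowest class index
  (deterministic); evaluation utilities can instead randomize ties where a
  chance-level analysis requires it.
* Peak picking is greedy non-maximum suppression: local maxima of `x(t)` at
  or above threshold, accepted in descending height with a minimum
  separation (default 0.2 s, matching the evaluation tolerance; set 0 to
  disable). `auto_threshold` offers an Otsu split of the peak-height
  distribution for thresholded runs; ROC evaluation is threshold-free.
* Causal mode delays every trace by the largest kernel right edge `t2` so
  each output sample uses only past data; reported times subtract the delay.

With `k = 1` and supports interior to the recording, trace differences equal
exact joint log-likelihood differences; the test suite asserts this to 1e−6
on dense candidate grids (observed agreement ~1e−12).

## Synthetic data

The generator emulates a saccade-style experiment and fixes the study
conditions used by the test suite and the acceptance script: 5 spike + 5
field channels, 8 classes, 20 events by default, inter-event gaps uniform on
`2 ± 0.5` s, spike rates from a 10 Hz baseline to a 100 Hz preferred-class
peak, field SNR 0.1 at unit noise variance, Δ = 1 ms, and 1 s of quiet pad
before the first and after the last event so kernels stay interior. Choices
the data do not pin down, made once:

* **Spatial tuning** is cosine, `φ[c] ∝ (1 + cos(2π(c − c_pref)/S))/2`, the
  standard directional model; arbitrary `φ` can be supplied directly.
* **Temporal responses** are unit-L2 Gaussian bumps on `[0, 0.3]` s with
  latency uniform in `[0.08, 0.2]` s and width in `[0.02, 0.05]` s.
* **SNR definition**: mean of the squared preferred-class response over the
  kernel support divided by σ². Gains solve the rate span and SNR targets in
  closed form.
* **Gap jitter** is uniform (the distribution is otherwise unspecified).
* Seeding: one master seed; each channel consumes its own spawned child
  stream, so channel subsets are bit-reproducible regardless of how many
  channels are simulated.

What the generator does **not** emulate: task structure (fixation/delay/go
epochs), spike-history effects, autocorrelated or non-stationary field
noise, cross-channel noise correlations, and electrode artifacts. Passing
tests therefore demonstrate correctness of the estimator under its own
model class, not robustness to the full statistics of real recordings —
that is what the cross-modal scale `k` partially absorbs on real data.

## Parameter learning

Fitting is per channel, from event-aligned epochs (default window `[0, 0.3]`
s; epochs that leave the recording or overlap a previous epoch are dropped
with a warning) plus the event-free baseline:

* **Field channels.** The ML per-class template under the Gaussian model is
  the event-triggered average. The time × class matrix of averages is
  factorized to rank one by SVD; σ̂² is the residual variance of the epochs
  around the rank-1 predictions pooled with the baseline samples (floored at
  the smallest positive double so noise-free inputs stay valid).
* **Spike channels.** `α̂ = log(baseline spikes / baseline duration)`.
  Per-class PSTH rates are smoothed (Gaussian kernel, σ = 10 ms), floored at
  0.5 spikes/s, logged, baseline-subtracted, and factorized rank one. An
  optional refinement (default on) then runs alternating damped-Newton
  ascent of `(r, φ)` on the per-bin Poisson likelihood of the smoothed
  counts, with a 2% pseudo-exposure at the baseline rate; each step
  backtracks until the objective does not decrease, and iteration stops when
  the gain falls below 1e−6. The smoothing and shrinkage exist because the
  raw-count ML is ill-posed whenever a bin collects zero spikes in every
  class — its log-rate coordinate diverges to −∞, which at moderate trial
  counts destroys the estimate (we measured temporal-response correlation
  collapsing from 0.99 to ~−0.1 at 50 trials/class without them).
* **Scale convention.** `r φᵀ` is scale-ambiguous, so `‖r‖₂ = 1` with the
  largest-magnitude element positive, scale absorbed into `φ`.
* **Cross-modal scale.** `k` is grid-searched (default 25 log-spaced points
  on `[1e−3, 1e3]`) on the *training* recording, maximizing detection AUC
  plus classification accuracy; exact ties break toward the value closest
  to 1 (unbiased fusion). When the fields are uninformative the objective
  plateaus for all sufficiently small `k`, and the tie rule then returns
  the largest value on the plateau — still well below 1.

Recovery under the study conditions with 500 events/class: temporal-response
correlations ≥ 0.99 for both modalities, σ̂² within ~0.2%, baseline rates
within ~1% (computed by `tests/test_acceptance.py` and
`medetect.experiments.recovery_experiment`).

## Evaluation

* **Tolerance-window ROC/AUC.** Every local maximum of `x(t)` is a
  candidate. Detection opportunities are windows of width `2·tol` (default
  tol = 0.2 s): one centered on each true event, scored by its tallest
  peak, and full-width control windows tiled inside the event-free
  complement of the timeline (fragments shorter than one window are
  discarded), scored the same way. Sweeping the threshold over the peak
  heights gives TPR (fraction of event windows above threshold) and FPR
  (fraction of control windows above threshold); AUC is the trapezoid area.
  This symmetric windowed construction is what pins the chance level at
  0.5: on a recording with no event-related signal the two window-max
  distributions are identical by stationarity. Constructions that label
  individual peaks by greedy matching instead measure the maximum of
  several exchangeable noise peaks per event window and inflate the null
  AUC well above 0.5 (we measured ~0.8), which would make "chance level"
  uninterpretable.
* **Classification accuracy** is, by default, the fraction of true events
  whose matched detection (greedy one-to-one, descending score — so one
  event can never be claimed by two detections) carries the correct class;
  a threshold-free "at truth" mode instead reads the argmax class at the
  trace peak inside each true event's window, with optionally randomized
  tie-breaking.
* **Timing NRMSE** is the RMS of (detected − true) times over matched
  events, normalized by the tolerance, so 1.0 means errors at the matching
  edge. Unmatched events are excluded from NRMSE (they already penalize
  TPR and accuracy).
* **Channel-count sweep.** Channel orders are shuffled (default 10×); every
  `(n_spike, n_field)` prefix sub-model is evaluated and summarized as
  mean ± SEM, with percent multimodal-over-unimodal improvement computed as
  `100·(multi − uni)/uni`. No hypothesis-testing machinery is included.

## Problem sizes

The default test suite and the acceptance script use desk-scale versions of
the study conditions chosen once for statistical adequacy: 400–800 events
for the chance-accuracy anchor (binomial SE ≤ 0.017), 10–20 seeds × 60–100
events for the null-AUC anchor, 50 events at SNR 10 for the perfect-detection
anchor, 500 events/class for parameter recovery, and 20 replicates of the
20-event condition for the fusion comparison.

## Known limitations

* The Bernoulli-bin spike approximation degrades when `λΔ` approaches 1;
  with the default 100 Hz peak at 1 ms bins, `λΔ ≤ 0.1`.
* `k` is selected on the same data used to fit the templates (no inner
  split); on real data with strong model mismatch a held-out split may be
  preferable.
* The detector assumes isolated events: trace values near two events closer
  than one kernel support reflect superposed responses that the single-event
  score does not model.
* Edge detections (`edge=True`) have attenuated matched-filter responses
  and slightly misspecified offset terms; downstream analyses may drop them.
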
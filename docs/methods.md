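# Methods

## Data model and preprocessing

The unit of analysis is the household-day. Raw input is a 5-minute grid of
binary activations, one column per PIR sensor (8 by default; consumer
thermostat bases support up to 32). Each calendar day is summarised as 48
half-hour motion states; a window is motion-positive when the summed
activations over its 6 steps and all sensors reach 4. This single sum rule
covers both intuitive triggers — one sensor active for 20 of 30 minutes, or
four sensors active in one 5-minute step each — and deliberately ignores
which sensor fired (sensor locations are typically unlabelled in donated
thermostat data).

Aggregation windows are aligned to clock half-hours, not sliding. A day is
*present* only if all 288 five-minute rows exist; days with fewer rows are
dropped and logged, because the model consumes only complete 48-slot
sequences. Blank/NaN sensor entries inside a present row are read as 0
(absence of a report is treated as no detected motion; no imputation rule is
attempted). Cohort inclusion mirrors a realistic deployment filter: at least
8 sensors, at least 355 days online in the year, at most 4 occupants when
occupancy metadata exists.

## The sequence model

Days are modelled as exchangeable draws from a household-specific generative
model, a variational autoencoder with recurrent encoder and decoder:

* encoder: 2 LSTM layers × 100 units (tanh), final hidden state mapped by two
  linear heads to μ_x and log σ²_x of a diagonal Gaussian posterior over a
  7-dimensional latent;
* sampling: z = μ_x + σ_x ⊙ ε, ε ~ N(0, I) (reparameterization);
* decoder: z repeated across the 48 steps, 2 LSTM layers × 100 units, a
  per-step linear head with sigmoid giving slot-wise motion probabilities.

The loss is mean per-slot binary cross-entropy plus the closed-form
KL(q(z|x) ‖ N(0, I)) plus an L1 penalty (weight 0.001) on the encoder LSTM
weight matrices. The KL weight is 1 throughout (no annealing). Optimisation
is Adam (learning rate 0.001, decay 0 by default, both exposed), mini-batch
7, 200 epochs by default, day order reshuffled each epoch from the config
seed with the final short batch kept.

Choices worth making explicit:

* **Bernoulli likelihood.** The output nonlinearity is a sigmoid and the
  reconstruction error is binary cross-entropy — the canonical likelihood for
  binary slot data. Probabilities are clipped to [1e−7, 1−1e−7] when a BCE is
  computed from probabilities; training itself uses the logit form, which
  needs no clipping.
* **Per-day loss is the mean over 48 slots**, not the sum, so scores are
  comparable across sequence lengths and configurations; the anomaly
  threshold below is quantile-based and invariant to this monotone choice.
* **L1 on the encoder only**: both encoder layers' input and recurrent
  kernels; biases are exempt.
* **Implementation**: the LSTM cells (standard i/f/g/o gating), BPTT and Adam
  are written directly on float64 NumPy and kept single-threaded, which makes
  every forward and backward pass bit-reproducible under a seed. The
  backward pass is pinned by a finite-difference gradient check in the test
  suite. Input kernels use Glorot-uniform initialisation; recurrent kernels
  are block-orthogonal (one orthogonal block per gate) with forget-gate bias
  1 — the initialisation scheme popularised by mainstream deep-learning
  libraries, which in our experiments is what lets boundary slots (the
  1→0 transition at sleep onset) converge within a 50-epoch budget.

## Anomaly detection

A day's anomaly score is its reconstruction loss using one reparameterized
posterior sample (n_mc = 1, seeded; exposed for variance reduction). The
flagging threshold is median(scores) + (P75 − P25), computed with
linear-interpolation quantiles on the scored set itself, and the comparison
is inclusive (score ≥ threshold ⇒ anomalous). With fewer than 4 scores the
quantiles do not serve the rule's intent and an error is raised. Note the
degenerate corollary, which the tests assert rather than hide: if all scores
are equal, the threshold equals them and every day is flagged.

Per-household validation reports the Table-style row: abnormal days, total
observed days, mean reconstruction loss, the ROC AUC of per-slot
reconstruction probabilities against observed slot states pooled over all
(day, slot) pairs, and the number of flagged days falling on weekends. A
single-class validation set yields an undefined (None) AUC, not an error.

## Behavioural indicators

The regular activity pattern is the day-averaged reconstruction with
z = μ_x (posterior mean, no sampling noise), binarized at 0.5 — the
lowest-variance summary of the model's habitual template. Sleep is the
longest *circular* run of zeros in the binary pattern, because sleep
typically spans midnight; ties prefer the run covering 03:00 (slot 6), then
the earliest start. Sleep time is the slot opening that run, wake time the
slot after it, duration 30 min per slot. All-ones or all-zeros patterns give
undefined sleep parameters.

Minutes at home are 30 × motion-positive slots. Whether sleep counts as
at-home is genuinely ambiguous, so both modes exist and outputs label which
was used: `motion` (raw days; default) and `motion_or_sleep` (adds the
nightly run of a regular pattern). The weekend-vs-weekday contrast is a
two-sided Mann–Whitney U on per-day minutes (robust to the non-normal,
tie-heavy minute distributions); when every day has identical minutes the
test degenerates and (U = n₁n₂/2, p = 1) is returned by convention.
Weekday-specific templates retrain one model per day of week (seed offset by
the weekday index); subsets under 20 days are skipped with a warning.

## Synthetic households

The generator emulates what the pipeline assumes about real donated
thermostat data: k independent sensors firing with probability
`p_fire_active` per 5-minute step while occupants are active and
`p_fire_idle` while asleep/away, driven by a wake/depart/return/sleep
schedule with an optional weekend override (Saturday/Sunday; day 0 is
anchored to a Monday). Defaults are a working household — 8 sensors, wake
05:30, depart 09:30, return 16:30, sleep 22:30, 365 days,
p_fire_active = 0.2, p_fire_idle = 0.01. At those rates an active half-hour
window sums ≈ 9.6 activations (motion-positive with probability ≈ 0.99) and
an idle window ≈ 0.5 (false-positive rate ≈ 1e−3), i.e. clear but not
noise-free signal. Missing days are dropped whole (never partial), anomalous
days are corrupted as a block — `absence` (all-day idle), `insomnia` (night
slots active), `shifted` (schedule rotated by 6 slots by default) — and
labelled, and cohort members get one shared schedule offset drawn from ±2
slots plus independent child seeds.

Not emulated: sensor-location semantics and spatial correlation between
sensors, multi-occupant disaggregation, partial-day outages,
daylight-saving artefacts, and any dependence of firing rates on occupant
count. Passing tests therefore demonstrate recovery under schedule-driven,
conditionally independent firing — not robustness to correlated sensor
faults or gradual behavioural drift.

## Problem sizes and numerical choices

Training at the full default configuration (365 days × 200 epochs) is the
production setting; the test suite and the acceptance script use the same
architecture at 50 epochs on one household-year (and 12-unit models for
small unit-level recovery checks), sizes at which all recovery properties
already hold. Quantiles are linear-interpolation; scores, thresholds and
flags are float64; training aborts with the epoch named if the loss becomes
non-finite; `epochs = 0` returns the initialised model with an empty
history. End-to-end pipeline runs are byte-deterministic for a fixed config
and seed.

## Known limitations

* The median+IQR rule always flags the upper tail — on a household with no
  genuine anomalies it still marks ~15–25% of days; it is a triage rule, not
  a calibrated test.
* One model per household; no pooling, so cold-start households with few
  days are out of scope (the inclusion filter enforces this).
* The latent often carries little information for single-schedule households
  (the KL term collapses toward 0 and the decoder reproduces the mean
  pattern); this is harmless for anomaly scoring and pattern extraction, but
  the latent space should not be over-interpreted.
* Reconstruction-probability AUC conflates model fit with day-to-day
  behavioural variability; low AUC can mean either a poor model or an
  irregular household.
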
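# Methods

This note documents the models, defaults, and design choices behind
`pansense`, and what the synthetic conditions do and do not establish.

## Network model

The PAN is a star: one main node that always classifies locally, and up to
three supporting nodes that classify locally and report `(class, weight)`
over a single hop. The channel is abstracted away — a transmission either
arrives within the step or the node is marked failed; there is no radio,
latency, battery, or multi-hop model. Suppression percentage (avoided
transmissions over the supports × steps budget) is the energy proxy.

One simulation step is one classification window; the step duration is the
window span. In streaming mode the main node overlaps collection and
processing, so the decision about window *t* is emitted during window
*t + 1*; an aligned mode (used for all offline accuracy evaluation) emits
decisions at their own step. The labels are identical in both modes.

### Vote

Only the top-1 `(class, weight)` pair per node enters the vote, and the
main node's vote is weighted exactly like a support's. Ties are broken by
the lowest class index; if the main node's own label is among the tied
leaders it wins. Tie-breaking is a deliberate, documented choice — any
deterministic rule works, and ties are measure-zero for continuous weights.

### Transmit-set optimisation

The greedy minimiser starts from full transmit sets, scans supports in
configuration order and activities in canonical order, and accepts a
removal when the ensemble **training** accuracy drops by at most ε.
After each accepted removal the accuracy baseline moves to the new value
and the scan restarts from the beginning (`restart_on_removal=True`;
disabling it continues in place, which is faster and usually equivalent).
Accuracy during optimisation is computed on aligned decisions — the
training stream has no delayed-emission semantics.

Because the baseline ratchets, the guarantee is cumulative:
`final ≥ baseline − ε · (accepted removals)`. With the default ε = 0.001 —
chosen small so that only outlier-level noise is tolerated — any removal
whose cost exceeds one misclassified window in a thousand is rejected.
When ε is below the accuracy quantum (one over the number of training
windows), accepted removals are exactly cost-free and the greedy result
also satisfies the one-shot constraint an exhaustive minimiser enforces;
the test suite exploits this to compare greedy against enumeration on tiny
instances. Greedy is not guaranteed size-optimal, only feasible.

Only supporting nodes' sets are optimised; the main node always votes.

### Expected suppression

`100 · (1 − flags_on / (8 · n_supports))`, rounded half-up to an integer
(62.5 → 63). The quantity assumes every activity occupies equal time and
local recognition matches the truth; the simulator's oracle-classifier mode
reproduces it exactly on balanced streams, which pins the simulator's
transmission accounting to the closed form. With realistic classifiers and
optimised sets, observed suppression is typically higher, because supports
rarely recognise (and hence report) classes outside their transmit sets.

## Preprocessing

Fixed order: trim → resample → gravity split → windowing.

* **Trim**: drop `floor(0.02·T)` samples from each end of a session
  (preparation/stop phases).
* **Resample**: block-average decimation from the 100 Hz raw rate to
  F ∈ {5, 10, 20} Hz (default 20). Integer-stride averaging doubles as the
  anti-alias filter and preserves constants exactly; non-divisor rates are
  rejected with the nearest valid suggestion.
* **Gravity split**: per accelerometer channel,
  `g_t = α g_{t−1} + (1−α) a_t`, `g_0 = a_0`, body = `a − g`. The
  reference constant is α = 0.9 at 20 Hz (time constant ≈ 0.5 s). Across
  rates the per-second pole is held fixed: `α(r) = 0.9^(20/r)`, i.e. the
  exponent scales with the *reference-to-target* rate ratio so the cutoff
  frequency is rate-invariant.
* **Windows**: WS ∈ {64, 128, 196} samples (default 64), 50% overlap by
  default (the convention of the windowing literature the defaults follow;
  exposed as a flag), trailing partial window dropped.
* **Split**: 80/20 by *session*, stratified by activity, deterministic per
  seed. Window-level splitting would leak through overlapping windows and
  inflate accuracy, so it is not offered.

## Classifier backends

* **light** (default): per-channel mean, standard deviation, energy, and
  dominant frequency (argmax of the non-DC rFFT magnitude, reported as
  0 Hz when the peak is below 3× the median bin magnitude — a flat
  spectrum has no meaningful dominant frequency, and reporting its argmax
  would inject uniform noise). Features are standardised and fed to a
  multinomial logistic layer (L2, C = 10). Deterministic given a seed;
  trains in well under a second at desk scale.
* **rnn**: LSTM(60) → dropout(0.5) → dense(60, relu) → softmax(8), trained
  with categorical cross-entropy and Adam (batch 64, ≤ 40 epochs, cap 50).
  Implemented as a compact numpy network with full backpropagation through
  time; the analytic gradients are checked against finite differences in
  the test suite. Dropout acts only during training: the inference-time
  softmax output *is* the node's voting-weight vector. Exact cross-platform
  bit-reproducibility of trained recurrent weights is not promised; tests
  involving this backend assert contracts and ranges, not exact values.

Both backends consume 6 channels (3 body-acceleration + 3 gyroscope); the
three gravity channels can be appended via the preprocessing API if a
deployment wants posture information in the classifier.

## Synthetic data generator

Each `(activity, position)` pair is a sum of 1–3 sinusoidal harmonics
(relative strengths 1 / 0.4 / 0.15) of an activity base frequency, a
constant 9.81 m/s² gravity vector in a mount- and posture-specific
orientation, and white Gaussian sensor noise. Base frequencies: walking
1.8 Hz, jogging 2.8 Hz, squats 0.7 Hz, jump 1.2 Hz, arm swings 1.0 Hz;
static postures 0 Hz. Sessions draw shared per-session phase, ±5%
frequency and ±10% amplitude jitter (so splits are non-trivial), shared
across positions to emulate four devices worn during the same bout; sensor
noise is drawn per device. Raw sampling is 10 ms.

The amplitude and noise tables are position-structured on purpose, so each
mount has a realistic blind spot: the waist barely sees squats and jumps
(its most-confused pair — they share a channel profile there and only the
base frequency separates them, at low SNR); the leg barely sees arm swings
(standing-like energy); the arm cannot separate sitting from standing; the
chest's static-posture noise levels are close together. Every class is
still covered well by at least two positions, which is the regime where
the weighted vote pays off. Static postures carry no oscillatory content
and are distinguished by their noise-magnitude signatures alone.

What the generator does **not** emulate: biomechanics (no joint or
soft-tissue models), non-stationarity within a session, transitions
between activities, device orientation drift, or real inter-subject
variability. Passing tests therefore establish that the *method* —
windowing, voting, suppression, optimisation, simulation — behaves
correctly and reproduces the combinatorial suppression surface, not that
any particular absolute accuracy transfers to recorded data.

## Scales and defaults

* Desk scale (tests, CLI defaults): 10 sessions × 24 s per activity and
  position, seed 42 → 2 080 windows per position at 20 Hz / WS 64, split
  80/20 by session. Chosen so the full suite runs in seconds while leaving
  every contract (≥ 90% waist single-node accuracy, ensemble ≥ best
  single, positive suppression) comfortably testable.
* Experiment scale (`experiment_scale_plan`): seven 2-minute sessions per
  activity plus one 99 s walking session; through the standard pipeline
  this yields 16 136 windows across the four positions, the scale of the
  reference acquisition campaign the generator emulates.

## Known limitations

* The suppression metric assumes balanced activity durations; skewed
  usage shifts realised suppression (usually upward, as rare training
  activities dominate the transmit sets).
* The greedy optimiser's scan order (configuration order × canonical
  activity order) is deterministic and documented but can change which of
  several equally-feasible minimal sets is found.
* The numpy recurrent backend is CPU-bound and intended for
  fixture-scale training and smoke testing, not for large corpora.
* `brute_force_minimum_sets` is a test oracle only (≤ 2 supports,
  ≤ 4 classes); it does not scale and is not part of the method.
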
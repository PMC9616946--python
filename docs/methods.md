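# Methods

`headernet` reproduces, end to end, a surveillance pipeline for purposeful
soccer headers measured with a skin-mounted behind-the-ear head-impact
sensor: simulation of triggered sensor events, construction of
video-verified ground truth, class-balanced preparation, a bidirectional
LSTM classifier, and an evaluation harness that compares the network with
simple acceleration-threshold rules under realistic class imbalance.

## Sensor model and simulator

The emulated device records tri-axial linear acceleration (anterior–
posterior, left–right, inferior–superior) at 1000 Hz.  When the resultant
acceleration exceeds a trigger threshold (default 8 g), a 100 ms window is
stored: 10 ms pre-trigger, 90 ms post-trigger.  Every simulated trace obeys
the trigger invariant — the resultant first reaches the threshold exactly
at sample index 10 and stays strictly below it over the ten pre-trigger
samples; the sub-threshold onset of the impact pulse extends into the
pre-trigger window, as on the physical device.  The resultant (not any
single axis) drives the trigger, the usual device convention.  Gravity is
not modelled; traces are dynamic acceleration only.

**Headers** are single smooth raised-cosine resultant pulses.  Peak
magnitudes follow a log-normal distribution with median 15 g and log-s.d.
0.28, truncated to [8, 60] g; the spread was fixed so that about 6% of
header peaks fall in the 8–10 g band, matching how strongly real header
magnitudes concentrate just above the trigger.  Pulse durations are uniform
on 6–14 ms.  The pulse direction is a unit vector dominated by the
anterior–posterior axis with Gaussian off-axis jitter (s.d. 0.3).

**Spurious events** (ball strikes to the body, jumps, knocks on the
sensor) come from a three-archetype mixture — narrow spike (< 3 ms FWHM),
damped 50–150 Hz ringing, and 2–4 irregular raised-cosine bumps — with
default weights 0.4 / 0.3 / 0.3.  Their peak magnitudes follow a
two-component log-normal mixture (medians 5.8 g and 25 g, weights
0.967 / 0.033, truncated below by the trigger), chosen so that roughly 43%
of retained spurious peaks exceed 10 g and 14% exceed 16 g — the
exceedance pattern that makes simple amplitude thresholds perform as
poorly as they do in the field.

Whole **sessions** add the bookkeeping around the waveforms: two 45-minute
halves, a roster of 14 with 11 on the pitch and random second-half
substitutions, ~39 scheduled headers per match, an 11% sensor miss rate
(headers that stay below the trigger), about 21 in-match on-pitch spurious
events per captured header, and out-of-match / off-pitch spurious events at
configurable rates.  Sensor timestamps carry Gaussian jitter (s.d. 0.5 s)
against the video clock, truncated inside ±2 s.  Two constraints keep the
synthetic truth table exactly recoverable by the matching stage: headers of
the same player are at least 4 s apart, and in-match spurious events stay
more than 4 s from that player's headers.  Real data offer no such
guarantee; the matching stage is therefore tested separately on dense
ambiguous clusters.  Identical seed and configuration reproduce a session
bit-identically.

What the simulator does *not* emulate: biofidelic skull/neck dynamics,
rotational-velocity channels, helmeted-impact waveforms, the vendor's
proprietary event classification, and the long tail of waveform diversity
in real spurious events.  Passing benchmarks on this generator demonstrates
that the pipeline's machinery is correct and that the network can learn
shape-based discrimination at realistic imbalance — not that the trained
weights would transfer to any physical sensor.

## Ground truth

Labeling mirrors the field procedure: discard events outside verified
match times (closed half intervals; an event exactly on a boundary is
inside), discard events from players not on the pitch, then match the
remainder to the video header log.  A sensor event and a video header match
if they share player and session and differ by at most 2 s.  Multiplicity
is resolved by a globally greedy one-to-one assignment by ascending |Δt|,
with ties broken by earlier sensor timestamp and then event id — the
result is deterministic and independent of input order.  Matched events
are valid headers (VH), retained unmatched events are non-headers (NH),
and video headers with no sensor partner (sub-threshold headers) are
dropped and counted.  Every stage conserves counts; the labeling report
enforces `retained = VH + NH` and `raw = retained + removed`.

## Preparation

Traces are z-normalized per event and per axis (mean 0, s.d. 1, population
convention), which makes classification invariant to per-event amplitude
rescaling — classification should rest on waveform shape, not magnitude.
A constant axis cannot be normalized and is reported as degenerate rather
than silently coerced.

The ~1/21 class imbalance is corrected by augmentation before
normalization: a uniformly drawn header trace is duplicated and unit-
variance pink (1/f) noise, scaled by σ = 10% of the raw copy's per-axis
standard deviation, is added independently per axis, until the classes are
balanced.  Pink noise is generated by spectral shaping — white Gaussian
noise transformed to the frequency domain, amplitudes multiplied by
f^(−1/2), DC bin zeroed, inverse-transformed and normalized to unit sample
variance; its average periodogram slope over the central frequency decade
is −1.  Noise is added to the *raw* trace (adding it after normalization
would be equivalent up to the rescaling that normalization removes).
Augmented events carry a flag and are never placed in the test partition.

Datasets are split 49% / 21% / 30% (train / validation / test), stratified
by label.  Per label, the test count is the floored test fraction (so 904
headers give a 271-header test partition and 19,145 non-headers give
5743), validation is floored next, and the remainder trains.

## Network and training

Architecture: sequence input (3 × 100) → bidirectional LSTM with 100
hidden units per direction, taking the final forward and backward hidden
states (200 values) → fully connected hidden layer (width tunable in
[20, 100]) → linear output map to the two classes → softmax.  The two
stacked fully connected layers have no interposed activation, matching the
usual sequence-classification layer stack.  The loss is mean cross entropy
over the softmax outputs plus an L2 penalty λ·Σw² on weight matrices only
(biases exempt).  Initialization is Glorot-uniform per matrix with
forget-gate biases at 1, seed-controlled.

The optimizer implements the moving-average recurrences

    m_l = β₁ m_{l−1} + (1 − β₁) ∇E(θ_l)
    v_l = β₂ v_{l−1} + (1 − β₂) [∇E(θ_l)]²
    θ_{l+1} = θ_l − α m_l / (√v_l + ε)

with β₁ = 0.9, β₂ = 0.99, ε = 1e−8 — deliberately *without* the
bias-correction terms of standard Adam, because this uncorrected form is
what the recurrences above state; a config switch (`bias_correction`)
restores the standard variant.  Training runs 3 epochs of shuffled
mini-batches and is bit-reproducible given the config seed.

Because the per-parameter step of this update never anneals (in steady
state it approaches α times the sign of the smoothed gradient), the last
iterate is not systematically the best one.  The trainer therefore probes
the validation loss every `val_check_steps` updates (default 5) and at
each epoch end, and returns the best checkpoint.  The validation partition
exists exactly for such model selection; the per-epoch history is reported
unchanged.

Reference defaults (`TrainingConfig()`): learning rate 0.168, mini-batch
119, L2 factor 0.0016, 43 fully connected nodes — the configuration tuned
on a full-scale (~20k event) campaign.  These are appropriate at that data
scale; the desk-scale benchmark below supports far fewer optimizer steps
and uses its own tuned values.

## Hyperparameter tuning

`classifier.tune` performs Bayesian optimization over the 4-dimensional
box: learning rate 1e−2–1 (log), mini-batch 64–128, L2 factor 1e−8–1e−1
(log), fully connected width 20–100.  A Gaussian-process surrogate
(Matérn 5/2 kernel on the unit-scaled box, observation noise 1e−4) is fit
to the observed validation errors; each proposal maximizes Expected
Improvement over a 512-point random candidate pool.  The default budget is
40 evaluations after a 5-point random initial design — a deterministic,
hardware-independent stand-in for a wall-clock budget.  The configuration
with the lowest observed validation error is returned; proposals never
leave the box.

## Evaluation

Metrics are sensitivity, specificity, precision, accuracy and F1 in their
standard ratio forms; a zero denominator yields an explicit
undefined flag (rendered `n/a`), never 0.  Reports print percentages
rounded half-up to one decimal.

"Fivefold cross validation" over a 49/21/30 split is implemented as five
independent stratified random re-partitions (not five rotating disjoint
folds, which a 30% test share cannot produce): each fold freshly
partitions, augments train and validation only, trains a new network from
a fold-specific seed and scores all methods on the identical test
partition.  The balanced scenario subsamples test non-headers down to the
header count; the unbalanced scenario uses the full ~1/21 test partition.
Headline numbers are means of per-fold metrics; pooled metrics computed
from summed counts are reported alongside (the two conventions differ
slightly and both are legitimate summaries).  Amplitude-threshold
baselines label an event a header when the raw peak resultant exceeds
10 g or 16 g; they are deterministic given the test partition.

## Reference synthetic benchmark

The desk-scale benchmark (`headernet.benchmark`) is one simulated session
with 50 scheduled headers and ~1/21 imbalance — about 1000 retained
events — evaluated with 5-fold re-partitioning in both scenarios.  Its
training configuration (learning rate 0.0119, batch 78, L2 0.0235, 56
hidden nodes) was selected once by this package's own Bayesian tuner on an
independently seeded synthetic tuning dataset of the same shape — with
the tuning objective averaged over three training seeds, since a
single-run validation error at this data scale is noisy enough to favour
lucky unstable configurations — and then frozen.  At ~900 balanced
training events the optimizer takes an order of magnitude fewer steps
than a full campaign, so the selected learning rate sits near the bottom
of the search box rather than at the full-scale optimum.  Each fold's
test partition holds only ~13 headers, so a single misclassified header
moves fold sensitivity by almost 8 percentage points; fold-averaged
metrics at this scale carry seed-to-seed variation of several points.  The study-scale generator (26 sessions, ~44k raw events) is used
for bookkeeping quantities only (capture rate, raw precision, class
ratio); no network is trained at that scale here.

## Numerical and design choices

* Trace serialization uses 17 significant digits, making text round-trips
  bit-exact for doubles; readers parse with round-trip float precision.
* All schedule intervals are closed; timestamps are decimal seconds since
  session start (world-clock synchronization is upstream of this package).
* Matching with window → 0 degenerates to exact-time hits; negative
  windows are rejected.
* The trigger-alignment contract is enforced by construction (envelope
  shifting) plus rejection of noise draws that would break it.
* σ = 10% augmentation noise is interpreted relative to the per-axis raw
  standard deviation; alternatives (10% of peak, 0.1 g absolute) would not
  be amplitude-invariant under z-normalization.
* Degenerate inputs fail loudly: constant axes, empty datasets, classes
  missing from a scenario, non-finite gradients.

## Known limitations

* The BiLSTM runs on plain numpy; it is fast enough for the benchmark
  scale (seconds per fold) but not intended for campaign-scale training.
* The spurious-event archetypes are plausible stand-ins, not measured
  waveforms; conclusions about absolute classifier performance on real
  sensors cannot be drawn from the benchmark.
* The vendor's proprietary event filter is out of scope; no surrogate for
  it is provided.
* Rotational-velocity channels are not modelled.
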
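# Methods

This note documents the model, the defaults and the design decisions behind
`emgdqn`, including the places where the design was genuinely open and what
this package chose.

## Problem and data model

A recording is an 8-channel surface-EMG signal at 200 Hz (default length
T = 1000 points = 5 s) with a per-point binary mask marking where the
muscle is active, plus a gesture label from {fist, waveIn, open, waveOut,
pinch, relax}.  Models are user-specific: every user supplies a train/test
split and a few `waveOut` synchronization recordings used only to normalise
armband orientation.

## Front end

**Segmentation.** Windows of `length = 300` points, `stride = 40`
(0-based, half-open spans); a sample of T points yields
⌊(T−300)/40⌋+1 windows.

**Energy gate.** A window is "active" iff its energy (sum of squares over
channels and points) is at least 18% of the maximum window energy *within
the same sample* (inclusive comparison; an all-zero sample has no active
window).  The reference quantity for the 18% threshold was an open choice;
per-sample maximum was picked because it is self-normalising across users,
gains and electrode impedances.  Inactive windows are replaced by the
all-zero observation.

**Orientation correction.** Per-channel energies are summed over all sync
samples; the dataset is circularly channel-rotated so the argmax channel
(ties → lowest index) lands at index 0.  A pure circular shift is used (no
direction reversal).  This makes the whole front end invariant to armband
rotation: the feature stream of any rotated copy of a dataset is
bit-identical after correction.

**Features.** Per channel of an active window: AE, E, RMS, STD, MAV in
that order, channel-major (ch0's five features, then ch1's, ...), 40 values
total.  STD uses the unbiased L−1 denominator.  AE has no standard closed
form; here it is the mean of the rectified signal after a centred 25-point
(~125 ms) moving average with truncated edges — a standard low-complexity
envelope, distinct from MAV because smoothing is edge-truncated before
averaging.  An analytic-signal (Hilbert) magnitude would be a reasonable
alternative; it was not chosen to keep the front end free of FFTs.

## Environment and rewards

Each sample is an episode; step t presents observation O_t (window t's
features) and the action is a gesture label.  A window's *true* label is
the sample's gesture when the window overlaps the mask by more than half
the window length (strict > L/2), else relax — a mask-majority rule, which
renders the truth at window resolution as faithfully as possible to the
point mask.

Rewards: +1 / −1 per correctly / incorrectly labelled window.  At the
final window the predicted label sequence is post-processed (below) and
compared with the truth; the terminal reward is the last window's ±1 plus
+10 if the overlap factor exceeds 0.75 (strict) *and* the dominant
predicted label equals the true gesture, else −10.  The additive
combination keeps per-window credit assignment intact at the terminal
step.  Requiring the dominant label to match prevents rewarding a
well-localised but wrongly-labelled span.

**Overlap factor.** ρ = 2|A∩B|/(|A|+|B|) (Sørensen–Dice), where A is the
set of points carrying the dominant non-relax predicted label and B the
set of non-relax truth points; ρ = 1 when both sets are empty, 0 when
exactly one is.  Dice was chosen over Jaccard as the convention of this
evaluation lineage.

**Comparison resolution.** The truth vector that ρ is computed against is
the ground truth rendered through the same window→point expansion as the
prediction (window truths of active windows, expanded as below).  Both
vectors then live at the resolution the system actually operates at
(40-point stride, 300-point support), and an oracle policy that outputs
every window's true label attains ρ = 1 exactly.  Comparing against the
raw point mask instead would bound ρ strictly below 1 for *any* policy —
the energy gate admits windows overlapping a burst by only ~54 of 300
points, so spans rendered from windows systematically overhang the mask —
which would make the recognition reward unattainable regardless of the
agent's quality.  This is the one place where the natural-seeming
conventions genuinely conflict; the resolution above is the one that
preserves the oracle invariant.

## Post-processing

Window labels expand to points by "last active window covering the point
wins"; points covered by no active window are relax.  Majority voting then
replaces every label within the activity region by the modal non-relax
label (ties → earliest first occurrence) and forces relax outside it.  The
activity region handed to the vote is the non-relax support of the
expanded prediction itself, so voting homogenises the span's label but
never widens the span.  Voting is idempotent and leaves at most one
non-relax label.

**Metrics.** Classification: dominant label equals the true gesture (an
all-relax prediction is dominant relax; on a gesture sample that counts as
a misclassification).  Recognition: classified correctly *and* ρ > 0.75
(the same threshold as the training reward).  Recognition accuracy is
therefore bounded above by classification accuracy.

## Agent

**Architecture.** Feed-forward 40 → 50 → 50 → 6 with ReLU; the recurrent
variant inserts a 27-unit LSTM after the input followed by dropout
(keep = 0.8; the probability was unspecified, 0.2 drop is the usual
default), then the same dense stack.  Initialisation is seeded uniform
±1/√fan_in; the LSTM forget-gate bias starts at 1.

**Learning.** The update is a minibatch squared-error gradient step with
Adam (first-moment decay 0.9 = the "gradient decay factor", second 0.999,
L2 10⁻⁴ on weight matrices only), applied to the taken action's output
with targets held constant — the minibatch realisation of the classic
single-sample temporal-difference parameter update.  Defaults follow the
tuned operating point: γ = 0.99, buffer 10⁶, minibatch 64, 15 epochs per
user, α = 3×10⁻⁴ (the best validated learning rate).

**Exploration.** ε starts at 1 and decays multiplicatively per learn step,
ε ← max(0.01, ε·(1−5×10⁻³)); the per-step rule and the 0.01 floor are
package choices (per-step decay gives ~920 exploratory learn steps, a
small fraction of a 15-epoch run).

**Target network.** θ⁻ is soft-updated every τ learn steps
(`target_update_freq`, default 1): θ⁻ ← τ_s·θ + (1−τ_s)·θ⁻ with
τ_s = 5×10⁻³.  Gating the soft update by the frequency composes the two
constants (a pure hard copy every τ steps corresponds to τ_s = 1).

**Replay.** FIFO buffer, uniform sampling without replacement, one learn
step per environment step once the buffer holds a full minibatch.  The
recurrent variant uses episode-wise replay instead: whole episodes are
stored, and after each acted episode four BPTT updates are taken on
uniformly sampled episodes (hidden state resets at episode boundaries; the
dropout mask is shared across the time steps of an update — variational
dropout).  Episode-wise replay is the minimal scheme under which the
hidden state in the target computation is well-defined.

**Observation scaling.** The raw features span orders of magnitude
(E ≈ 300·amp² versus MAV ≈ amp), which stalls learning when targets have
magnitude ≤ 11 and per-parameter Adam steps are ≈ α.  The trainer divides
each observation dimension by its max-abs over the user's training windows
(a zero column divides by 1).  Scaling preserves the inactive-window zero
vector, is stored in the checkpoint, and is applied identically at
evaluation.

**Determinism.** A single seeded generator drives initialisation, epoch
shuffling, exploration, replay sampling and dropout, in a fixed order;
training runs are bit-reproducible, and checkpoints (networks, optimizer
moments, ε, counters, replay contents, generator state) resume
bit-compatibly at epoch boundaries.

## Synthetic data

The generator emulates the statistical structure the pipeline relies on:
8-channel baseline Gaussian noise (SD 0.05) with, for active gestures, a
white-noise carrier scaled per channel by a class-specific single-peaked
amplitude pattern (peaks on distinct electrodes, heights 0.9–1.1) and
shaped by a raised-cosine envelope (10% ramps).  Burst length is uniform
in 40–70% of the recording (sustained contractions over most of a 5 s
prompt window), onset uniform over the feasible range.  Ground truth is
exactly the burst support.  Default splits: 60 training / 30 test samples
per user, balanced over the six classes, plus 2 waveOut sync samples.

What it does *not* emulate: 1/f-ish EMG spectra and electrode filtering
(irrelevant here — all features are time-domain amplitudes), motor-unit
physiology, within-burst amplitude drift, inter-trial electrode shift, or
label noise in the masks.  Passing tests on synthetic users therefore
demonstrate that the learning machinery works when class information is
carried by channel amplitude patterns, not that real-world accuracy levels
are reproduced; real recordings are harder (overlapping patterns,
non-stationarity), and accuracy on real cohorts should be expected to fall
short of the near-perfect synthetic figures.

## Numerical choices and degenerate inputs

- Energy-gate comparison inclusive; all-zero samples have no active window.
- Argmax ties (actions, channels, vote modes) break deterministically:
  lowest index / earliest occurrence.
- Samples shorter than one window raise a segmentation error; synthetic
  T < 300 is rejected at configuration time.
- Dataset files store float32 rendered with 9 significant digits — exact
  round-trip, byte-deterministic writes.
- `alpha = 0` is accepted and performs a zero step (useful as an identity
  check); negative rates are rejected.

## Known limitations

- The recurrent variant learns far more slowly under this reward structure
  and typically underperforms the feed-forward agent; it is provided as a
  tested variant, not a recommended default.
- Resume is supported at epoch boundaries only.
- The per-user training loop is single-threaded numpy; a 60-sample,
  15-epoch run takes ~15 s on one CPU core, so large sweeps scale
  linearly.
- No import adapter for the public armband dataset distribution is
  bundled; `emg_io`'s documented text layout plus the synthetic generator
  cover the tested surface.
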
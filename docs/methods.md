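# Methods

This note documents the models and procedures implemented in `seegdecode`,
the defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions that matter for
reproducibility.

## Signal model and feature extraction

Recordings are multichannel voltage traces (µV) from depth leads (SEEG) or
surface grids (ECoG), with channel labels `<lead><contact>` (e.g. `LA3`).
Common-mode noise is suppressed by **bipolar derivation**: contact *i* minus
contact *i + 1* on the same lead. A lead with *k* contacts yields *k − 1*
pairs named `<lead>:<i>-<i+1>`; missing contacts are never bridged, because
bridging would widen the spatial extent of the derivation. For grids,
adjacency is interpreted as consecutive contacts within a row (row-major),
mirroring the within-lead chain.

Each bipolar trace is converted to **integrated amplitude features (IAFs)**:

- Non-overlapping **200 ms windows**, tapered with the classic Blackman
  window (a₀ = 0.42, a₁ = 0.5, a₂ = 0.08). Non-overlapping windows keep the
  transform cheap and make each window independently computable, which is
  what a real-time implementation needs. A trailing partial window is
  discarded.
- **Short FFT** per window; amplitude = modulus of the one-sided DFT. At
  200 ms the bin spacing is 1/0.2 s = 5 Hz.
- **Band integration**: bin amplitudes are *summed* (not averaged) over
  half-open intervals [low, high). The defaults are delta/theta [0, 10),
  alpha/mu [10, 15), beta [15, 30), gamma1 [30, 100), gamma2 [100, 500) and
  gamma3 [500, 5000) Hz; the widening gamma bands compensate the 1/f decay
  of power density so band amplitudes stay comparable. Half-open intervals
  resolve the shared edges (10, 15, 30, 100, 500 Hz appear in two bands
  each) without double counting, and summation makes band integration
  conserve total amplitude when the bands partition [0, Nyquist). The DC bin
  belongs to the lowest band, so slow evoked-potential energy appears in the
  delta/theta feature. A band at or above Nyquist is dropped (with a logged
  warning); a band straddling Nyquist is truncated to it.
- **1 s boxcar smoothing** of each band series, centered, with shrinking
  windows at the edges. Centering preserves response latency, which matters
  when trials are later correlated against a composite; a `causal` option
  averages only current and past windows for real-time parity.
- **z-standardization** per feature over all windows of the task, constants
  stored for the inverse transform. Zero-variance features are excluded and
  flagged rather than silently zeroed. Standardizing over the entire task
  means test windows contribute to the constants; `fit_windows` restricts
  the fit to the training partition for leakage-free evaluation. (Pearson
  correlation is invariant to per-feature affine maps, so the choice does
  not affect the repeatability metric itself.)

The order of operations is taper → DFT → band-integrate → boxcar →
standardize. The pipeline contains no randomness.

## Repeatability metric and feature selection

Evoked band responses during sustained movements are largely **phasic**
(transient) or **phasic-tonic** (transient plus a sustained plateau), with
trial-to-trial amplitude variation. Features useful for decoding are the
ones whose temporal shape *repeats* across trials, whatever that shape is.

For each cue class, each feature's windows are epoched from the cue onset
(snapped back to the latest 200 ms grid point at or before it, keeping the
grid uniform across trials) to **400 ms after cue offset** — a 4 s cue gives
22 windows. Trials are averaged into a **composite temporal response**; the
**mean correlation coefficient (MCC)** is the average Pearson correlation of
each trial's trace with the composite. Trials or composites with zero
variance are excluded from the average; a feature with no valid trial is
flagged invalid and can never be selected.

Two modes exist. `include_all` (default) lets each trial participate in its
own composite — the literal construction — which is optimistically biased
for small trial counts (a pure-noise feature with *n* trials has expected
MCC ≈ 1/√n). `leave_one_out` recomputes the composite without the scored
trial and removes the bias; the test suite asserts the bias direction
statistically.

Selection applies a rule per class and unions the passing sets across
classes (each class's cued period is scored separately, so the union is the
right aggregate for a multi-class decoder). Two rules are supported because
both have been used in practice: a strict threshold (`mcc > 0.6`, "moderate
correlation or better") and a closed range (`0.4 ≤ mcc ≤ 0.6`). The
threshold form is the default throughout this package; the range form is
available as `"0.4:0.6"`. Raising a threshold never enlarges the selection
(tested as a property).

## Decoders and evaluation

Every 200 ms window receives a label: 0 for rest, 1..K for cue classes,
where a cue's windows span its snapped onset to 400 ms past its offset.
Rest is an explicit class, so decoders predict during rest periods too.

- **SVM**: multi-class gaussian-kernel (RBF) SVM over per-window IAF
  vectors, one-vs-one. C and gamma are chosen by a small grid on contiguous
  training folds (defaults C ∈ {1, 10}, gamma = `scale`). The SVM is
  deliberately memoryless — no temporal stacking — because its contrast with
  the stateful LSTM is the point of the comparison.
- **LSTM**: a single-layer LSTM (64 hidden units by default) with a softmax
  readout at every timestep, implemented in NumPy and trained by
  backpropagation through time with Adam (learning rate 0.01, ≤ 200 epochs),
  global-norm gradient clipping at 5, and early stopping (patience 20) on a
  held-out fifth of the training sequences. Gradients are verified against
  numerical differentiation in the test suite. Three initialization choices
  matter:
  - forget-gate bias 1 (remember by default);
  - readout weights zero and readout bias at the log class priors, so the
    untrained network is exactly the class-prior predictor;
  - the untrained model competes in early-stopping selection, so on data
    with no learnable signal the decoder degrades to the majority-class
    predictor instead of an arbitrary noise fit.
  Sequences are cut at grid-snapped cue onsets (one cue-plus-rest block per
  sequence, a leading partial rest block kept as its own sequence). Aligning
  sequences to the task structure keeps the cue's position within a sequence
  identical across train and test; fixed-length chunking from the partition
  start is available as an option but lets the network learn
  position-in-chunk timing that does not transfer.

Evaluation uses a **contiguous train/test split snapped to a trial
boundary** (default 75 % train), so no trial contributes windows to both
partitions and test windows never influence training or selection (selection
uses only events wholly inside the training partition). The headline metric
is window-wise accuracy on test windows, reported as mean ± SD over
`n_repeats` re-trainings with fresh seeds on the same split; a trial-wise
majority-vote accuracy is also reported. (The variance source is re-training
randomness, not split rotation; the SVM is deterministic given the data, so
its SD is 0.) Chance level is the frequency of the majority test label. The
four-architecture grid — {SVM, LSTM} × {no selection, MCC selection} — runs
all cells on the same split with shared seeds.

## Synthetic recordings

The generator emulates a cued sensorimotor block task so the whole pipeline
is testable with known ground truth. Defaults describe the study conditions
used throughout the tests: 3 leads × 16 contacts at 2 kHz, two classes,
20 trials per class, 4 s cues alternating with 4 s rest (plus a lead-in
rest), class order randomized per seed. 2 kHz keeps desk-scale runtimes;
the gamma3 band is then truncated at the 1 kHz Nyquist, which mirrors
reduced-rate clinical recordings.

- **Background**: per-channel Gaussian noise with PSD ∝ f^(−2) (a typical
  intracranial broadband slope), 20 µV RMS. The fitted Welch slope is tested
  to match the configured exponent within ±0.3.
- **Planted responses**: 20 % of bipolar pairs are informative; each
  responds during the cues of a single class (round-robin), so classes have
  distinct spatial signatures. Response envelopes are unit-normalized
  shapes — `phasic_onset` (Gaussian bump ~0.4 s post-onset),
  `phasic_onset_offset` (a second bump just after cue offset),
  `phasic_tonic` (fast rise, ≥ 0.5-of-peak plateau through the cue), and
  `low_band_suppression` (non-positive sustained dip). Carrier-borne kinds
  multiply the envelope onto band-passed Gaussian noise (4th-order
  zero-phase Butterworth at the band edges), so integrated band amplitude —
  not a line spectrum — is modulated. Suppression multiplicatively attenuates
  the pair's own 0–30 Hz content, reflecting the broadband low-frequency
  decrease seen during movement preparation; the ground truth accordingly
  lists the delta/theta, alpha/mu and beta features of that pair. (A
  single-band suppression would in any case bleed into the neighboring band
  through the 200 ms Blackman main lobe, making a single-band ground truth
  physically wrong.)
- **Effect calibration**: `effect_size` is the peak change of integrated
  band amplitude in SD units of the pair's background band amplitude.
  Because amplitudes of independent signals add in quadrature, the carrier
  gain is set to √(Δ(2m + Δ))/A₁ where Δ = effect_size·SD, m is the mean
  background band amplitude and A₁ the unit-carrier band amplitude.
- **Trial variability**: per-trial amplitude scale ~ N(1, cv) truncated at
  0.1 (default cv 0.3) and onset latency ~ N(0, 50 ms).
- **Survival under bipolar derivation**: a planted trace is added to every
  contact from the lead tip through the pair's first contact, making it
  common-mode on all inner pairs; adjacent-contact subtraction cancels it
  everywhere except the target pair. Ground truth therefore matches the
  derivable feature set exactly.

Identical configurations (including seed) produce bit-identical recordings.

What the generator does **not** emulate: volume conduction and realistic
dipole geometry, line noise and movement artifacts, amplitude drift across
the session, correlated noise between channels, behavioural variability in
response shape, and inter-trial-interval jitter. Passing tests therefore
show that the pipeline recovers planted effects of the stated size under
stationary 1/f noise — not that it would do so on clinical recordings.

## Numerical conventions and edge cases

- Epoch/label snapping uses `floor((t − t₀)/0.2 + 1e−9)`; the epsilon guards
  float representation of decimal onsets.
- Boxcar spans must be odd multiples of the window step (default 5 windows);
  sub-step spans are the identity.
- Events must be sorted and non-overlapping with offset > onset; violations
  are rejected with the offending row. An event running past the feature
  grid drops that trial with a warning.
- Unequal cue durations within a class are rejected unless `crop_to_min`.
- EDF output is 16-bit with per-channel physical ranges; quantization error
  is bounded by (range/32767)/2. The writer quantizes against the range
  exactly as printed in the header, so a reader reconstructs with the same
  scale.
- Degenerate decoding inputs (empty feature selection, single-class labels,
  a class missing from a partition, non-finite training loss) are rejected
  with named errors rather than silently proceeding.

## Problem sizes used in tests and the acceptance script

Unit tests run on a single-lead 1 kHz session (8 trials/class). The
acceptance battery uses: three default-size sessions (effect 4, jitter 0.2)
for selection precision/recall; one default session for the four-architecture
grid (5 repeat seeds); one phasic-only session for the sustained-output
contrast (correct cue-class fraction in the final second of each test cue);
and one single-lead zero-effect session for null safety (selected-feature
fraction at `> 0.6`, and window-shuffled-label accuracy expressed as binomial
z-scores against majority-frequency chance). These sizes were chosen as the
smallest sessions at which the planted-effect and ordering properties are
stable across seeds.

## Known limitations

- `include_all` MCC is biased upward at small trial counts; use
  `leave_one_out` when comparing MCC values across different numbers of
  trials.
- The SVM hyperparameter grid is intentionally tiny; serious use should
  widen it.
- The LSTM is full-batch and single-threaded; it is sized for dozens of
  sequences, not thousands.
- Accuracy is defined per window; with unbalanced rest/cue durations the
  chance level moves with the rest fraction. The trial-wise majority-vote
  accuracy is reported alongside for a duration-independent view.
- No permutation-based significance testing of MCC values; selection uses
  fixed thresholds.
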
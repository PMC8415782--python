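# seegdecode

Decoding of sustained movement and tactile-stimulus classes from task-locked
intracranial recordings (SEEG depth leads or ECoG grids), built around three
ideas:

1. **Integrated amplitude features (IAFs).** Bipolar-derived voltage traces
   are cut into non-overlapping 200 ms Blackman-tapered windows; a short FFT
   per window (5 Hz bin spacing) gives amplitude spectra whose bins are summed
   within standard frequency bands — delta/theta [0, 10), alpha/mu [10, 15),
   beta [15, 30) and three gamma bands of increasing bandwidth [30, 100),
   [100, 500), [500, 5000) Hz — then smoothed with a 1 s boxcar and
   z-standardized per feature across the task.
2. **Repeatability-based feature selection (MCC).** Evoked band responses are
   often transient (phasic) and vary in amplitude trial to trial. For each
   feature and cue class, trials epoched from cue onset to 400 ms past cue
   offset are averaged into a composite temporal response; the mean Pearson
   correlation of individual trials with that composite — the mean correlation
   coefficient, MCC — scores how reliably the feature repeats. Features pass
   a threshold rule (``mcc > 0.6``) or a range rule (``0.4 <= mcc <= 0.6``),
   per class, unioned across classes.
3. **Sequence decoding.** Two window-wise decoders are compared, with and
   without MCC selection: a memoryless gaussian-kernel (RBF) multi-class SVM
   over per-window IAF vectors, and an LSTM recurrent network that emits one
   class decision per window. Because the LSTM carries state, it can hold a
   sustained output through a long cue even when its input features are
   transient — the key behavioural contrast with the SVM.

Patient recordings of this kind are rarely shareable, so the package includes
a synthetic-recording generator that plants ground-truthed band-limited
evoked responses (phasic, phasic-tonic, low-band suppression, gamma
enhancement) on a subset of bipolar pairs over 1/f background noise. Every
stage of the pipeline is tested end-to-end against that ground truth.

## Worked example

The one-command demo simulates a two-class cued-movement session (3 depth
leads × 16 contacts at 2 kHz, 20 trials per class, 4 s cues and 4 s rest,
20 % of bipolar pairs informative at a 3 SD effect), extracts IAFs, selects
features at ``mcc > 0.6`` on the training partition, and evaluates the four
decoding architectures on a held-out contiguous test partition:

```sh
seegdecode demo --out-dir runs/demo --seed 0
```

```
svm       svm (selection none): 72.75 ± 0.00% (chance 45.00%)
mcc_svm   svm (selection >0.6): 91.00 ± 0.00% (chance 45.00%)
lstm      lstm (selection none): 65.50 ± 2.47% (chance 45.00%)
mcc_lstm  lstm (selection >0.6): 85.75 ± 0.00% (chance 45.00%)
```

Each line is the window-wise accuracy (mean ± SD over decoder re-trainings)
of one architecture on the test windows; chance is the frequency of the
majority window label (here rest, 45 %). Repeatability-based selection lifts
both decoder families well above their unselected counterparts, and the
selected-feature LSTM additionally holds correct, sustained predictions
through whole cues. The run directory contains the simulated EDF recording,
the events table, the IAF matrix (HDF5), the per-architecture reports and a
copy of the configuration with its hash.

The same stages are available as individual subcommands
(``simulate``, ``extract``, ``select``, ``train``, ``report``, ``run``) and
as library functions:

```python
from seegdecode import (SynthConfig, simulate_recording, build_bipolar_montage,
                        apply_montage, extract_iaf, epoch_features, mcc,
                        composite_response, select_features)

recording, events, truth = simulate_recording(SynthConfig(seed=1))
bipolar = apply_montage(recording, build_bipolar_montage(recording))
iaf = extract_iaf(bipolar)                       # windows x (pair, band)
epochs = epoch_features(iaf, events)             # cue onset .. offset + 0.4 s
table = mcc(epochs, composite_response(epochs))  # repeatability per feature
selection = select_features(table, ">0.6")
```

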
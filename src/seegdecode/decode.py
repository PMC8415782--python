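"""Window-wise decoding: gaussian-kernel SVM and LSTM, with/without selection.

Every 200 ms feature window receives a label — 0 for rest, 1..K for the cue
classes, where a cue's windows run from its (grid-snapped) onset to 400 ms
past its offset. Decoders are evaluated on a contiguous, trial-boundary
independent test partition; accuracy is the fraction of correctly labeled
test windows, reported as mean ± SD over repeated re-trainings with
different seeds. A trial-wise majority-vote accuracy over cue trials is also
reported. The four-architecture grid crosses {SVM, LSTM} with {no selection,
MCC selection}; feature selection and (optionally) standardization see only
the training partition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import confusion_matrix
from sklearn.svm import SVC

from .features import IAFMatrix
from .lstm import LSTMClassifier
from .repeatability import (
    FeatureSelection,
    SelectionRule,
    composite_response,
    epoch_features,
    mcc,
    select_features,
)
from .signalio import EventTable

logger = logging.getLogger(__name__)

REST_LABEL = "rest"


@dataclass
class LabeledWindows:
    """Class id per feature window; 0 is rest, 1..K the cue classes."""

    labels: np.ndarray  # (n_windows,) int
    class_names: list[str]  # index 0 is the rest label

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


@dataclass
class SVMConfig:
    """RBF-kernel SVM on per-window IAF vectors (memoryless by design)."""

    c_grid: tuple[float, ...] = (1.0, 10.0)
    gamma_grid: tuple = ("scale",)
    n_folds: int = 3


@dataclass
class LSTMConfig:
    hidden_units: int = 64
    learning_rate: float = 0.01
    max_epochs: int = 200
    patience: int = 20
    chunk_windows: int | None = None  # default: one cue+rest block


@dataclass
class DecoderConfig:
    kind: str = "svm"  # svm | lstm
    svm: SVMConfig = field(default_factory=SVMConfig)
    lstm: LSTMConfig = field(default_factory=LSTMConfig)
    seed: int = 0
    n_repeats: int = 5
    split: float = 0.75


@dataclass
class EvalReport:
    """Window-wise decoding accuracy over repeated re-trainings."""

    per_repeat_accuracy: list[float]
    mean_accuracy: float
    sd_accuracy: float | None  # None when a single repeat was run
    confusion: np.ndarray  # (K+1, K+1), summed over repeats
    chance_level: float
    class_names: list[str]
    decoder_kind: str
    selection_rule: str | None
    n_selected_features: int | None
    trial_majority_accuracy: float | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["confusion"] = self.confusion.tolist()
        return d

    def summary(self) -> str:
        sd = f"{100 * self.sd_accuracy:.2f}" if self.sd_accuracy is not None else "n/a"
        sel = self.selection_rule or "none"
        return (
            f"{self.decoder_kind} (selection {sel}): "
            f"{100 * self.mean_accuracy:.2f} ± {sd}% "
            f"(chance {100 * self.chance_level:.2f}%)"
        )


def make_window_labels(
    events: EventTable,
    window_start_times: np.ndarray,
    post_offset_s: float = 0.4,
    rest_label: str = REST_LABEL,
) -> LabeledWindows:
    """Label each window: the cue's class within [onset, offset + 0.4 s), else rest.

    Onsets are snapped to the window grid exactly as in epoching, so epoch
    windows and labeled windows coincide.
    """
    step = float(window_start_times[1] - window_start_times[0])
    t0 = float(window_start_times[0])
    class_names = [rest_label] + sorted(set(events.labels))
    ids = {name: k for k, name in enumerate(class_names)}
    labels = np.zeros(len(window_start_times), dtype=int)
    claimed = np.zeros(len(window_start_times), dtype=bool)
    for onset, offset, label in zip(events.onsets_s, events.offsets_s, events.labels):
        start = int(np.floor((onset - t0) / step + 1e-9))
        n_win = int(np.floor((offset - onset + post_offset_s) / step + 1e-9))
        stop = min(start + n_win, len(labels))
        start = max(start, 0)
        if claimed[start:stop].any():
            raise ValueError(
                f"labeled interval for cue at {onset} s overlaps a previous one"
            )
        labels[start:stop] = ids[label]
        claimed[start:stop] = True
    return LabeledWindows(labels, class_names)


def split_train_test(
    iaf: IAFMatrix,
    labeled: LabeledWindows,
    events: EventTable,
    split: float = 0.75,
) -> tuple[np.ndarray, np.ndarray]:
    """Contiguous train/test window indices, cut at a trial boundary.

    The requested fraction is snapped to the nearest cue-onset boundary so no
    trial contributes windows to both partitions. Both partitions must
    contain every class (including rest).
    """
    if not 0.0 < split < 1.0:
        raise ValueError("split fraction must be in (0, 1)")
    step = iaf.window_step_s
    t0 = float(iaf.window_start_times[0])
    boundaries = np.array(
        [int(np.floor((on - t0) / step + 1e-9)) for on in events.onsets_s]
    )
    target = split * iaf.n_windows
    cut = int(boundaries[np.argmin(np.abs(boundaries - target))])
    if cut <= 0 or cut >= iaf.n_windows:
        raise ValueError("split leaves an empty partition")
    train_idx = np.arange(cut)
    test_idx = np.arange(cut, iaf.n_windows)
    for name, idx in (("train", train_idx), ("test", test_idx)):
        present = set(labeled.labels[idx].tolist())
        for k, cname in enumerate(labeled.class_names):
            if k not in present:
                raise ValueError(
                    f"class {cname!r} is absent from the {name} partition; "
                    "use more trials or a different split"
                )
    return train_idx, test_idx


def _fit_svm(
    X: np.ndarray, y: np.ndarray, config: SVMConfig, seed: int
) -> SVC:
    """Fit an RBF SVM, choosing C/gamma on contiguous train folds."""
    best, best_score = None, -np.inf
    combos = [(c, g) for c in config.c_grid for g in config.gamma_grid]
    if len(combos) == 1:
        c, g = combos[0]
        return SVC(kernel="rbf", C=c, gamma=g, random_state=seed).fit(X, y)
    folds = np.array_split(np.arange(len(y)), config.n_folds)
    for c, g in combos:
        scores = []
        for f in folds:
            mask = np.ones(len(y), dtype=bool)
            mask[f] = False
            if len(np.unique(y[mask])) < 2 or len(f) == 0:
                continue
            clf = SVC(kernel="rbf", C=c, gamma=g, random_state=seed).fit(X[mask], y[mask])
            scores.append(np.mean(clf.predict(X[f]) == y[f]))
        score = float(np.mean(scores)) if scores else -np.inf
        if score > best_score:
            best_score, best = score, (c, g)
    c, g = best
    return SVC(kernel="rbf", C=c, gamma=g, random_state=seed).fit(X, y)


def train_svm(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    config: SVMConfig | None = None,
    seed: int = 0,
) -> SVC:
    """Multi-class gaussian-kernel SVM over per-window feature vectors."""
    if train_features.shape[1] == 0:
        raise ValueError(
            "no features to train on; relax the selection rule"
        )
    if len(np.unique(train_labels)) < 2:
        raise ValueError("training labels contain fewer than 2 classes")
    return _fit_svm(train_features, train_labels, config or SVMConfig(), seed)


def chunk_sequences(
    values: np.ndarray, labels: np.ndarray, chunk_windows: int
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Cut contiguous windows into consecutive sequences of fixed length.

    The final shorter remainder is kept as its own sequence.
    """
    seqs, labs = [], []
    for start in range(0, len(labels), chunk_windows):
        stop = min(start + chunk_windows, len(labels))
        if stop - start >= 2:
            seqs.append(values[start:stop])
            labs.append(labels[start:stop])
    return seqs, labs


def event_aligned_sequences(
    values: np.ndarray,
    labels: np.ndarray,
    window_indices: np.ndarray,
    events: EventTable,
    step_s: float,
    t0: float,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Cut a contiguous window run into one sequence per cue block.

    Sequence boundaries sit at the grid-snapped cue onsets inside the run, so
    every sequence (train or test) starts at a cue onset and extends through
    the following rest; a leading partial rest segment is kept as its own
    sequence. Aligning sequences to the task structure keeps the within-chunk
    timing of cues identical across partitions.
    """
    lo, hi = int(window_indices[0]), int(window_indices[-1]) + 1
    onsets = [int(np.floor((on - t0) / step_s + 1e-9)) for on in events.onsets_s]
    bounds = sorted({w for w in onsets if lo < w < hi})
    edges = [lo] + bounds + [hi]
    seqs, labs = [], []
    for a, b in zip(edges, edges[1:]):
        if b - a >= 2:
            seqs.append(values[a - lo : b - lo])
            labs.append(labels[a - lo : b - lo])
    return seqs, labs


def train_lstm(
    train_sequences: list[np.ndarray],
    train_labels: list[np.ndarray],
    config: LSTMConfig | None = None,
    seed: int = 0,
) -> LSTMClassifier:
    """Sequence-to-sequence LSTM over contiguous window runs."""
    config = config or LSTMConfig()
    if not train_sequences or train_sequences[0].shape[1] == 0:
        raise ValueError("no features to train on; relax the selection rule")
    clf = LSTMClassifier(
        hidden_units=config.hidden_units,
        learning_rate=config.learning_rate,
        max_epochs=config.max_epochs,
        patience=config.patience,
        seed=seed,
    )
    return clf.fit(train_sequences, train_labels)


def default_chunk_windows(events: EventTable, step_s: float) -> int:
    """One cue-plus-rest block, in windows (the LSTM's default sequence length)."""
    if len(events) >= 2:
        block = float(np.median(np.diff(events.onsets_s)))
    else:
        block = float(events.offsets_s[0] - events.onsets_s[0]) * 2.0
    return max(2, int(round(block / step_s)))


def _trial_majority_accuracy(
    pred: np.ndarray,
    truth: np.ndarray,
    test_idx: np.ndarray,
    events: EventTable,
    labeled: LabeledWindows,
    step_s: float,
    t0: float,
    post_offset_s: float = 0.4,
) -> float | None:
    """Majority vote over each test cue trial's windows."""
    ids = {name: k for k, name in enumerate(labeled.class_names)}
    lo, hi = test_idx[0], test_idx[-1]
    correct, total = 0, 0
    for onset, offset, label in zip(events.onsets_s, events.offsets_s, events.labels):
        start = int(np.floor((onset - t0) / step_s + 1e-9))
        stop = start + int(np.floor((offset - onset + post_offset_s) / step_s + 1e-9))
        if start < lo or stop > hi + 1:
            continue
        votes = pred[start - lo : stop - lo]
        counts = np.bincount(votes, minlength=labeled.n_classes)
        correct += int(np.argmax(counts) == ids[label])
        total += 1
    return correct / total if total else None


@dataclass
class _PreparedData:
    train_X: np.ndarray
    train_y: np.ndarray
    test_X: np.ndarray
    test_y: np.ndarray
    train_idx: np.ndarray
    test_idx: np.ndarray
    chunk: int


def _prepare(
    iaf: IAFMatrix,
    events: EventTable,
    labeled: LabeledWindows,
    split: float,
    selection: FeatureSelection | None,
) -> _PreparedData:
    train_idx, test_idx = split_train_test(iaf, labeled, events, split)
    values = iaf.values
    if selection is not None:
        if len(selection) == 0:
            raise ValueError("empty feature selection; relax the rule")
        cols = [iaf.feature_names.index(f) for f in selection.selected]
        values = values[:, cols]
    chunk = default_chunk_windows(events, iaf.window_step_s)
    return _PreparedData(
        train_X=values[train_idx],
        train_y=labeled.labels[train_idx],
        test_X=values[test_idx],
        test_y=labeled.labels[test_idx],
        train_idx=train_idx,
        test_idx=test_idx,
        chunk=chunk,
    )


def evaluate(
    iaf: IAFMatrix,
    events: EventTable,
    config: DecoderConfig,
    selection: FeatureSelection | None = None,
    labeled: LabeledWindows | None = None,
) -> EvalReport:
    """Train ``config.n_repeats`` decoders (fresh seed each) and score them.

    Accuracy is window-wise on the held-out contiguous test partition; the
    confusion matrix is summed over repeats; chance level is the frequency of
    the majority label among test windows.
    """
    if labeled is None:
        labeled = make_window_labels(events, iaf.window_start_times)
    data = _prepare(iaf, events, labeled, config.split, selection)
    seeds = [config.seed + 1000 * r for r in range(config.n_repeats)]
    accs, confusions, trial_accs = [], [], []
    all_classes = np.arange(labeled.n_classes)
    for seed in seeds:
        if config.kind == "svm":
            clf = train_svm(data.train_X, data.train_y, config.svm, seed)
            pred = clf.predict(data.test_X)
        elif config.kind == "lstm":
            step, t0 = iaf.window_step_s, float(iaf.window_start_times[0])
            if config.lstm.chunk_windows:
                seqs, labs = chunk_sequences(
                    data.train_X, data.train_y, config.lstm.chunk_windows
                )
                test_seqs, _ = chunk_sequences(
                    data.test_X, data.test_y, config.lstm.chunk_windows
                )
            else:
                seqs, labs = event_aligned_sequences(
                    data.train_X, data.train_y, data.train_idx, events, step, t0
                )
                test_seqs, _ = event_aligned_sequences(
                    data.test_X, data.test_y, data.test_idx, events, step, t0
                )
            clf = train_lstm(seqs, labs, config.lstm, seed)
            pred = np.concatenate(clf.predict(test_seqs))
            # fixed-length chunking may drop a short remainder; align truth
        else:
            raise ValueError(f"unknown decoder kind {config.kind!r}")
        truth = data.test_y[: len(pred)]
        accs.append(float(np.mean(pred == truth)))
        confusions.append(confusion_matrix(truth, pred, labels=all_classes))
        ta = _trial_majority_accuracy(
            pred,
            truth,
            data.test_idx[: len(pred)],
            events,
            labeled,
            iaf.window_step_s,
            float(iaf.window_start_times[0]),
        )
        if ta is not None:
            trial_accs.append(ta)
    test_counts = np.bincount(data.test_y, minlength=labeled.n_classes)
    return EvalReport(
        per_repeat_accuracy=accs,
        mean_accuracy=float(np.mean(accs)),
        sd_accuracy=float(np.std(accs, ddof=1)) if len(accs) > 1 else None,
        confusion=np.sum(confusions, axis=0),
        chance_level=float(test_counts.max() / test_counts.sum()),
        class_names=labeled.class_names,
        decoder_kind=config.kind,
        selection_rule=selection.rule if selection is not None else None,
        n_selected_features=len(selection) if selection is not None else None,
        trial_majority_accuracy=float(np.mean(trial_accs)) if trial_accs else None,
    )


def select_on_train(
    iaf: IAFMatrix,
    events: EventTable,
    rule: SelectionRule | str,
    split: float,
    mode: str = "include_all",
) -> FeatureSelection:
    """MCC feature selection using only events fully inside the train partition."""
    labeled = make_window_labels(events, iaf.window_start_times)
    train_idx, _ = split_train_test(iaf, labeled, events, split)
    cut_time = float(iaf.window_start_times[train_idx[-1]]) + iaf.window_step_s
    keep = [
        i
        for i in range(len(events))
        if events.offsets_s[i] + 0.4 <= cut_time + 1e-9
    ]
    train_events = EventTable(
        events.onsets_s[keep],
        events.offsets_s[keep],
        [events.labels[i] for i in keep],
    )
    epochs = epoch_features(iaf, train_events)
    table = mcc(epochs, composite_response(epochs), mode=mode)
    return select_features(table, rule)


def architecture_grid(
    iaf: IAFMatrix,
    events: EventTable,
    rule: SelectionRule | str = ">0.6",
    config: DecoderConfig | None = None,
) -> dict[str, EvalReport]:
    """Evaluate the four decoding architectures on one split with shared seeds.

    Cells: plain SVM, MCC-selected SVM, plain LSTM, MCC-selected LSTM.
    """
    config = config or DecoderConfig()
    labeled = make_window_labels(events, iaf.window_start_times)
    selection = select_on_train(iaf, events, rule, config.split)
    reports: dict[str, EvalReport] = {}
    for kind in ("svm", "lstm"):
        cfg = DecoderConfig(
            kind=kind,
            svm=config.svm,
            lstm=config.lstm,
            seed=config.seed,
            n_repeats=config.n_repeats,
            split=config.split,
        )
        reports[kind] = evaluate(iaf, events, cfg, selection=None, labeled=labeled)
        reports[f"mcc_{kind}"] = evaluate(
            iaf, events, cfg, selection=selection, labeled=labeled
        )
    return reports
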
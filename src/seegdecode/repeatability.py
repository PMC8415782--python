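"""Trial-repeatability analysis: epoching, composite responses, MCC, selection.

For every feature and cue class, trials are epoched from cue onset to 400 ms
after cue offset, averaged into a composite temporal response, and scored by
the mean correlation coefficient (MCC): the average Pearson correlation of
each trial's trace with the composite. Features repeat reliably when their
MCC is high; selection keeps features whose MCC passes a threshold (strictly
greater) or falls inside a closed range, per class, unioned across classes.

Two MCC modes are provided. ``include_all`` lets each trial participate in
its own composite — the literal construction — which is optimistically biased
for small trial counts; ``leave_one_out`` recomputes the composite without
the scored trial and removes that bias.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import IAFMatrix
from .signalio import EventTable

logger = logging.getLogger(__name__)

POST_OFFSET_S = 0.4  #: epoch extension beyond cue offset (s)


@dataclass
class EpochSet:
    """Cue-aligned feature epochs, grouped by class.

    ``trials[c]`` has shape (n_trials, n_epoch_windows, n_features); all
    epochs of one class share a window count (cue duration + 0.4 s of grid).
    ``relative_times[c]`` gives each epoch window's start relative to the
    snapped cue onset; ``event_indices[c]`` maps trials back to event rows.
    """

    trials: dict[str, np.ndarray]
    relative_times: dict[str, np.ndarray]
    event_indices: dict[str, list[int]]
    feature_names: list[str]

    @property
    def class_names(self) -> list[str]:
        return sorted(self.trials)

    def n_trials(self, class_name: str) -> int:
        return self.trials[class_name].shape[0]


@dataclass
class CompositeResponse:
    """Per class and feature: the mean trace over trials."""

    traces: dict[str, np.ndarray]  # (n_epoch_windows, n_features)
    n_trials: dict[str, int]
    feature_names: list[str]


@dataclass
class MCCTable:
    """Mean correlation coefficient per class and feature, with validity."""

    values: dict[str, np.ndarray]  # per class, (n_features,); NaN where invalid
    n_valid_trials: dict[str, np.ndarray]
    feature_names: list[str]

    @property
    def class_names(self) -> list[str]:
        return sorted(self.values)

    def valid(self, class_name: str) -> np.ndarray:
        return self.n_valid_trials[class_name] > 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.class_names:
            for j, name in enumerate(self.feature_names):
                pair, _, band = name.rpartition("|")
                rows.append(
                    {
                        "feature": name,
                        "pair": pair,
                        "band": band,
                        "class": c,
                        "mcc": self.values[c][j],
                        "n_valid_trials": int(self.n_valid_trials[c][j]),
                    }
                )
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


@dataclass(frozen=True)
class SelectionRule:
    """Either ``mcc > threshold`` (strict) or ``low <= mcc <= high``."""

    threshold: float | None = None
    low: float | None = None
    high: float | None = None

    def __post_init__(self) -> None:
        is_thresh = self.threshold is not None
        is_range = self.low is not None and self.high is not None
        if is_thresh == is_range:
            raise ValueError("rule must be exactly one of threshold or [low, high]")
        if is_range and self.low > self.high:
            raise ValueError(f"range low {self.low} exceeds high {self.high}")

    @classmethod
    def parse(cls, text: str) -> "SelectionRule":
        """Parse ``">0.6"`` (threshold) or ``"0.4:0.6"`` (closed range)."""
        text = text.strip()
        m = re.fullmatch(r">\s*(-?\d*\.?\d+)", text)
        if m:
            return cls(threshold=float(m.group(1)))
        m = re.fullmatch(r"(-?\d*\.?\d+)\s*:\s*(-?\d*\.?\d+)", text)
        if m:
            return cls(low=float(m.group(1)), high=float(m.group(2)))
        raise ValueError(f"cannot parse selection rule {text!r}")

    def applies(self, mcc: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            if self.threshold is not None:
                mask = mcc > self.threshold
            else:
                mask = (mcc >= self.low) & (mcc <= self.high)
        return mask & np.isfinite(mcc)

    def describe(self) -> str:
        if self.threshold is not None:
            return f">{self.threshold}"
        return f"{self.low}:{self.high}"


@dataclass
class FeatureSelection:
    """Selected features: the union of per-class passing sets."""

    selected: list[str]
    per_class: dict[str, list[str]]
    rule: str
    feature_indices: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.selected)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "rule": self.rule,
                    "selected": self.selected,
                    "per_class": self.per_class,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureSelection":
        payload = json.loads(Path(path).read_text())
        return cls(
            selected=payload["selected"],
            per_class=payload["per_class"],
            rule=payload["rule"],
        )


def epoch_features(
    iaf: IAFMatrix,
    events: EventTable,
    post_offset_s: float = POST_OFFSET_S,
    crop_to_min: bool = False,
) -> EpochSet:
    """Cut the IAF matrix into cue-aligned epochs, one block per class.

    The epoch starts at the latest window-grid start time at or before the
    cue onset and extends to ``post_offset_s`` past the cue offset (a 4 s cue
    gives 22 windows at the 200 ms step). Trials running past the end of the
    recording are dropped with a warning. Classes must have equal cue
    durations unless ``crop_to_min`` is set, which crops all epochs of a
    class to its shortest cue.
    """
    step = iaf.window_step_s
    t0 = float(iaf.window_start_times[0])
    durations: dict[str, list[float]] = {}
    for onset, offset, label in zip(events.onsets_s, events.offsets_s, events.labels):
        durations.setdefault(label, []).append(offset - onset)
    epoch_windows: dict[str, int] = {}
    for label, durs in durations.items():
        if max(durs) - min(durs) > 1e-9:
            if not crop_to_min:
                raise ValueError(
                    f"class {label!r} has unequal cue durations "
                    f"({min(durs)}-{max(durs)} s); pass crop_to_min to crop"
                )
            logger.warning("class %s cropped to its minimum cue %g s", label, min(durs))
        epoch_windows[label] = int(np.floor((min(durs) + post_offset_s) / step + 1e-9))

    trials: dict[str, list[np.ndarray]] = {c: [] for c in durations}
    idx_map: dict[str, list[int]] = {c: [] for c in durations}
    for row, (onset, label) in enumerate(zip(events.onsets_s, events.labels)):
        start = int(np.floor((onset - t0) / step + 1e-9))
        stop = start + epoch_windows[label]
        if start < 0 or stop > iaf.n_windows:
            logger.warning(
                "event row %d (%s at %g s) extends past the feature grid; dropped",
                row, label, onset,
            )
            continue
        trials[label].append(iaf.values[start:stop])
        idx_map[label].append(row)

    out_trials, rel_times = {}, {}
    for label in durations:
        if not trials[label]:
            raise ValueError(f"no complete trial remains for class {label!r}")
        out_trials[label] = np.stack(trials[label])
        rel_times[label] = np.arange(epoch_windows[label]) * step
    return EpochSet(out_trials, rel_times, idx_map, iaf.feature_names)


def composite_response(epochs: EpochSet) -> CompositeResponse:
    """Average the cue-aligned trials of each class, per feature and window."""
    traces = {c: epochs.trials[c].mean(axis=0) for c in epochs.trials}
    n = {c: epochs.trials[c].shape[0] for c in epochs.trials}
    return CompositeResponse(traces, n, epochs.feature_names)


def _pearson_by_feature(trial: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Pearson r between a trial and a reference trace, per feature column.

    Columns where either side has zero variance come back NaN.
    """
    tc = trial - trial.mean(axis=0)
    rc = ref - ref.mean(axis=0)
    denom = np.sqrt((tc**2).sum(axis=0) * (rc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (tc * rc).sum(axis=0) / denom
    r[denom == 0] = np.nan
    return r


def mcc(
    epochs: EpochSet,
    composite: CompositeResponse | None = None,
    mode: str = "include_all",
) -> MCCTable:
    """Mean correlation coefficient of trial traces against the composite.

    Per class and feature, each trial's Pearson correlation with the composite
    temporal response is computed and averaged over trials. Trials or
    composites with zero variance in a feature are excluded from its average;
    a feature with no valid trial is NaN with ``n_valid_trials`` 0. In
    ``leave_one_out`` mode the composite is recomputed without the scored
    trial before correlating.
    """
    if mode not in ("include_all", "leave_one_out"):
        raise ValueError(f"unknown MCC mode {mode!r}")
    if composite is None:
        composite = composite_response(epochs)
    n_features = len(epochs.feature_names)
    first = next(iter(epochs.trials.values()))
    if first.shape[1] < 3:
        raise ValueError("MCC needs epochs of at least 3 windows")
    values: dict[str, np.ndarray] = {}
    n_valid: dict[str, np.ndarray] = {}
    for c, block in epochs.trials.items():
        n_trials = block.shape[0]
        comp = composite.traces[c]
        rs = np.empty((n_trials, n_features))
        for i in range(n_trials):
            if mode == "leave_one_out" and n_trials > 1:
                ref = (n_trials * comp - block[i]) / (n_trials - 1)
            else:
                ref = comp
            rs[i] = _pearson_by_feature(block[i], ref)
        finite = np.isfinite(rs)
        valid_counts = finite.sum(axis=0)
        with np.errstate(invalid="ignore"):
            mean_r = np.where(finite, rs, 0.0).sum(axis=0) / valid_counts
        values[c] = mean_r
        n_valid[c] = valid_counts
    return MCCTable(values, n_valid, epochs.feature_names)


def select_features(
    table: MCCTable, rule: SelectionRule | str
) -> FeatureSelection:
    """Apply the MCC rule per class and return the union across classes."""
    if isinstance(rule, str):
        rule = SelectionRule.parse(rule)
    per_class: dict[str, list[str]] = {}
    union: set[int] = set()
    for c in table.class_names:
        mask = rule.applies(table.values[c])
        idx = np.flatnonzero(mask)
        per_class[c] = [table.feature_names[j] for j in idx]
        union.update(int(j) for j in idx)
    ordered = sorted(union)
    if not ordered:
        logger.warning("selection rule %s selects no feature", rule.describe())
    return FeatureSelection(
        selected=[table.feature_names[j] for j in ordered],
        per_class=per_class,
        rule=rule.describe(),
        feature_indices=ordered,
    )
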
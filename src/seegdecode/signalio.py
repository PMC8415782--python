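"""Raw-recording and event-table I/O plus bipolar montage construction.

Recordings are exchanged as EDF (16-bit integer samples, physical units µV);
events as a UTF-8 tab-separated file with header ``onset_s  offset_s  label``,
seconds as decimal floats. Bipolar derivation follows the standard SEEG
convention: adjacent contacts within one lead are subtracted (contact *i*
minus contact *i + 1*); gaps in the contact numbering are never bridged.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .edf import write_edf

logger = logging.getLogger(__name__)

#: Default pattern splitting an EDF channel label into (lead_id, contact_index).
CHANNEL_LABEL_PATTERN = r"^(?P<lead>[A-Za-z]+[A-Za-z']*?)(?P<contact>\d+)$"


@dataclass(frozen=True)
class ChannelInfo:
    """One recording channel: a contact on a lead."""

    channel_id: str
    lead_id: str
    contact_index: int
    anatomical_label: str | None = None


@dataclass
class RawRecording:
    """Multichannel voltage samples with channel metadata.

    Parameters
    ----------
    sampling_rate : float
        Samples per second, shared by all channels.
    samples : ndarray, shape (n_channels, n_samples)
        Voltage traces in µV.
    channels : list of ChannelInfo
        Per-channel metadata, same order as the rows of ``samples``.
    """

    sampling_rate: float
    samples: np.ndarray
    channels: list[ChannelInfo]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x time) array")
        if self.samples.shape[0] != len(self.channels):
            raise ValueError(
                f"{self.samples.shape[0]} sample rows but "
                f"{len(self.channels)} channel records"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        seen: dict[tuple[str, int], str] = {}
        for ch in self.channels:
            key = (ch.lead_id, ch.contact_index)
            if key in seen:
                raise ValueError(
                    f"duplicate contact {ch.contact_index} on lead {ch.lead_id!r} "
                    f"(channels {seen[key]!r} and {ch.channel_id!r})"
                )
            seen[key] = ch.channel_id

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel_index(self, channel_id: str) -> int:
        for i, ch in enumerate(self.channels):
            if ch.channel_id == channel_id:
                return i
        raise KeyError(f"channel {channel_id!r} not present in recording")


@dataclass
class EventTable:
    """Cue intervals with class labels, sorted and non-overlapping."""

    onsets_s: np.ndarray
    offsets_s: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        self.offsets_s = np.asarray(self.offsets_s, dtype=float)
        n = len(self.onsets_s)
        if not (len(self.offsets_s) == len(self.labels) == n):
            raise ValueError("onsets, offsets and labels must have equal length")
        for i in range(n):
            if self.offsets_s[i] <= self.onsets_s[i]:
                raise ValueError(
                    f"event row {i}: offset {self.offsets_s[i]} s is not after "
                    f"onset {self.onsets_s[i]} s"
                )
        order = np.argsort(self.onsets_s, kind="stable")
        self.onsets_s = self.onsets_s[order]
        self.offsets_s = self.offsets_s[order]
        self.labels = [self.labels[i] for i in order]
        for i in range(1, n):
            if self.onsets_s[i] < self.offsets_s[i - 1]:
                raise ValueError(
                    f"event row {i} (onset {self.onsets_s[i]} s) overlaps the "
                    f"previous event ending at {self.offsets_s[i - 1]} s"
                )

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def class_names(self) -> list[str]:
        return sorted(set(self.labels))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"onset_s": self.onsets_s, "offset_s": self.offsets_s, "label": self.labels}
        )


@dataclass(frozen=True)
class BipolarPair:
    """One bipolar derivation: minuend contact minus subtrahend contact."""

    name: str
    minuend: str
    subtrahend: str


@dataclass
class MontageSpec:
    """Ordered bipolar pairs, named ``<lead>:<i>-<i+1>``."""

    pairs: list[BipolarPair] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def pair_names(self) -> list[str]:
        return [p.name for p in self.pairs]


def write_recording(recording: RawRecording, path: str | Path) -> None:
    """Write a recording as 16-bit EDF; channel labels are ``<lead><contact>``."""
    labels = [ch.channel_id for ch in recording.channels]
    write_edf(Path(path), recording.samples, recording.sampling_rate, labels)


def read_recording(
    path: str | Path, label_pattern: str = CHANNEL_LABEL_PATTERN
) -> RawRecording:
    """Read an EDF file into a :class:`RawRecording`.

    Channel metadata is parsed from the EDF labels using ``label_pattern``
    (default: trailing digits are the contact index, the preceding letters the
    lead id, e.g. ``LA3`` -> lead ``LA``, contact 3).
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    rates = {float(raw.info["sfreq"])}
    if len(rates) != 1:
        raise ValueError(f"mixed sampling rates in {path}: {sorted(rates)}")
    pattern = re.compile(label_pattern)
    channels = []
    for name in raw.ch_names:
        m = pattern.match(name.strip())
        if m is None:
            raise ValueError(
                f"channel label {name!r} does not match pattern {label_pattern!r}"
            )
        channels.append(
            ChannelInfo(
                channel_id=name.strip(),
                lead_id=m.group("lead"),
                contact_index=int(m.group("contact")),
            )
        )
    # MNE restores physical units as volts; recordings are exchanged in µV.
    samples = raw.get_data() * 1e6
    return RawRecording(
        sampling_rate=float(raw.info["sfreq"]), samples=samples, channels=channels
    )


def write_events(events: EventTable, path: str | Path) -> None:
    events.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_events(path: str | Path) -> EventTable:
    """Read and validate a tab-separated event file (onset_s, offset_s, label)."""
    frame = pd.read_csv(path, sep="\t", header=0, dtype={"label": str})
    required = {"onset_s", "offset_s", "label"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"events file {path} lacks columns {sorted(missing)}")
    if len(frame) == 0:
        logger.warning("events file %s has a header but no rows", path)
        return EventTable(np.empty(0), np.empty(0), [])
    for i, row in frame.iterrows():
        if row["offset_s"] <= row["onset_s"]:
            raise ValueError(
                f"events file {path} row {i}: offset_s {row['offset_s']} "
                f"<= onset_s {row['onset_s']}"
            )
    return EventTable(
        frame["onset_s"].to_numpy(),
        frame["offset_s"].to_numpy(),
        frame["label"].astype(str).tolist(),
    )


def build_bipolar_montage(recording: RawRecording) -> MontageSpec:
    """Pair each contact with its next-numbered neighbor on the same lead.

    A lead with contacts 1..k yields k-1 pairs (i minus i+1). Contacts whose
    successor index is missing (explanted or excluded channels) contribute no
    pair: the gap is not bridged. Pair ordering is by lead id, then contact.
    """
    by_lead: dict[str, dict[int, str]] = {}
    for ch in recording.channels:
        by_lead.setdefault(ch.lead_id, {})[ch.contact_index] = ch.channel_id
    pairs: list[BipolarPair] = []
    for lead in sorted(by_lead):
        contacts = by_lead[lead]
        if len(contacts) < 2:
            logger.warning("lead %s has a single contact; no bipolar pairs", lead)
            continue
        for idx in sorted(contacts):
            if idx + 1 in contacts:
                pairs.append(
                    BipolarPair(
                        name=f"{lead}:{idx}-{idx + 1}",
                        minuend=contacts[idx],
                        subtrahend=contacts[idx + 1],
                    )
                )
    if not pairs:
        raise ValueError("no lead has two adjacent contacts; montage is empty")
    return MontageSpec(pairs)


def apply_montage(recording: RawRecording, montage: MontageSpec) -> RawRecording:
    """Derive bipolar traces: each output channel is minuend minus subtrahend."""
    rows = np.empty((len(montage), recording.n_samples))
    channels = []
    for i, pair in enumerate(montage.pairs):
        a = recording.channel_index(pair.minuend)
        b = recording.channel_index(pair.subtrahend)
        rows[i] = recording.samples[a] - recording.samples[b]
        lead = recording.channels[a].lead_id
        contact = recording.channels[a].contact_index
        channels.append(
            ChannelInfo(channel_id=pair.name, lead_id=lead, contact_index=contact)
        )
    return RawRecording(
        sampling_rate=recording.sampling_rate, samples=rows, channels=channels
    )


def write_montage(montage: MontageSpec, path: str | Path) -> None:
    pd.DataFrame(
        {
            "minuend": [p.minuend for p in montage.pairs],
            "subtrahend": [p.subtrahend for p in montage.pairs],
        },
        index=montage.pair_names,
    ).to_csv(path, sep="\t", index_label="pair")
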
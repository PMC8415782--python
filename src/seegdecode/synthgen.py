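"""Synthetic task-locked SEEG-style recordings with planted evoked responses.

The generator emulates a cued sensorimotor block task: multichannel 1/f
background noise on 16-contact depth leads, with cue blocks followed by rest,
and a subset of bipolar pairs carrying ground-truthed band-limited amplitude
modulations (phasic bursts after cue onset and/or offset, phasic-tonic
responses sustained through the cue, and low-band suppression). Modulations
are multiplicative envelopes on band-passed Gaussian carrier noise, so
integrated band amplitude — not a line spectrum — is modulated.

Planted signals are added identically to every contact from the lead tip up
to the anode of the target pair. Adjacent-contact subtraction then cancels
the signal on every pair except the target one, so each planted feature
survives bipolar derivation exactly where the ground truth says it does.

Each informative pair responds during the cues of a single class; with the
default round-robin assignment every class has its own spatial signature, so
classes are decodable. Per-trial variability is a lognormal-free amplitude
scale (truncated normal around 1) and a Gaussian onset-latency shift.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .features import Band, BandSpec, DEFAULT_BANDS, blackman_window
from .signalio import (
    ChannelInfo,
    EventTable,
    MontageSpec,
    RawRecording,
    build_bipolar_montage,
    write_events,
    write_recording,
)

logger = logging.getLogger(__name__)

RESPONSE_KINDS = (
    "phasic_onset",
    "phasic_onset_offset",
    "phasic_tonic",
    "low_band_suppression",
)

_LEAD_NAMES = [f"L{chr(ord('A') + i)}" for i in range(26)]

#: low-band suppression acts on the whole low-frequency range (delta/theta,
#: alpha/mu and beta all decrease together during movement preparation)
LOW_SUPPRESSION_HIGH_HZ = 30.0


@dataclass(frozen=True)
class BackgroundSpec:
    """1/f background: PSD ~ f**-exponent, broadband RMS in µV."""

    exponent: float = 2.0
    scale_uv: float = 20.0


@dataclass
class SynthConfig:
    """Study conditions for one simulated session.

    Defaults describe a two-class sustained-movement task: 4 s cues and 4 s
    rest on a 200 ms-aligned grid, 3 depth leads of 16 contacts at 2 kHz,
    with 20% of bipolar pairs carrying evoked responses at 3 SD peak effect.
    """

    seed: int = 0
    sampling_rate: float = 2000.0
    n_leads: int = 3
    contacts_per_lead: int = 16
    classes: tuple[str, ...] = ("open", "close")
    trials_per_class: int = 20
    cue_duration_s: float = 4.0
    rest_duration_s: float = 4.0
    informative_fraction: float = 0.2
    response_kinds: tuple[str, ...] = RESPONSE_KINDS
    target_bands: tuple[str, ...] = ("gamma1", "gamma2", "gamma1")
    effect_size: float = 3.0
    amplitude_jitter_cv: float = 0.3
    latency_jitter_s: float = 0.05
    background: BackgroundSpec = field(default_factory=BackgroundSpec)
    epoch_extension_s: float = 0.4

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValueError("at least one class is required")
        if self.trials_per_class < 1:
            raise ValueError("at least one trial per class is required")
        for name, dur in (
            ("cue_duration_s", self.cue_duration_s),
            ("rest_duration_s", self.rest_duration_s),
        ):
            k = dur / 0.2
            if dur <= 0 or abs(k - round(k)) > 1e-9:
                raise ValueError(f"{name} must be a positive multiple of 0.2 s")
        if not 0.0 <= self.informative_fraction < 1.0:
            raise ValueError("informative_fraction must be in [0, 1)")
        for kind in self.response_kinds:
            if kind not in RESPONSE_KINDS:
                raise ValueError(
                    f"unknown response kind {kind!r}; known: {RESPONSE_KINDS}"
                )

    @property
    def n_trials(self) -> int:
        return self.trials_per_class * len(self.classes)


@dataclass(frozen=True)
class PlantedFeature:
    """One ground-truthed informative (pair, band) feature."""

    pair_name: str
    band_name: str
    response_kind: str
    effect_size: float
    class_name: str

    @property
    def feature_name(self) -> str:
        return f"{self.pair_name}|{self.band_name}"


@dataclass
class GroundTruth:
    informative_features: list[PlantedFeature]
    events: EventTable

    @property
    def feature_names(self) -> set[str]:
        return {f.feature_name for f in self.informative_features}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "informative_features": [asdict(f) for f in self.informative_features],
            "events": self.events.to_frame().to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        feats = [PlantedFeature(**f) for f in payload["informative_features"]]
        rows = payload["events"]
        events = EventTable(
            np.array([r["onset_s"] for r in rows]),
            np.array([r["offset_s"] for r in rows]),
            [r["label"] for r in rows],
        )
        return cls(feats, events)


def make_response_envelope(
    kind: str, epoch_times: np.ndarray, cue_duration_s: float
) -> np.ndarray:
    """Unit-normalized evoked-response envelope over epoch-relative times.

    ``epoch_times`` are seconds relative to cue onset, spanning at least the
    cue. Phasic kinds are transient bumps (onset, or onset plus offset) that
    decay essentially to zero well before the cue ends; ``phasic_tonic``
    rises quickly and holds a plateau through the cue; ``low_band_suppression``
    is a non-positive sustained dip (amplitude decrease).
    """
    t = np.asarray(epoch_times, dtype=float)
    if t[-1] < cue_duration_s:
        raise ValueError("epoch_times must span the cue (onset to >= offset)")

    def bump(center: float, width: float) -> np.ndarray:
        return np.exp(-0.5 * ((t - center) / width) ** 2)

    def smoothstep(edge: float, tau: float) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-(t - edge) / tau))

    if kind == "phasic_onset":
        env = bump(0.4, 0.2)
    elif kind == "phasic_onset_offset":
        env = bump(0.4, 0.2) + 0.8 * bump(cue_duration_s + 0.25, 0.1)
    elif kind == "phasic_tonic":
        plateau = 0.65
        rise = smoothstep(0.25, 0.08)
        fall = 1.0 - smoothstep(cue_duration_s + 0.2, 0.08)
        transient = (1.0 - plateau) * bump(0.5, 0.25)
        env = (plateau * rise + transient) * fall
    elif kind == "low_band_suppression":
        env = -(smoothstep(0.3, 0.1) * (1.0 - smoothstep(cue_duration_s + 0.2, 0.1)))
    else:
        raise ValueError(f"unknown response kind {kind!r}; known: {RESPONSE_KINDS}")
    peak = np.max(np.abs(env))
    return env / peak if peak > 0 else env


def _one_over_f_noise(
    rng: np.random.Generator, n_samples: int, fs: float, spec: BackgroundSpec
) -> np.ndarray:
    """Gaussian noise with PSD ~ f**-exponent, scaled to the configured RMS."""
    white = rng.standard_normal(n_samples)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-spec.exponent / 2.0)
    x = np.fft.irfft(spectrum * shaping, n=n_samples)
    return x * (spec.scale_uv / np.std(x))


def _bandpass_sos(band: Band, fs: float):
    nyq = fs / 2.0
    high = min(band.high, 0.995 * nyq)
    if band.low <= 0:
        return sps.butter(4, high, btype="lowpass", fs=fs, output="sos")
    return sps.butter(4, [band.low, high], btype="bandpass", fs=fs, output="sos")


def _band_carrier(rng: np.random.Generator, n: int, band: Band, fs: float) -> np.ndarray:
    """Unit-variance band-limited Gaussian carrier (zero-phase 4th-order filter)."""
    carrier = sps.sosfiltfilt(_bandpass_sos(band, fs), rng.standard_normal(n))
    return carrier / np.std(carrier)


def _band_amplitude_series(trace: np.ndarray, band: Band, fs: float) -> np.ndarray:
    """Integrated band amplitude of one trace on the 200 ms window grid."""
    n_win = int(round(0.2 * fs))
    n_windows = trace.size // n_win
    seg = trace[: n_windows * n_win].reshape(n_windows, n_win) * blackman_window(n_win)
    amp = np.abs(np.fft.rfft(seg, axis=-1))
    freqs = np.fft.rfftfreq(n_win, d=1.0 / fs)
    mask = (freqs >= band.low) & (freqs < band.high)
    return amp[:, mask].sum(axis=-1)


def _event_schedule(config: SynthConfig, rng: np.random.Generator) -> EventTable:
    labels = [c for c in config.classes for _ in range(config.trials_per_class)]
    order = rng.permutation(len(labels))
    labels = [labels[i] for i in order]
    onsets, offsets = [], []
    t = config.rest_duration_s  # lead-in rest
    for _ in labels:
        onsets.append(t)
        offsets.append(t + config.cue_duration_s)
        t += config.cue_duration_s + config.rest_duration_s
    return EventTable(np.array(onsets), np.array(offsets), labels)


def simulate_recording(
    config: SynthConfig,
) -> tuple[RawRecording, EventTable, GroundTruth]:
    """Generate a task-locked recording, its event table, and the ground truth.

    Deterministic: the same configuration (including seed) yields bit-identical
    outputs. Planted effect sizes are calibrated so that at envelope peak the
    integrated band amplitude of the target bipolar pair rises (or falls) by
    ``effect_size`` standard deviations of its background band amplitude;
    added carrier power combines with the background in quadrature and the
    calibration accounts for that.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    nyq = fs / 2.0
    events = _event_schedule(config, rng)
    duration = float(events.offsets_s[-1]) + config.rest_duration_s
    n_samples = int(round(duration * fs))

    if config.n_leads > len(_LEAD_NAMES):
        raise ValueError(f"at most {len(_LEAD_NAMES)} leads supported")
    channels = [
        ChannelInfo(f"{lead}{c}", lead, c)
        for lead in _LEAD_NAMES[: config.n_leads]
        for c in range(1, config.contacts_per_lead + 1)
    ]
    samples = np.empty((len(channels), n_samples))
    for i in range(len(channels)):
        samples[i] = _one_over_f_noise(rng, n_samples, fs, config.background)
    recording = RawRecording(fs, samples, channels)

    montage = build_bipolar_montage(recording)
    n_inf = int(round(config.informative_fraction * len(montage)))
    chosen = sorted(rng.choice(len(montage), size=n_inf, replace=False))

    band_by_name = {b.name: b for b in DEFAULT_BANDS}
    planted: list[PlantedFeature] = []
    epoch_len = int(round((config.cue_duration_s + config.epoch_extension_s) * fs))
    epoch_t = np.arange(epoch_len) / fs

    for i, pair_idx in enumerate(chosen):
        pair = montage.pairs[pair_idx]
        kind = config.response_kinds[i % len(config.response_kinds)]
        if kind == "low_band_suppression":
            # broadband low-frequency decrease; the target-band cycle applies
            # to carrier-borne kinds only
            band = Band("low", 0.0, min(LOW_SUPPRESSION_HIGH_HZ, nyq))
        else:
            band = band_by_name[config.target_bands[i % len(config.target_bands)]]
        class_name = config.classes[i % len(config.classes)]
        if band.low >= nyq:
            logger.warning(
                "target band %s is above Nyquist %g Hz; pair %s left uninformative",
                band.name, nyq, pair.name,
            )
            continue

        anode = recording.channel_index(pair.minuend)
        cathode = recording.channel_index(pair.subtrahend)
        anode_contact = recording.channels[anode].contact_index
        lead = recording.channels[anode].lead_id
        # contacts from the lead tip through the anode: the planted trace is
        # common-mode on every inner pair and survives only on the target pair
        stack = [
            recording.channel_index(ch.channel_id)
            for ch in recording.channels
            if ch.lead_id == lead and ch.contact_index <= anode_contact
        ]

        base_env = make_response_envelope(kind, epoch_t, config.cue_duration_s)
        timeline = np.zeros(n_samples)
        for onset, label in zip(events.onsets_s, events.labels):
            if label != class_name:
                continue
            shift = rng.normal(0.0, config.latency_jitter_s)
            amp = max(0.1, rng.normal(1.0, config.amplitude_jitter_cv))
            start = int(round((onset + shift) * fs))
            lo, hi = max(0, start), min(n_samples, start + epoch_len)
            if hi > lo:
                timeline[lo:hi] = amp * base_env[lo - start : hi - start]

        bipolar_bg = samples[anode] - samples[cathode]
        bg_amp = _band_amplitude_series(bipolar_bg, band, fs)
        m, sd = float(np.mean(bg_amp)), float(np.std(bg_amp))

        if kind == "low_band_suppression":
            # multiplicative suppression of the pair's own band content
            depth_target = config.effect_size * sd
            depth = min(0.9, depth_target / m) if m > 0 else 0.0
            sos = _bandpass_sos(band, fs)
            band_diff = sps.sosfiltfilt(sos, bipolar_bg)
            planted_trace = timeline * depth * band_diff  # timeline <= 0
        else:
            if config.effect_size > 0:
                carrier = _band_carrier(rng, n_samples, band, fs)
                unit_amp = float(np.mean(_band_amplitude_series(carrier, band, fs)))
                delta = config.effect_size * sd
                gain = float(np.sqrt(delta * (2.0 * m + delta))) / unit_amp
            else:
                carrier = np.zeros(n_samples)
                gain = 0.0
            planted_trace = timeline * gain * carrier

        for ch_idx in stack:
            samples[ch_idx] += planted_trace
        if kind == "low_band_suppression":
            # every standard band inside the suppressed range carries the dip
            planted.extend(
                PlantedFeature(pair.name, b.name, kind, config.effect_size, class_name)
                for b in DEFAULT_BANDS
                if b.high <= band.high and b.low < nyq
            )
        else:
            planted.append(
                PlantedFeature(pair.name, band.name, kind, config.effect_size, class_name)
            )

    truth = GroundTruth(planted, events)
    return recording, events, truth


def write_simulation(
    config: SynthConfig, out_dir: str | Path
) -> tuple[Path, Path, Path]:
    """Simulate and persist: EDF recording, events TSV, ground-truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    recording, events, truth = simulate_recording(config)
    edf_path = out_dir / "recording.edf"
    events_path = out_dir / "events.tsv"
    truth_path = out_dir / "ground_truth.json"
    write_recording(recording, edf_path)
    write_events(events, events_path)
    truth.to_json(truth_path)
    return edf_path, events_path, truth_path
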
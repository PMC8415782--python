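"""Integrated amplitude features (IAFs) on a 200 ms window grid.

The feature pipeline converts each bipolar trace into band-amplitude time
series: non-overlapping 200 ms Blackman-tapered windows, a short FFT per
window (5 Hz bin spacing at the 200 ms default), summation of bin amplitudes
within pre-selected frequency bands, a centered 1 s boxcar smoother, and
z-standardization per feature over the whole task. Band intervals are
half-open [low, high) so shared band edges are never double-counted, and the
DC bin is included in the lowest band. All operations are deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from scipy.signal.windows import blackman as _scipy_blackman

from .signalio import RawRecording

logger = logging.getLogger(__name__)

WINDOW_S = 0.2  #: default analysis window length (s); the feature grid step
BOXCAR_SPAN_S = 1.0  #: default boxcar smoother span (s)


@dataclass(frozen=True)
class Band:
    name: str
    low: float  # Hz, inclusive
    high: float  # Hz, exclusive


#: Standard band set: delta/theta, alpha/mu, beta, and three gamma bands of
#: increasing bandwidth (compensating the 1/f fall-off of power density).
DEFAULT_BANDS = (
    Band("delta_theta", 0.0, 10.0),
    Band("alpha_mu", 10.0, 15.0),
    Band("beta", 15.0, 30.0),
    Band("gamma1", 30.0, 100.0),
    Band("gamma2", 100.0, 500.0),
    Band("gamma3", 500.0, 5000.0),
)


@dataclass
class BandSpec:
    """Ordered, pairwise-disjoint half-open frequency bands."""

    bands: tuple[Band, ...] = DEFAULT_BANDS

    def __post_init__(self) -> None:
        self.bands = tuple(self.bands)
        for b in self.bands:
            if not b.low < b.high:
                raise ValueError(f"band {b.name}: low {b.low} must be < high {b.high}")
        ordered = sorted(self.bands, key=lambda b: b.low)
        for a, b in zip(ordered, ordered[1:]):
            if b.low < a.high:
                raise ValueError(f"bands {a.name} and {b.name} overlap")
        self.bands = tuple(ordered)

    def __len__(self) -> int:
        return len(self.bands)

    @property
    def names(self) -> list[str]:
        return [b.name for b in self.bands]

    def for_nyquist(self, nyquist_hz: float) -> "BandSpec":
        """Drop bands at/above Nyquist; truncate a band straddling it."""
        kept: list[Band] = []
        for b in self.bands:
            if b.low >= nyquist_hz:
                logger.warning(
                    "band %s [%g, %g) Hz is above Nyquist %g Hz; dropped",
                    b.name, b.low, b.high, nyquist_hz,
                )
            elif b.high > nyquist_hz:
                logger.warning(
                    "band %s truncated at Nyquist: [%g, %g) -> [%g, %g) Hz",
                    b.name, b.low, b.high, b.low, nyquist_hz,
                )
                kept.append(Band(b.name, b.low, nyquist_hz))
            else:
                kept.append(b)
        if not kept:
            raise ValueError("no band survives below Nyquist")
        return BandSpec(tuple(kept))


@dataclass
class Spectrogram:
    """Per-channel amplitude spectra on the non-overlapping window grid."""

    amplitudes: np.ndarray  # (n_channels, n_windows, n_bins)
    frequencies_hz: np.ndarray
    window_start_times: np.ndarray
    channel_names: list[str]

    @property
    def bin_spacing_hz(self) -> float:
        return float(self.frequencies_hz[1] - self.frequencies_hz[0])


@dataclass
class IAFMatrix:
    """Standardizable integrated-amplitude feature matrix.

    ``values`` is windows x features; each feature is one (bipolar pair,
    band) combination, named ``<pair>|<band>``. When ``standardized`` the
    per-feature mean/SD over all windows are 0/1 and the fitted constants are
    kept for the inverse transform.
    """

    values: np.ndarray
    window_start_times: np.ndarray
    pair_names: list[str]
    band_names: list[str]
    standardized: bool = False
    means: np.ndarray | None = None
    sds: np.ndarray | None = None
    excluded_features: list[str] = field(default_factory=list)

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return [f"{p}|{b}" for p, b in zip(self.pair_names, self.band_names)]

    @property
    def window_step_s(self) -> float:
        return float(self.window_start_times[1] - self.window_start_times[0])

    def unstandardized(self) -> np.ndarray:
        if not self.standardized:
            return self.values.copy()
        return self.values * self.sds + self.means

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=self.values)
            f.create_dataset("window_start_times", data=self.window_start_times)
            f.attrs["pair_names"] = self.pair_names
            f.attrs["band_names"] = self.band_names
            f.attrs["standardized"] = self.standardized
            f.attrs["excluded_features"] = self.excluded_features
            if self.means is not None:
                f.create_dataset("means", data=self.means)
                f.create_dataset("sds", data=self.sds)

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "IAFMatrix":
        with h5py.File(path, "r") as f:
            return cls(
                values=f["values"][()],
                window_start_times=f["window_start_times"][()],
                pair_names=list(f.attrs["pair_names"]),
                band_names=list(f.attrs["band_names"]),
                standardized=bool(f.attrs["standardized"]),
                means=f["means"][()] if "means" in f else None,
                sds=f["sds"][()] if "sds" in f else None,
                excluded_features=list(f.attrs["excluded_features"]),
            )

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            self.values, index=self.window_start_times, columns=self.feature_names
        ).to_csv(path, sep="\t", index_label="window_start_s")


def blackman_window(n: int) -> np.ndarray:
    """Classic symmetric Blackman taper (a0=0.42, a1=0.5, a2=0.08)."""
    if n < 2:
        raise ValueError("Blackman window needs at least 2 samples")
    return _scipy_blackman(n, sym=True)


def window_spectra(bipolar: RawRecording, window_s: float = WINDOW_S) -> Spectrogram:
    """Amplitude spectrogram over non-overlapping Blackman-tapered windows.

    A trailing partial window is discarded. Amplitude is the modulus of the
    one-sided DFT of the tapered segment; bin spacing is 1/window_s Hz.
    """
    n_win_samples = window_s * bipolar.sampling_rate
    if abs(n_win_samples - round(n_win_samples)) > 1e-9:
        raise ValueError(
            f"window of {window_s} s is not a whole number of samples at "
            f"{bipolar.sampling_rate} Hz"
        )
    n_win_samples = int(round(n_win_samples))
    n_windows = bipolar.n_samples // n_win_samples
    if n_windows == 0:
        raise ValueError(
            f"recording of {bipolar.n_samples} samples is shorter than one "
            f"{n_win_samples}-sample window"
        )
    taper = blackman_window(n_win_samples)
    segments = bipolar.samples[:, : n_windows * n_win_samples].reshape(
        bipolar.n_channels, n_windows, n_win_samples
    )
    amplitudes = np.abs(np.fft.rfft(segments * taper, axis=-1))
    freqs = np.fft.rfftfreq(n_win_samples, d=1.0 / bipolar.sampling_rate)
    starts = np.arange(n_windows) * window_s
    return Spectrogram(
        amplitudes=amplitudes,
        frequencies_hz=freqs,
        window_start_times=starts,
        channel_names=[ch.channel_id for ch in bipolar.channels],
    )


def integrate_bands(spectrogram: Spectrogram, bands: BandSpec) -> np.ndarray:
    """Sum bin amplitudes within each band: low <= bin frequency < high.

    Returns an array of shape (n_channels, n_windows, n_bands). Bands are
    first clipped to the spectrogram's Nyquist via :meth:`BandSpec.for_nyquist`.
    """
    usable = bands.for_nyquist(float(spectrogram.frequencies_hz[-1]))
    out = np.empty(spectrogram.amplitudes.shape[:2] + (len(usable),))
    for j, b in enumerate(usable.bands):
        mask = (spectrogram.frequencies_hz >= b.low) & (
            spectrogram.frequencies_hz < b.high
        )
        if not mask.any():
            raise ValueError(f"band {b.name} contains no frequency bin")
        out[..., j] = spectrogram.amplitudes[..., mask].sum(axis=-1)
    return out


def boxcar_smooth(
    series: np.ndarray,
    span_s: float = BOXCAR_SPAN_S,
    step_s: float = WINDOW_S,
    causal: bool = False,
    axis: int = 0,
) -> np.ndarray:
    """Boxcar (moving-average) smoother along the window axis.

    Centered by default, with shrinking windows at the edges (mean of the
    samples actually available). ``causal=True`` averages the current and
    preceding windows only, for real-time parity. The span must be an odd
    multiple of the window step; spans below one step return the input.
    """
    k = span_s / step_s
    if k < 1.0 - 1e-9:
        return np.asarray(series, dtype=float).copy()
    if abs(k - round(k)) > 1e-9 or int(round(k)) % 2 == 0:
        raise ValueError(
            f"boxcar span {span_s} s must be an odd multiple of the {step_s} s step"
        )
    k = int(round(k))
    series = np.asarray(series, dtype=float)
    moved = np.moveaxis(series, axis, 0)
    n = moved.shape[0]
    kernel = np.ones(k)
    flat = moved.reshape(n, -1)
    if causal:
        sums = np.stack([np.convolve(flat[:, j], kernel)[:n] for j in range(flat.shape[1])], axis=1)
        counts = np.convolve(np.ones(n), kernel)[:n]
    else:
        half = k // 2
        sums = np.stack(
            [np.convolve(flat[:, j], kernel)[half : half + n] for j in range(flat.shape[1])],
            axis=1,
        )
        counts = np.convolve(np.ones(n), kernel)[half : half + n]
    out = (sums / counts[:, None]).reshape(moved.shape)
    return np.moveaxis(out, 0, axis)


def standardize(
    values: np.ndarray,
    window_start_times: np.ndarray,
    pair_names: list[str],
    band_names: list[str],
    fit_windows: np.ndarray | None = None,
) -> IAFMatrix:
    """Z-standardize each feature over the task; zero-SD features are excluded.

    ``fit_windows`` optionally restricts the windows used to fit the mean/SD
    (e.g. the training partition, for leakage-free evaluation); the transform
    is still applied to every window.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 2:
        raise ValueError("standardization needs at least 2 windows")
    fit = values if fit_windows is None else values[fit_windows]
    means = fit.mean(axis=0)
    sds = fit.std(axis=0)
    ok = sds > 0
    excluded = [
        f"{p}|{b}" for p, b, good in zip(pair_names, band_names, ok) if not good
    ]
    if excluded:
        logger.warning("excluding %d zero-variance features: %s", len(excluded), excluded)
    kept = np.flatnonzero(ok)
    return IAFMatrix(
        values=(values[:, kept] - means[kept]) / sds[kept],
        window_start_times=np.asarray(window_start_times, dtype=float),
        pair_names=[pair_names[i] for i in kept],
        band_names=[band_names[i] for i in kept],
        standardized=True,
        means=means[kept],
        sds=sds[kept],
        excluded_features=excluded,
    )


def extract_iaf(
    bipolar: RawRecording,
    bands: BandSpec | None = None,
    window_s: float = WINDOW_S,
    boxcar_span_s: float = BOXCAR_SPAN_S,
    causal_boxcar: bool = False,
    standardize_output: bool = True,
    fit_windows: np.ndarray | None = None,
) -> IAFMatrix:
    """Full IAF pipeline on an already-bipolar recording.

    Order of operations: Blackman taper -> DFT -> band integration -> boxcar
    smoothing of the band series -> per-feature z-standardization. The window
    grid is anchored at the recording start.
    """
    bands = bands if bands is not None else BandSpec()
    spec = window_spectra(bipolar, window_s)
    integrated = integrate_bands(spec, bands)  # (channels, windows, bands)
    retained = bands.for_nyquist(float(spec.frequencies_hz[-1]))
    smoothed = boxcar_smooth(
        integrated, span_s=boxcar_span_s, step_s=window_s, causal=causal_boxcar, axis=1
    )
    n_ch, n_win, n_bands = smoothed.shape
    flat = smoothed.transpose(1, 0, 2).reshape(n_win, n_ch * n_bands)
    pair_names = [c for c in spec.channel_names for _ in retained.bands]
    band_names = [b.name for _ in spec.channel_names for b in retained.bands]
    if not standardize_output:
        return IAFMatrix(
            values=flat,
            window_start_times=spec.window_start_times,
            pair_names=pair_names,
            band_names=band_names,
            standardized=False,
        )
    return standardize(
        flat, spec.window_start_times, pair_names, band_names, fit_windows=fit_windows
    )
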
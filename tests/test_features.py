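"""IAF extraction: taper, short FFT, band integration, smoothing, scaling."""

import numpy as np
import pytest

from seegdecode import (
    Band,
    BandSpec,
    ChannelInfo,
    RawRecording,
    blackman_window,
    boxcar_smooth,
    extract_iaf,
    integrate_bands,
    standardize,
    window_spectra,
)
from seegdecode.features import Spectrogram


def recording_from(samples, fs):
    samples = np.atleast_2d(samples)
    channels = [ChannelInfo(f"LA{i + 1}", "LA", i + 1) for i in range(samples.shape[0])]
    return RawRecording(fs, samples, channels)


class TestBlackman:
    @pytest.mark.parametrize("n", [2, 10, 2000, 2001])
    def test_endpoints_vanish(self, n):
        w = blackman_window(n)
        assert abs(w[0]) < 1e-12 and abs(w[-1]) < 1e-12

    @pytest.mark.parametrize("n", [11, 2001])
    def test_odd_midpoint_is_unity(self, n):
        assert blackman_window(n)[n // 2] == pytest.approx(1.0, abs=1e-12)

    def test_symmetry(self):
        w = blackman_window(2001)
        np.testing.assert_allclose(w, w[::-1], atol=1e-15)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            blackman_window(1)


class TestWindowSpectra:
    def test_bin_spacing_5hz_at_10khz(self):
        rec = recording_from(np.random.default_rng(0).standard_normal(20000), 10000.0)
        spec = window_spectra(rec, window_s=0.2)
        assert spec.bin_spacing_hz == pytest.approx(5.0)
        assert spec.amplitudes.shape[1] == 10  # 2 s / 0.2 s windows of 2000 samples

    def test_sinusoid_peaks_at_its_own_bin(self):
        fs = 2000.0
        t = np.arange(int(fs * 1.0)) / fs
        rec = recording_from(np.sin(2 * np.pi * 100.0 * t), fs)
        spec = window_spectra(rec)
        peak_bins = spec.frequencies_hz[np.argmax(spec.amplitudes[0], axis=-1)]
        np.testing.assert_array_equal(peak_bins, 100.0)

    def test_matches_brute_force_dft_oracle(self, rng):
        fs, win = 500.0, 0.2
        n = int(fs * win)
        x = rng.standard_normal(3 * n)
        spec = window_spectra(recording_from(x, fs), window_s=win)
        taper = blackman_window(n)
        for w in range(3):
            seg = x[w * n : (w + 1) * n] * taper
            ks = np.arange(n)
            oracle = np.array(
                [np.abs(np.sum(seg * np.exp(-2j * np.pi * f * ks / n))) for f in range(n // 2 + 1)]
            )
            np.testing.assert_allclose(spec.amplitudes[0, w], oracle, rtol=1e-9, atol=1e-12)

    def test_trailing_partial_window_discarded(self):
        rec = recording_from(np.ones(250), 500.0)  # 2.5 windows
        assert window_spectra(rec).amplitudes.shape[1] == 2

    def test_too_short_recording_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            window_spectra(recording_from(np.ones(50), 500.0))


def flat_spectrogram(freqs):
    freqs = np.asarray(freqs, dtype=float)
    return Spectrogram(
        amplitudes=np.ones((1, 4, len(freqs))),
        frequencies_hz=freqs,
        window_start_times=np.arange(4) * 0.2,
        channel_names=["LA:1-2"],
    )


class TestBandIntegration:
    def test_half_open_interval_on_uniform_spectrum(self):
        spec = flat_spectrogram(np.arange(0, 255, 5))
        out = integrate_bands(spec, BandSpec((Band("low", 0, 10),)))
        np.testing.assert_array_equal(out[0, :, 0], 2.0)  # bins 0 and 5 only

    def test_partition_conserves_total_amplitude(self):
        freqs = np.arange(0, 255, 5)  # Nyquist bin at 250
        spec = flat_spectrogram(freqs)
        bands = BandSpec(
            (Band("a", 0, 30), Band("b", 30, 100), Band("c", 100, 250))
        )
        out = integrate_bands(spec, bands)
        below_nyquist = np.sum(freqs < 250)
        np.testing.assert_allclose(out.sum(axis=-1), below_nyquist)

    def test_band_above_nyquist_dropped(self):
        spec = flat_spectrogram(np.arange(0, 255, 5))
        bands = BandSpec((Band("low", 0, 100), Band("hi", 250, 500)))
        out = integrate_bands(spec, bands)
        assert out.shape[-1] == 1

    def test_band_straddling_nyquist_truncated(self):
        spec = flat_spectrogram(np.arange(0, 255, 5))
        out = integrate_bands(spec, BandSpec((Band("g", 100, 500),)))
        # bins 100..245 inclusive
        np.testing.assert_array_equal(out[0, :, 0], 30.0)

    def test_gamma_burst_dominates_beta(self, rng):
        fs = 1000.0
        t = np.arange(int(fs * 4)) / fs
        burst = np.where((t >= 1.0) & (t < 2.0), np.sin(2 * np.pi * 40 * t), 0.0)
        rec = recording_from(100 * burst + rng.standard_normal(t.size), fs)
        spec = window_spectra(rec)
        bands = BandSpec((Band("beta", 15, 30), Band("gamma1", 30, 100)))
        out = integrate_bands(spec, bands)
        in_burst = (spec.window_start_times >= 1.0) & (spec.window_start_times < 2.0)
        assert np.all(out[0, in_burst, 1] > out[0, in_burst, 0])

    def test_overlapping_bands_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            BandSpec((Band("a", 0, 20), Band("b", 10, 30)))


class TestBoxcar:
    def test_constant_series_unchanged(self):
        x = np.full(50, 3.7)
        np.testing.assert_allclose(boxcar_smooth(x), x)

    def test_unit_impulse_spreads_over_span(self):
        x = np.zeros(30)
        x[10] = 1.0
        out = boxcar_smooth(x, span_s=1.0, step_s=0.2)
        np.testing.assert_allclose(out[8:13], 0.2)
        assert out[7] == 0.0 and out[13] == 0.0

    def test_matches_sliding_mean_oracle(self, rng):
        x = rng.standard_normal(40)
        out = boxcar_smooth(x, span_s=1.0, step_s=0.2)
        oracle = np.array(
            [np.mean(x[max(0, i - 2) : min(40, i + 3)]) for i in range(40)]
        )
        np.testing.assert_allclose(out, oracle, rtol=1e-12)

    def test_causal_mode_uses_only_past(self, rng):
        x = np.zeros(20)
        x[10] = 1.0
        out = boxcar_smooth(x, span_s=1.0, step_s=0.2, causal=True)
        assert np.all(out[:10] == 0.0)
        assert out[10] > 0

    def test_subspan_is_identity(self):
        x = np.arange(10.0)
        np.testing.assert_array_equal(boxcar_smooth(x, span_s=0.1, step_s=0.2), x)

    def test_even_span_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            boxcar_smooth(np.arange(10.0), span_s=0.8, step_s=0.2)


class TestStandardize:
    def test_unit_moments_after_transform(self):
        out = standardize(
            np.array([[1.0], [2.0], [3.0]]), np.arange(3) * 0.2, ["p"], ["b"]
        )
        assert out.values.mean() == pytest.approx(0.0, abs=1e-9)
        assert out.values.std() == pytest.approx(1.0, abs=1e-9)

    def test_constant_feature_flagged_and_excluded(self, caplog):
        vals = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
        with caplog.at_level("WARNING"):
            out = standardize(vals, np.arange(5) * 0.2, ["p1", "p2"], ["b", "b"])
        assert out.n_features == 1
        assert out.excluded_features == ["p2|b"]

    def test_round_trip_through_stored_constants(self, rng):
        vals = 5.0 + 3.0 * rng.standard_normal((20, 4))
        out = standardize(vals, np.arange(20) * 0.2, ["p"] * 4, list("abcd"))
        np.testing.assert_allclose(out.unstandardized(), vals, atol=1e-12)


class TestExtractIaf:
    def test_feature_count_three_leads_six_bands(self):
        rng = np.random.default_rng(0)
        channels = [
            ChannelInfo(f"{lead}:{i}-{i + 1}", lead, i)
            for lead in ("LA", "LB", "LC")
            for i in range(1, 16)
        ]
        bipolar = RawRecording(
            10000.0, rng.standard_normal((45, 20000)), channels
        )
        iaf = extract_iaf(bipolar)
        assert iaf.n_features == 45 * 6  # all six bands live below 5 kHz Nyquist

    def test_pure_function(self, small_sim):
        from seegdecode import apply_montage, build_bipolar_montage

        _, recording, _, _ = small_sim
        bipolar = apply_montage(recording, build_bipolar_montage(recording))
        a = extract_iaf(bipolar)
        b = extract_iaf(bipolar)
        np.testing.assert_array_equal(a.values, b.values)

    def test_window_count_independent_of_channels(self, rng):
        fs = 500.0
        for n_ch in (1, 3):
            channels = [ChannelInfo(f"LA{i+1}", "LA", i + 1) for i in range(n_ch)]
            rec = RawRecording(fs, rng.standard_normal((n_ch, int(fs * 3.1))), channels)
            iaf = extract_iaf(rec, standardize_output=False)
            assert iaf.n_windows == 15  # floor(3.1 / 0.2)

    def test_planted_pair_shows_cue_locked_average(self, small_iaf):
        iaf, events, truth = small_iaf
        planted = next(
            f for f in truth.informative_features if f.response_kind == "phasic_onset"
        )
        col = iaf.feature_names.index(planted.feature_name)
        step = iaf.window_step_s
        epochs = []
        for onset, label in zip(events.onsets_s, events.labels):
            if label != planted.class_name:
                continue
            start = int(onset / step)
            epochs.append(iaf.values[start : start + 22, col])
        avg = np.mean(epochs, axis=0)
        # early-cue peak well above the pre-offset tail
        assert avg[:8].max() > avg.mean() + 1.0

    def test_hdf5_round_trip(self, small_iaf, tmp_path):
        iaf, _, _ = small_iaf
        iaf.to_hdf5(tmp_path / "iaf.h5")
        back = type(iaf).from_hdf5(tmp_path / "iaf.h5")
        np.testing.assert_array_equal(back.values, iaf.values)
        assert back.feature_names == iaf.feature_names
        assert back.standardized
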
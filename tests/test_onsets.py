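"""Channel separation, marker enhancement and onset extraction."""

import numpy as np
import pytest

import tapalign as ta
from tapalign.config import QualityError
from tapalign.onsets import _envelope
from tapalign.stimulus import _ms_to_samples


def naive_onset_oracle(samples: np.ndarray, fs: int, threshold_frac: float,
                       window_ms: float, gap_ms: float) -> np.ndarray:
    """Scan-every-sample reference implementation of the onset extractor.

    Rectify, smooth with a causal moving average (zeros before the signal),
    find the first sample of each supra-threshold excursion, merge onsets
    closer than the refractory gap. Deliberately written as an explicit
    per-sample loop, independent of the vectorized implementation.
    """
    w = max(1, round(window_ms * fs / 1000))
    rect = np.abs(samples)
    env = np.empty_like(rect)
    for i in range(rect.size):
        lo = max(0, i + 1 - w)
        env[i] = rect[lo:i + 1].sum() / w
    thresh = threshold_frac * env.max()
    if env.max() <= 0:
        return np.array([])
    gap = round(gap_ms * fs / 1000)
    onsets, prev_above, last = [], False, None
    for i in range(env.size):
        above = env[i] >= thresh
        if above and not prev_above:
            if last is None or i - last >= gap:
                onsets.append(i)
                last = i
        prev_above = above
    return np.asarray(onsets, dtype=float) * 1000.0 / fs


def click_train(times_ms, fs=44100, total_ms=3000.0, amp=0.8, dur_ms=5.0):
    samples = np.zeros(int(total_ms * fs / 1000))
    n = int(dur_ms * fs / 1000)
    burst = amp * np.sin(2 * np.pi * 1000 * np.arange(n) / fs)
    for t in times_ms:
        i = int(round(t * fs / 1000))
        samples[i:i + n] += burst
    return ta.Waveform(samples, fs)


class TestBandpass:
    def test_center_tone_within_1db(self, config):
        fs = config.sample_rate
        f0 = np.sqrt(200 * 340)
        t = np.arange(fs) / fs
        x = ta.Waveform(0.5 * np.sin(2 * np.pi * f0 * t), fs)
        y = ta.bandpass(x, 200, 340)
        mid = slice(fs // 10, -fs // 10)
        ratio = np.sqrt(np.mean(y.samples[mid] ** 2)
                        / np.mean(x.samples[mid] ** 2))
        assert abs(20 * np.log10(ratio)) < 1.0

    def test_octave_outside_attenuated_40db(self, config):
        fs = config.sample_rate
        t = np.arange(fs) / fs
        x = ta.Waveform(0.5 * np.sin(2 * np.pi * 680 * t), fs)
        y = ta.bandpass(x, 200, 340)
        mid = slice(fs // 10, -fs // 10)
        ratio = np.sqrt(np.mean(y.samples[mid] ** 2)
                        / np.mean(x.samples[mid] ** 2))
        assert 20 * np.log10(ratio) < -40.0

    def test_zero_phase_impulse_response_is_symmetric(self, config):
        fs = config.sample_rate
        x = np.zeros(fs)
        x[fs // 2] = 1.0
        y = ta.bandpass(ta.Waveform(x, fs), 200, 340).samples
        k = 400  # samples; the response is negligible farther out
        left = y[fs // 2 - k: fs // 2]
        right = y[fs // 2 + 1: fs // 2 + 1 + k]
        np.testing.assert_allclose(left[::-1], right, atol=1e-6)
        assert y.size == x.size


class TestExtractOnsets:
    def test_single_click_located_precisely(self, config):
        wave = click_train([1000.0])
        onsets = ta.extract_onsets(wave, config)
        assert onsets.size == 1
        assert 999.0 <= onsets[0] <= 1002.0

    def test_two_clicks_give_two_onsets(self, config):
        onsets = ta.extract_onsets(click_train([500.0, 1000.0]), config)
        assert onsets.size == 2
        assert onsets[1] - onsets[0] == pytest.approx(500.0, abs=2.0)

    def test_echo_within_refractory_merged(self, config):
        onsets = ta.extract_onsets(click_train([1000.0, 1005.0]), config)
        assert onsets.size == 1
        assert onsets[0] == pytest.approx(1000.0, abs=2.0)

    def test_silence_yields_empty_list(self, config):
        wave = ta.Waveform(np.zeros(44100), 44100)
        assert ta.extract_onsets(wave, config).size == 0

    def test_matches_naive_oracle_exactly(self, config):
        """On hand-placed bursts the vectorized extractor must equal the
        per-sample scanning oracle, sample for sample."""
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(100, 2800, 8))  # some closer than the
        wave = click_train(times)                   # refractory gap: exercises merging
        got = ta.extract_onsets(wave, config)
        want = naive_onset_oracle(wave.samples, wave.sample_rate,
                                  config.onset_threshold_frac,
                                  config.envelope_window_ms,
                                  config.min_onset_gap_ms)
        np.testing.assert_array_equal(got, want)

    @pytest.mark.parametrize("delta_ms", [30.0, 250.0, 1000.0])
    def test_shift_equivariance(self, config, delta_ms):
        wave = click_train([400.0, 900.0])
        base = ta.extract_onsets(wave, config)
        shifted = ta.extract_onsets(wave.delayed(delta_ms), config)
        np.testing.assert_allclose(shifted, base + delta_ms, atol=0.05)

    @pytest.mark.parametrize("scale", [0.1, 0.25, 1.0])
    def test_amplitude_invariance(self, config, scale):
        wave = click_train([400.0, 900.0])
        scaled = ta.Waveform(wave.samples * scale, wave.sample_rate)
        np.testing.assert_allclose(ta.extract_onsets(scaled, config),
                                   ta.extract_onsets(wave, config),
                                   atol=1.0)


class TestEnhanceMarkers:
    def _burst(self, low, high, at_ms, fs, total_ms=2000.0, dur_ms=250.0):
        from scipy import signal as sp
        rng = np.random.default_rng(1)
        n = int(total_ms * fs / 1000)
        x = np.zeros(n)
        nb = int(dur_ms * fs / 1000)
        sos = sp.butter(6, [low, high], btype="bandpass", fs=fs, output="sos")
        burst = sp.sosfilt(sos, rng.standard_normal(3 * nb))[-nb:]
        burst /= np.max(np.abs(burst))
        i = int(at_ms * fs / 1000)
        x[i:i + nb] = burst
        return x, i, nb

    def test_marker_like_burst_boosted(self, config):
        fs = config.sample_rate
        x, i, nb = self._burst(*config.marker_band, 800.0, fs)
        wave = ta.Waveform(x, fs)
        marker_ch = ta.bandpass(wave, *config.marker_band)
        test_ch = ta.bandpass(wave, *config.test_band)
        out = ta.enhance_markers(marker_ch, test_ch, config)
        gain = np.abs(out.samples[i:i + nb]) / \
            np.maximum(np.abs(marker_ch.samples[i:i + nb]), 1e-12)
        frac_boosted = np.mean(np.isclose(gain, config.boost_gain))
        assert frac_boosted >= 0.9

    def test_broadband_tap_like_burst_not_boosted(self, config):
        fs = config.sample_rate
        x, i, nb = self._burst(*config.tap_band, 800.0, fs)
        wave = ta.Waveform(x, fs)
        marker_ch = ta.bandpass(wave, *config.marker_band)
        test_ch = ta.bandpass(wave, *config.test_band)
        out = ta.enhance_markers(marker_ch, test_ch, config)
        gain = np.abs(out.samples) / np.maximum(np.abs(marker_ch.samples),
                                                1e-12)
        assert not np.any(np.isclose(gain, config.boost_gain))

    def test_silence_stays_silent(self, config):
        silent = ta.Waveform(np.zeros(44100), 44100)
        out = ta.enhance_markers(silent, silent, config)
        np.testing.assert_array_equal(out.samples, 0.0)


class TestSplitChannels:
    def test_all_channels_same_length(self, config, simulated_trial):
        rec = simulated_trial["recording"]
        ch = ta.split_channels(rec, config)
        for w in (ch.tap_channel, ch.marker_channel, ch.test_channel,
                  ch.enhanced_marker_channel):
            assert w.samples.size == rec.samples.size
            assert w.sample_rate == rec.sample_rate

    def test_too_short_recording_rejected(self, config):
        short = ta.Waveform(np.zeros(1000), config.sample_rate)
        with pytest.raises(QualityError):
            ta.split_channels(short, config)


class TestDetectMarkers:
    def test_clean_trial_recovers_all_markers_within_2ms(
            self, config, simulated_trial):
        markers, err = ta.detect_markers(simulated_trial["recording"],
                                         simulated_trial["prepared"], config)
        truth = simulated_trial["truth"].marker_onsets
        assert markers.size == truth.size
        np.testing.assert_allclose(markers, truth, atol=2.0)
        assert err <= 2.0

    def test_attenuated_end_block_fails(self, config, prepared_metronome):
        """Simulated noise cancellation: end-block markers crushed x0.01."""
        fs = config.sample_rate
        samples = prepared_metronome.waveform.samples.copy()
        for m in prepared_metronome.marker_onsets[config.markers_per_block:]:
            i0 = _ms_to_samples(m, fs)
            i1 = i0 + _ms_to_samples(config.marker_duration_ms, fs)
            samples[i0:i1] *= 0.01
        rec = ta.Waveform(samples, fs)
        with pytest.raises(QualityError, match="markers undetected"):
            ta.detect_markers(rec, prepared_metronome, config)

    def test_prepended_silence_shifts_markers_only(
            self, config, simulated_trial):
        rec = simulated_trial["recording"]
        markers, err = ta.detect_markers(rec, simulated_trial["prepared"],
                                         config)
        shifted_rec = rec.delayed(300.0)
        markers2, err2 = ta.detect_markers(shifted_rec,
                                           simulated_trial["prepared"], config)
        np.testing.assert_allclose(markers2, markers + 300.0, atol=0.05)
        assert err2 == pytest.approx(err, abs=0.05)
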
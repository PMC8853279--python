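"""Marker synthesis, stimulus filtering and trial assembly."""

import numpy as np
import pytest

import tapalign as ta
from tapalign.config import ConfigError, InputError


def band_energy_fraction(wave: ta.Waveform, low: float, high: float) -> float:
    """Periodogram oracle: fraction of spectral power inside [low, high] Hz."""
    freqs = np.fft.rfftfreq(wave.samples.size, 1.0 / wave.sample_rate)
    power = np.abs(np.fft.rfft(wave.samples)) ** 2
    return power[(freqs >= low) & (freqs <= high)].sum() / power.sum()


def tone(freq: float, duration_s: float, fs: int, amp: float = 0.5) -> ta.Waveform:
    t = np.arange(int(duration_s * fs)) / fs
    return ta.Waveform(amp * np.sin(2 * np.pi * freq * t), fs)


class TestMarkerSound:
    def test_duration_and_peak(self, config):
        m = ta.generate_marker_sound(config, seed=0)
        assert m.samples.size == round(config.marker_duration_ms
                                       * config.sample_rate / 1000)
        assert np.max(np.abs(m.samples)) == pytest.approx(
            config.marker_amplitude)

    def test_energy_concentrated_in_marker_band(self, config):
        for seed in (0, 1, 2):
            m = ta.generate_marker_sound(config, seed=seed)
            assert band_energy_fraction(m, *config.marker_band) >= 0.95

    def test_same_seed_is_bit_identical(self, config):
        a = ta.generate_marker_sound(config, seed=7)
        b = ta.generate_marker_sound(config, seed=7)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_marker_survives_its_own_extraction(self, config):
        """A lone marker block run through the marker-channel filter and the
        onset extractor must give back every marker within 2 ms."""
        from tapalign.stimulus import _marker_block
        rng = np.random.default_rng(0)
        block, offsets = _marker_block(config, rng)
        pad = np.zeros(int(0.3 * config.sample_rate))
        wave = ta.Waveform(np.concatenate([pad, block, pad]),
                           config.sample_rate)
        channel = ta.bandpass(wave, *config.marker_band)
        onsets = ta.extract_onsets(channel, config)
        expected = offsets + 300.0
        assert onsets.size == config.markers_per_block
        np.testing.assert_allclose(onsets, expected, atol=2.0)


class TestFilterStimulus:
    def test_passband_tone_preserved_within_1db(self, config):
        x = tone(1000.0, 1.0, config.sample_rate)
        y = ta.filter_stimulus(x, config)
        mid = slice(4410, -4410)  # avoid edge transients
        ratio = np.sqrt(np.mean(y.samples[mid] ** 2)
                        / np.mean(x.samples[mid] ** 2))
        assert abs(20 * np.log10(ratio)) < 1.0

    def test_stopband_tone_removed_by_40db(self, config):
        x = tone(200.0, 1.0, config.sample_rate)
        y = ta.filter_stimulus(x, config)
        mid = slice(4410, -4410)
        ratio = np.sqrt(np.mean(y.samples[mid] ** 2)
                        / np.mean(x.samples[mid] ** 2))
        assert 20 * np.log10(ratio) < -40.0

    def test_silence_stays_silent(self, config):
        x = ta.Waveform(np.zeros(1000), config.sample_rate)
        y = ta.filter_stimulus(x, config)
        np.testing.assert_allclose(y.samples, 0.0, atol=1e-12)

    def test_sample_rate_mismatch_rejected(self, config):
        with pytest.raises(ConfigError):
            ta.filter_stimulus(tone(1000, 0.1, 22050), config)


class TestPrepareStimulus:
    def test_onsets_shifted_by_constant(self, config):
        stim, onsets = ta.make_isochronous_stimulus(500.0, 3, config)
        prepared = ta.prepare_stimulus(stim, onsets, config, seed=0)
        shift = prepared.stim_onsets - onsets
        np.testing.assert_allclose(shift, shift[0])
        assert shift[0] == pytest.approx(config.block_duration_ms
                                         + config.padding_ms)

    def test_marker_count_is_two_blocks(self, config):
        stim, onsets = ta.make_isochronous_stimulus(500.0, 3, config)
        prepared = ta.prepare_stimulus(stim, onsets, config, seed=0)
        assert prepared.marker_onsets.size == 2 * config.markers_per_block
        # every stimulus onset lies strictly between the marker blocks
        last_begin = prepared.marker_onsets[config.markers_per_block - 1]
        first_end = prepared.marker_onsets[config.markers_per_block]
        assert np.all(prepared.stim_onsets > last_begin)
        assert np.all(prepared.stim_onsets < first_end)

    def test_total_duration_is_concatenation(self, config):
        stim, onsets = ta.make_isochronous_stimulus(500.0, 3, config)
        prepared = ta.prepare_stimulus(stim, onsets, config, seed=0)
        expected = (2 * config.block_duration_ms + 2 * config.padding_ms
                    + stim.duration_ms)
        assert prepared.waveform.duration_ms == pytest.approx(expected, abs=0.1)

    def test_shift_equivariance(self, config):
        """Delaying the input stimulus delays stim_onsets by the same amount."""
        stim, onsets = ta.make_isochronous_stimulus(500.0, 3, config)
        delta = 200.0
        delayed = stim.delayed(delta)
        a = ta.prepare_stimulus(stim, onsets, config, seed=0)
        b = ta.prepare_stimulus(delayed, onsets + delta, config, seed=0)
        np.testing.assert_allclose(b.stim_onsets, a.stim_onsets + delta,
                                   atol=1e-9)

    def test_onsets_outside_stimulus_rejected(self, config):
        stim, _ = ta.make_isochronous_stimulus(500.0, 3, config)
        with pytest.raises(InputError, match="9999"):
            ta.prepare_stimulus(stim, np.array([0.0, 9999.0]), config)

    def test_empty_stimulus_rejected(self, config):
        with pytest.raises(InputError):
            ta.Waveform(np.array([]), config.sample_rate)

    def test_prepared_stimulus_barely_leaks_into_tap_band(self, config):
        """Outside the marker segments, the prepared waveform must be nearly
        invisible to the tapping channel."""
        stim, onsets = ta.make_isochronous_stimulus(500.0, 10, config)
        prepared = ta.prepare_stimulus(stim, onsets, config, seed=0)
        tap_view = ta.bandpass(prepared.waveform, *config.tap_band)
        fs = config.sample_rate
        mask = np.ones(tap_view.samples.size, dtype=bool)
        for m in prepared.marker_onsets:
            i0 = int((m - 50) * fs / 1000)
            i1 = int((m + config.marker_duration_ms + 50) * fs / 1000)
            mask[max(i0, 0):i1] = False
        rms_tap = np.sqrt(np.mean(tap_view.samples[mask] ** 2))
        rms_all = np.sqrt(np.mean(prepared.waveform.samples ** 2))
        assert rms_tap < 0.01 * rms_all


class TestIsochronousStimulus:
    def test_onsets_are_a_perfect_grid(self, config):
        _, onsets = ta.make_isochronous_stimulus(500.0, 100, config)
        assert onsets.size == 100
        assert onsets[0] == 0.0
        np.testing.assert_allclose(np.diff(onsets), 500.0, atol=0.05)
        assert onsets[-1] == pytest.approx(49500.0, abs=0.05)

    def test_single_click(self, config):
        wave, onsets = ta.make_isochronous_stimulus(500.0, 1, config)
        np.testing.assert_allclose(onsets, [0.0])
        assert wave.samples.size > 0

    def test_click_survives_stimulus_filtering(self, config):
        wave, _ = ta.make_isochronous_stimulus(500.0, 4, config)
        filtered = ta.filter_stimulus(wave, config)
        assert np.sqrt(np.mean(filtered.samples ** 2)) > \
            0.8 * np.sqrt(np.mean(wave.samples ** 2))

    @pytest.mark.parametrize("bad", [{"ioi_ms": -5.0}, {"n_clicks": 0},
                                     {"ioi_ms": 5.0}])
    def test_degenerate_parameters_rejected(self, config, bad):
        kwargs = {"ioi_ms": 500.0, "n_clicks": 10, **bad}
        with pytest.raises(ConfigError):
            ta.make_isochronous_stimulus(config=config, **kwargs)
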
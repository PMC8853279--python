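"""Stimulus preparation: marker synthesis, stimulus filtering, assembly.

A trial waveform is laid out as

    [marker block] [padding] [filtered stimulus] [padding] [marker block]

where each block holds ``markers_per_block`` marker sounds at known
positions. The stimulus onset list is shifted by the same constant offset as
the stimulus audio, so the known onsets stay valid on the prepared timeline.
Stimulus filtering is zero-phase so that it introduces no group delay and
the stated onset times remain correct after filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .config import ConfigError, InputError, PipelineConfig, Waveform

__all__ = [
    "PreparedStimulus",
    "generate_marker_sound",
    "filter_stimulus",
    "prepare_stimulus",
    "make_isochronous_stimulus",
]


@dataclass(frozen=True)
class PreparedStimulus:
    """A marker-bearing trial waveform plus its known event times.

    ``stim_onsets`` and ``marker_onsets`` are in ms from the start of
    ``waveform``. There are exactly ``2 * markers_per_block`` marker onsets:
    the beginning block and the end block.
    """

    waveform: Waveform
    stim_onsets: np.ndarray
    marker_onsets: np.ndarray
    config: PipelineConfig

    def __post_init__(self) -> None:
        object.__setattr__(self, "stim_onsets",
                           np.asarray(self.stim_onsets, dtype=np.float64))
        object.__setattr__(self, "marker_onsets",
                           np.asarray(self.marker_onsets, dtype=np.float64))

    def to_dict(self) -> dict:
        return {
            "stim_onsets": [float(x) for x in self.stim_onsets],
            "marker_onsets": [float(x) for x in self.marker_onsets],
            "config": self.config.to_dict(),
        }


def _ms_to_samples(ms: float, sample_rate: int) -> int:
    return int(round(ms * sample_rate / 1000.0))


def _bandpass_sos(low: float, high: float, sample_rate: int, order: int = 4):
    nyq = sample_rate / 2.0
    if not (0 < low < high < nyq):
        raise ConfigError(f"band ({low}, {high}) Hz invalid for fs={sample_rate}")
    return signal.butter(order, [low, high], btype="bandpass", fs=sample_rate,
                         output="sos")


def generate_marker_sound(config: PipelineConfig,
                          seed: int | np.random.Generator = 0) -> Waveform:
    """Synthesize one marker sound.

    An equal mixture of band-filtered white noise and a pure tone at the
    geometric centre of ``marker_band`` (~261 Hz for 200-340), with a sharp
    attack (the onset is the first sample) and a short raised-cosine fade at
    the tail. Peak amplitude equals ``marker_amplitude``; at the default
    duration >=95 % of the spectral energy falls inside ``marker_band``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    fs = config.sample_rate
    n = _ms_to_samples(config.marker_duration_ms, fs)
    if n < 8:
        raise ConfigError("marker_duration_ms too short for the sample rate")
    low, high = config.marker_band

    sos = _bandpass_sos(low, high, fs, order=6)
    # steady-state chunk of causally filtered noise: the first sample already
    # has full amplitude, keeping the physical attack sharp and detectable
    noise = signal.sosfilt(sos, rng.standard_normal(3 * n))[-n:]
    noise /= np.max(np.abs(noise))

    f_tone = float(np.sqrt(low * high))
    t = np.arange(n) / fs
    tone = np.sin(2 * np.pi * f_tone * t)

    out = 0.5 * noise + 0.5 * tone
    # short fade-out only: the attack must stay sharp so the physical start
    # of the sound is the detectable onset
    n_fade = min(_ms_to_samples(5.0, fs), n // 4)
    out[-n_fade:] *= 0.5 * (1 + np.cos(np.linspace(0, np.pi, n_fade)))
    out *= config.marker_amplitude / np.max(np.abs(out))
    return Waveform(out, fs)


def filter_stimulus(wave: Waveform, config: PipelineConfig) -> Waveform:
    """Remove the tapping frequency range from a stimulus.

    Zero-phase band-stop over ``stim_stopband`` (default 50-500 Hz), so the
    stimulus cannot mask the participant's taps in the recording. Energy an
    octave or more above the stopband passes within 1 dB; deep-stopband
    tones (e.g. 200 Hz) are attenuated by well over 40 dB.
    """
    if wave.sample_rate != config.sample_rate:
        raise ConfigError(
            f"stimulus sample rate {wave.sample_rate} != config {config.sample_rate}")
    low, high = config.stim_stopband
    sos = signal.butter(4, [low, high], btype="bandstop",
                        fs=config.sample_rate, output="sos")
    out = signal.sosfiltfilt(sos, wave.samples)
    peak = np.max(np.abs(out))
    if peak > 1.0:
        out = out / peak
    return Waveform(out, wave.sample_rate)


def _marker_block(config: PipelineConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Render one marker block; returns (samples, marker offsets in ms)."""
    fs = config.sample_rate
    offsets = config.block_marker_offsets_ms()
    n_block = _ms_to_samples(config.block_duration_ms, fs)
    block = np.zeros(n_block)
    for off in offsets:
        marker = generate_marker_sound(config, rng).samples
        i0 = _ms_to_samples(off, fs)
        block[i0:i0 + marker.size] = marker[: n_block - i0]
    return block, offsets


def prepare_stimulus(stim: Waveform, onsets: np.ndarray, config: PipelineConfig,
                     seed: int = 0) -> PreparedStimulus:
    """Assemble the playback waveform: marker blocks around the filtered stimulus.

    Parameters
    ----------
    stim : Waveform
        Raw stimulus audio (a metronome, or music).
    onsets : array of ms
        Known stimulus onsets, in ms from the start of ``stim``. They are
        never extracted from audio; they are shifted onto the prepared
        timeline and later realigned via the markers ("virtual onsets").
    """
    onsets = np.asarray(onsets, dtype=np.float64)
    if stim.samples.size == 0:
        raise InputError("empty stimulus")
    bad = onsets[(onsets < 0) | (onsets > stim.duration_ms)]
    if bad.size:
        raise InputError(f"onsets outside the stimulus span: {bad.tolist()}")
    if stim.sample_rate != config.sample_rate:
        raise ConfigError("stimulus sample rate does not match the config")

    fs = config.sample_rate
    rng = np.random.default_rng(seed)
    filtered = filter_stimulus(stim, config)
    block_a, offs = _marker_block(config, rng)
    block_b, _ = _marker_block(config, rng)
    pad = np.zeros(_ms_to_samples(config.padding_ms, fs))

    parts = [block_a, pad, filtered.samples, pad, block_b]
    waveform = Waveform(np.concatenate(parts), fs)

    # offsets measured in samples, converted back to ms, so recorded event
    # times land exactly on the sample grid of the waveform
    to_ms = 1000.0 / fs
    i_stim = block_a.size + pad.size
    i_end_block = i_stim + filtered.samples.size + pad.size
    shift_ms = i_stim * to_ms
    marker_onsets = np.concatenate([
        np.array([_ms_to_samples(o, fs) for o in offs]) * to_ms,
        (i_end_block + np.array([_ms_to_samples(o, fs) for o in offs])) * to_ms,
    ])
    return PreparedStimulus(waveform, onsets + shift_ms, marker_onsets, config)


def make_isochronous_stimulus(ioi_ms: float, n_clicks: int,
                              config: PipelineConfig,
                              click_freq_hz: float = 3000.0,
                              click_duration_ms: float = 10.0,
                              amplitude: float = 0.8) -> tuple[Waveform, np.ndarray]:
    """Build a metronome click train with onsets [0, ioi, 2*ioi, ...].

    The click is a short high-frequency burst well above ``stim_stopband``,
    so it survives stimulus filtering and never leaks into the tapping
    channel. Returns the waveform and the ground-truth click onsets (ms).
    """
    if ioi_ms <= 0:
        raise ConfigError(f"ioi_ms must be positive, got {ioi_ms}")
    if n_clicks < 1:
        raise ConfigError("n_clicks must be >= 1")
    if ioi_ms <= click_duration_ms and n_clicks > 1:
        raise ConfigError("ioi_ms must exceed the click duration")
    fs = config.sample_rate
    n_click = _ms_to_samples(click_duration_ms, fs)
    t = np.arange(n_click) / fs
    click = amplitude * np.sin(2 * np.pi * click_freq_hz * t)
    # Hann envelope keeps the click's spectrum tightly around click_freq_hz
    # (an abrupt attack would splash energy down into the tapping band)
    click *= np.hanning(n_click)
    onsets = np.arange(n_clicks, dtype=np.float64) * ioi_ms
    total = _ms_to_samples(onsets[-1], fs) + n_click + _ms_to_samples(50.0, fs)
    samples = np.zeros(total)
    for onset in onsets:
        i0 = _ms_to_samples(onset, fs)
        samples[i0:i0 + n_click] += click
    # report onsets on the sample grid
    grid_onsets = np.array([_ms_to_samples(o, fs) for o in onsets]) * 1000.0 / fs
    return Waveform(samples, fs), grid_onsets
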
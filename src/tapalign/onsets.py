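"""Channel separation and onset extraction from a mono trial recording.

The free-field recording mixes the played stimulus, the marker sounds and
the participant's tap sounds in one channel. Each element occupies its own
frequency range, so zero-phase band-pass filters split the recording into a
tapping channel, a marker channel and a test channel. The marker channel is
then *enhanced*: its amplitude is boosted only where the marker band holds
clearly more energy than the test band one octave below — true for marker
sounds (all energy in the marker band) but not for broadband taps or noise.
Onsets are the first samples of supra-threshold envelope excursions, with
the threshold set relative to the channel maximum so that the extraction is
invariant to the overall recording gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .config import ConfigError, PipelineConfig, QualityError, Waveform
from .stimulus import PreparedStimulus, _bandpass_sos, _ms_to_samples

__all__ = [
    "ChannelSet",
    "bandpass",
    "split_channels",
    "enhance_markers",
    "extract_onsets",
    "detect_markers",
]


@dataclass(frozen=True)
class ChannelSet:
    """The band-separated views of one recording (all same length/rate)."""

    tap_channel: Waveform
    marker_channel: Waveform
    test_channel: Waveform
    enhanced_marker_channel: Waveform


def bandpass(wave: Waveform, low_hz: float, high_hz: float,
             order: int = 4) -> Waveform:
    """Zero-phase Butterworth band-pass; output has the input's length.

    Applied forward and backward (``sosfiltfilt``) so there is no group
    delay: an impulse comes out symmetric about its original position and
    onset times are not shifted.
    """
    sos = _bandpass_sos(low_hz, high_hz, wave.sample_rate, order=order)
    return Waveform(signal.sosfiltfilt(sos, wave.samples), wave.sample_rate)


def _sliding_energy(x: np.ndarray, window: int) -> np.ndarray:
    """Causal moving average of x**2 over ``window`` samples.

    The signal is treated as zero before its first sample, so the estimate
    ramps up smoothly at the start instead of amplifying edge transients.
    """
    c = np.concatenate([[0.0], np.cumsum(x * x)])
    idx = np.arange(1, x.size + 1)
    lo = np.maximum(idx - window, 0)
    return (c[idx] - c[lo]) / window


def _envelope(x: np.ndarray, window: int) -> np.ndarray:
    """Causal moving average of |x| (rectify-and-smooth), zero-padded past."""
    c = np.concatenate([[0.0], np.cumsum(np.abs(x))])
    idx = np.arange(1, x.size + 1)
    lo = np.maximum(idx - window, 0)
    return (c[idx] - c[lo]) / window


def _boost_mask(marker_channel: Waveform, test_channel: Waveform,
                config: PipelineConfig) -> np.ndarray:
    """Boolean mask of samples where marker-band dominance is sustained.

    Sliding-window energies are normalised by their band widths (energy
    *density* per Hz), so a spectrally flat broadband event scores a ratio
    near 1 regardless of how wide each band is, while a marker — with all
    its energy inside the marker band and none an octave below — scores far
    above any reasonable threshold. A sample is marked only when the
    density ratio exceeds ``ratio_threshold`` for the majority of the
    following ``enhance_window_ms``: isolated excursions of the noisy
    energy ratio are thereby rejected, and only dominance sustained on the
    marker-duration timescale survives.
    """
    if marker_channel.samples.size != test_channel.samples.size:
        raise ConfigError("marker and test channels must have equal length")
    fs = marker_channel.sample_rate
    w = max(1, _ms_to_samples(config.enhance_window_ms, fs))
    bw_m = config.marker_band[1] - config.marker_band[0]
    bw_t = config.test_band[1] - config.test_band[0]
    d_m = _sliding_energy(marker_channel.samples, w) / bw_m
    d_t = _sliding_energy(test_channel.samples, w) / bw_t
    raw = d_m > config.ratio_threshold * d_t
    # forward-looking majority vote over one window; looking ahead keeps
    # the start of a boost region at (or just before) the marker attack
    c = np.concatenate([[0], np.cumsum(raw)])
    idx = np.arange(raw.size)
    hi = np.minimum(idx + w, raw.size)
    vote = (c[hi] - c[idx]) / np.maximum(hi - idx, 1)
    return vote > 0.5


def enhance_markers(marker_channel: Waveform, test_channel: Waveform,
                    config: PipelineConfig) -> Waveform:
    """Boost the marker channel only where markers plausibly are.

    Sliding-window energy densities of the marker and test bands are
    compared sample-wise (see ``_boost_mask``); the marker channel is
    multiplied by ``boost_gain`` where the marker band dominates in a
    sustained way and by ``attenuation_gain`` elsewhere. Taps are
    broadband, so their energy density is similar in both bands and they
    are never boosted; markers have essentially no test-band energy and
    are.
    """
    mask = _boost_mask(marker_channel, test_channel, config)
    gain = np.where(mask, config.boost_gain, config.attenuation_gain)
    return Waveform(marker_channel.samples * gain, marker_channel.sample_rate)


def split_channels(recording: Waveform, config: PipelineConfig) -> ChannelSet:
    """Split a mono recording into tap / marker / test / enhanced channels."""
    if recording.sample_rate != config.sample_rate:
        n_out = int(round(recording.samples.size
                          * config.sample_rate / recording.sample_rate))
        recording = Waveform(signal.resample(recording.samples, n_out),
                             config.sample_rate)
    if recording.duration_ms < config.block_duration_ms:
        raise QualityError("recording shorter than one marker block")
    tap = bandpass(recording, *config.tap_band)
    marker = bandpass(recording, *config.marker_band)
    test = bandpass(recording, *config.test_band)
    enhanced = enhance_markers(marker, test, config)
    return ChannelSet(tap, marker, test, enhanced)


def extract_onsets(wave: Waveform, config: PipelineConfig,
                   threshold_frac: float | None = None) -> np.ndarray:
    """Detect event onsets as first samples of supra-threshold excursions.

    The rectified signal is smoothed with a causal ``envelope_window_ms``
    moving average; the threshold is ``onset_threshold_frac`` times the
    envelope maximum (relative, hence gain-invariant). Excursions closer
    than ``min_onset_gap_ms`` are merged, keeping the first onset. Returns
    onset times in ms from the start of ``wave``; silence yields an empty
    list.
    """
    fs = wave.sample_rate
    frac = config.onset_threshold_frac if threshold_frac is None else threshold_frac
    w = max(1, _ms_to_samples(config.envelope_window_ms, fs))
    env = _envelope(wave.samples, w)
    peak = env.max()
    if peak <= 0:
        return np.array([], dtype=np.float64)
    above = env >= frac * peak
    starts = np.flatnonzero(above & ~np.concatenate([[False], above[:-1]]))
    if starts.size == 0:
        return np.array([], dtype=np.float64)
    gap = _ms_to_samples(config.min_onset_gap_ms, fs)
    kept = [starts[0]]
    for s in starts[1:]:
        if s - kept[-1] >= gap:
            kept.append(s)
    return np.asarray(kept, dtype=np.float64) * 1000.0 / fs


def _match_pattern(candidates: np.ndarray, expected_rel: np.ndarray,
                   tol_ms: float) -> tuple[np.ndarray, np.ndarray]:
    """Anchor the expected inter-marker pattern on detected candidates.

    For each candidate taken as the first marker, the expected marker times
    (pattern relative to the first marker) are matched to the nearest
    candidates within ``tol_ms``. The earliest anchor achieving the maximal
    number of matches wins — robust to spurious onsets before the first
    marker. Returns (matched times, matched expected indices); unmatched
    pattern positions are dropped.
    """
    best_times = np.array([], dtype=np.float64)
    best_idx = np.array([], dtype=np.intp)
    for anchor in candidates:
        targets = anchor + expected_rel
        times, idx = [], []
        for k, tgt in enumerate(targets):
            j = np.argmin(np.abs(candidates - tgt))
            if abs(candidates[j] - tgt) <= tol_ms:
                times.append(candidates[j])
                idx.append(k)
        if len(times) > best_idx.size:
            best_times = np.asarray(times)
            best_idx = np.asarray(idx, dtype=np.intp)
            if best_idx.size == expected_rel.size:
                break  # earliest full match
    return best_times, best_idx


def _refine_by_template(marker_channel: Waveform, candidates: np.ndarray,
                        matched_idx: np.ndarray, prepared: PreparedStimulus,
                        config: PipelineConfig) -> np.ndarray:
    """Matched-filter refinement of marker onsets.

    The prepared stimulus carries the exact marker waveforms, so each
    coarse (envelope-threshold) marker onset can be refined by
    cross-correlating the band-passed recording with the band-passed
    template of that marker in a window around the coarse estimate. The
    correlation peak is invariant to gain and additive noise, giving
    sample-accurate, bias-free marker times.
    """
    fs = config.sample_rate
    sos = _bandpass_sos(*config.marker_band, fs)
    n_marker = _ms_to_samples(config.marker_duration_ms, fs)
    half = _ms_to_samples(config.marker_match_tolerance_ms, fs)
    refined = np.empty_like(candidates)
    for out_i, (cand, k) in enumerate(zip(candidates, matched_idx)):
        t0 = _ms_to_samples(prepared.marker_onsets[k], fs)
        template = signal.sosfiltfilt(
            sos, prepared.waveform.samples[t0:t0 + n_marker])
        i_cand = _ms_to_samples(cand, fs)
        lo = max(0, i_cand - half)
        hi = min(marker_channel.samples.size, i_cand + half + template.size)
        segment = marker_channel.samples[lo:hi]
        if segment.size <= template.size:
            refined[out_i] = cand
            continue
        corr = signal.fftconvolve(segment, template[::-1], mode="valid")
        refined[out_i] = (lo + int(np.argmax(corr))) * 1000.0 / fs
    return refined


def detect_markers(recording: Waveform | ChannelSet,
                   prepared: PreparedStimulus,
                   config: PipelineConfig) -> tuple[np.ndarray, float]:
    """Locate the marker sounds in a recording and score their timing.

    Onsets extracted from the enhanced marker channel are matched against
    the known inter-marker interval pattern (anchored at the first detected
    marker). The marker timing error is the mean absolute deviation of the
    detected intervals from the known intervals, both measured relative to
    the first detected/known marker.

    Raises
    ------
    QualityError
        If fewer than ``min_markers_detected_frac`` of the expected markers
        are found — the signature of incompatible hardware (e.g. strong
        noise cancellation suppressing the markers).
    """
    channels = recording if isinstance(recording, ChannelSet) \
        else split_channels(recording, config)
    # short refractory here: the interval-pattern match below supplies the
    # structure, and a long merge gap could swallow a marker that follows a
    # spurious supra-threshold event (e.g. a late tap) closely
    cand_config = config.with_(min_onset_gap_ms=config.marker_match_tolerance_ms)
    candidates = extract_onsets(channels.enhanced_marker_channel, cand_config)
    # only supra-threshold events inside a boosted region can be markers;
    # without this, the gain-relative threshold would happily fit the
    # interval pattern onto noise crossings when no marker is present
    boosted = _boost_mask(channels.marker_channel, channels.test_channel,
                          config)
    fs_rec = channels.marker_channel.sample_rate
    w = max(1, _ms_to_samples(config.enhance_window_ms, fs_rec))
    candidates = np.array([
        t for t in candidates
        if boosted[_ms_to_samples(t, fs_rec):
                   _ms_to_samples(t, fs_rec) + w].any()
    ])
    expected = prepared.marker_onsets
    expected_rel = expected - expected[0]
    matched, idx = _match_pattern(candidates, expected_rel,
                                  config.marker_match_tolerance_ms)
    n_needed = int(np.ceil(config.min_markers_detected_frac * expected.size))
    if matched.size < max(n_needed, 1) or 0 not in idx:
        raise QualityError(
            f"markers undetected: matched {matched.size}/{expected.size} "
            "marker onsets (incompatible hardware or attenuated markers?)")
    matched = _refine_by_template(channels.marker_channel, matched, idx,
                                  prepared, config)
    detected_rel = matched - matched[0]
    marker_error_ms = float(np.mean(np.abs(detected_rel - expected_rel[idx])))
    return matched, marker_error_ms
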
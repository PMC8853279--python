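"""Virtual participant and virtual device: synthetic trials with ground truth.

The virtual participant taps according to the Vorberg-Wing linear
phase-correction model (timekeeper noise sigma_T, motor noise sigma_M,
error-correction gain alpha) around a constant mean asynchrony — negative
for the human tendency to anticipate the beat. The virtual device renders a
free-field recording of a prepared stimulus plus tap sounds: a start delay
stands in for the unpredictable sound-card/OS recording latency, additive
white noise for room/microphone noise, and a marker attenuation factor for
noise-cancellation technologies that suppress the loud marker sounds.
Every rendered event's true time on the recording timeline is returned, so
the full pipeline can be validated without any human data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .config import ConfigError, PipelineConfig, Waveform
from .stimulus import PreparedStimulus, _bandpass_sos, _ms_to_samples

__all__ = [
    "VirtualParticipant",
    "VirtualDevice",
    "GroundTruth",
    "simulate_taps",
    "render_tap_sound",
    "render_recording",
    "stationary_async_sd",
]


@dataclass(frozen=True)
class VirtualParticipant:
    """Parameters of the generative tapping model.

    ``mean_async`` (ms) is the constant anticipation bias; ``alpha`` the
    error-correction gain; ``sigma_t``/``sigma_m`` (ms) the timekeeper and
    motor noise SDs; ``miss_prob`` the probability a planned tap is omitted.
    """

    mean_async: float = -25.0
    alpha: float = 0.25
    sigma_t: float = 15.0
    sigma_m: float = 8.0
    miss_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_t < 0 or self.sigma_m < 0:
            raise ConfigError("noise SDs must be >= 0")
        if not (0 <= self.alpha < 2):
            raise ConfigError("alpha must be in [0, 2)")
        if not (0 <= self.miss_prob < 1):
            raise ConfigError("miss_prob must be in [0, 1)")


@dataclass(frozen=True)
class VirtualDevice:
    """Recording-chain parameters of the virtual laptop."""

    start_delay_ms: float = 250.0
    snr_db: float = 30.0
    marker_attenuation: float = 1.0
    tap_gain: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.start_delay_ms < 0:
            raise ConfigError("start_delay_ms must be >= 0")
        if not (0 <= self.marker_attenuation <= 1):
            raise ConfigError("marker_attenuation must be in [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """True event times on the recording timeline (ms), plus bookkeeping."""

    marker_onsets: np.ndarray
    stim_onsets: np.ndarray
    tap_onsets: np.ndarray
    true_asynchronies: np.ndarray
    start_delay_ms: float
    clip_fraction: float = 0.0


def stationary_async_sd(participant: VirtualParticipant) -> float:
    """Closed-form stationary SD of the model's centered asynchronies.

    gamma(0) = (sigma_T^2 + 2*(1-beta)*sigma_M^2) / (1 - beta^2) with
    beta = 1 - alpha; valid for 0 < alpha < 2.
    """
    beta = 1.0 - participant.alpha
    if not (-1 < beta < 1):
        raise ConfigError("stationary variance requires alpha in (0, 2)")
    var = (participant.sigma_t ** 2 + 2 * (1 - beta) * participant.sigma_m ** 2) \
        / (1 - beta ** 2)
    return float(np.sqrt(var))


def simulate_taps(stim_onsets: np.ndarray, participant: VirtualParticipant
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Generate tap times for a stimulus onset list.

    Centered asynchronies follow A_{n+1} = (1-alpha) A_n + T_n + M_{n+1} - M_n;
    A_0 is drawn from the stationary distribution when the noise is nonzero,
    so short series are stationary from the first tap. Tap n occurs at
    stim_onsets[n] + mean_async + A_n; taps are dropped independently with
    ``miss_prob``. Returns (tap times, true asynchronies) for rendered taps.
    """
    stim = np.asarray(stim_onsets, dtype=np.float64)
    if stim.size < 2:
        raise ConfigError("need at least 2 stimulus onsets to simulate tapping")
    rng = np.random.default_rng(participant.seed)
    n = stim.size
    beta = 1.0 - participant.alpha
    t_noise = rng.normal(0.0, participant.sigma_t, n)
    m_noise = rng.normal(0.0, participant.sigma_m, n + 1)
    a = np.empty(n)
    noisy = participant.sigma_t > 0 or participant.sigma_m > 0
    a[0] = rng.normal(0.0, stationary_async_sd(participant)) \
        if (noisy and 0 < participant.alpha < 2) else 0.0
    for i in range(n - 1):
        a[i + 1] = beta * a[i] + t_noise[i] + m_noise[i + 2] - m_noise[i + 1]
    taps = stim + participant.mean_async + a
    keep = rng.random(n) >= participant.miss_prob
    return taps[keep], (participant.mean_async + a)[keep]


def render_tap_sound(config: PipelineConfig,
                     seed: int | np.random.Generator = 0,
                     duration_ms: float = 15.0) -> Waveform:
    """A crisp finger-tap sound: a short decaying burst limited to tap_band.

    Models a fingertip striking the laptop chassis: broadband at the attack,
    decaying within ~15 ms, with >=70 % of its energy between the tap-band
    edges (80-500 Hz by default). The onset is the first sample.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    fs = config.sample_rate
    n = _ms_to_samples(duration_ms, fs)
    low, high = config.tap_band
    # noise concentrated in the interior of the tap band (edges avoided so
    # the analysis band-pass does not ring at its corner frequencies)
    # cover the test band (one octave below the marker band) as a real tap
    # does, so the marker-enhancement stage can tell taps from markers
    t = np.arange(n) / fs
    # the "thud": a reproducible damped oscillation near the low end of the
    # tap band, giving every tap the same steep attack shape
    body = np.sin(2 * np.pi * (2.2 * low) * t)
    # the "rattle": per-tap random broadband noise covering the tap band
    # (including the test band one octave below the markers, so the
    # marker-enhancement stage can tell taps from markers)
    sos = _bandpass_sos(low * 1.2, high * 0.85, fs, order=6)
    noise = signal.sosfilt(sos, rng.standard_normal(4 * n))[-n:]  # steady state
    noise /= np.sqrt(np.mean(noise ** 2))
    burst = (0.85 * body + 0.25 * noise) * np.exp(-t / (duration_ms / 4000.0))
    # ~2 ms raised-cosine attack: a fingertip pad striking a chassis does not
    # rise instantaneously, and the ramp tames broadband splash from a step
    n_att = max(2, _ms_to_samples(2.0, fs))
    burst[:n_att] *= 0.5 * (1 - np.cos(np.linspace(0, np.pi, n_att)))
    burst /= np.max(np.abs(burst))
    return Waveform(burst, fs)


def render_recording(prepared: PreparedStimulus, tap_times: np.ndarray,
                     device: VirtualDevice,
                     true_asynchronies: np.ndarray | None = None
                     ) -> tuple[Waveform, GroundTruth]:
    """Mix the prepared stimulus and tap sounds through the virtual device.

    Output = start-delay silence + prepared waveform (marker segments scaled
    by ``marker_attenuation``) + tap sounds at ``tap_gain`` + white Gaussian
    noise at ``snr_db`` relative to the clean mixture RMS. Samples are hard-
    limited to [-1, 1]; the clipped fraction is reported in the ground
    truth. All true event times are returned shifted by the start delay.
    """
    config = prepared.config
    fs = config.sample_rate
    tap_times = np.asarray(tap_times, dtype=np.float64)
    if tap_times.size and (tap_times.min() < 0
                           or tap_times.max() > prepared.waveform.duration_ms):
        raise ConfigError("tap times must lie within the prepared stimulus span")
    rng = np.random.default_rng(device.seed)

    stim_samples = prepared.waveform.samples.copy()
    if device.marker_attenuation != 1.0:
        for m in prepared.marker_onsets:
            i0 = _ms_to_samples(m, fs)
            i1 = min(stim_samples.size,
                     i0 + _ms_to_samples(config.marker_duration_ms, fs))
            stim_samples[i0:i1] *= device.marker_attenuation

    n_delay = _ms_to_samples(device.start_delay_ms, fs)
    tail = _ms_to_samples(100.0, fs)
    total = n_delay + stim_samples.size + tail
    mix = np.zeros(total)
    mix[n_delay:n_delay + stim_samples.size] = stim_samples

    tap_sample_idx = np.array([n_delay + _ms_to_samples(t, fs)
                               for t in tap_times], dtype=np.intp)
    for i0 in tap_sample_idx:
        tap = render_tap_sound(config, rng).samples * device.tap_gain
        i1 = min(total, i0 + tap.size)
        mix[i0:i1] += tap[: i1 - i0]

    rms = np.sqrt(np.mean(mix ** 2))
    if rms > 0 and np.isfinite(device.snr_db):
        noise_rms = rms / (10 ** (device.snr_db / 20.0))
        mix = mix + rng.normal(0.0, noise_rms, total)

    clipped = np.mean(np.abs(mix) > 1.0)
    mix = np.clip(mix, -1.0, 1.0)

    delay_ms = n_delay * 1000.0 / fs
    truth = GroundTruth(
        marker_onsets=prepared.marker_onsets + delay_ms,
        stim_onsets=prepared.stim_onsets + delay_ms,
        tap_onsets=tap_sample_idx * 1000.0 / fs,
        true_asynchronies=(np.asarray(true_asynchronies, dtype=np.float64)
                           if true_asynchronies is not None
                           else np.array([])),
        start_delay_ms=delay_ms,
        clip_fraction=float(clipped),
    )
    return Waveform(mix, fs), truth
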
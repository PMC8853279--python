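"""Configuration and core containers shared by every pipeline stage.

All times are milliseconds (floats); the time origin is the first sample of
the signal under discussion (0 ms). Frequencies are Hz. Amplitudes are
dimensionless, in [-1, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

__all__ = [
    "PipelineConfig",
    "Waveform",
    "ConfigError",
    "InputError",
    "QualityError",
]


class ConfigError(ValueError):
    """Invalid configuration (band edges, amplitudes, durations)."""


class InputError(ValueError):
    """Unreadable or malformed input file."""


class QualityError(RuntimeError):
    """The recording cannot be analyzed (e.g., markers undetected)."""


@dataclass(frozen=True)
class Waveform:
    """A mono audio signal: samples in [-1, 1] plus a sample rate in Hz."""

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size == 0:
            raise InputError("waveform must be a non-empty 1-D signal")
        if not np.all(np.isfinite(samples)):
            raise InputError("waveform contains non-finite samples")
        if self.sample_rate <= 0:
            raise ConfigError(f"sample_rate must be positive, got {self.sample_rate}")

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.samples.size / self.sample_rate

    def delayed(self, delay_ms: float) -> "Waveform":
        """Return a copy with ``delay_ms`` of leading silence."""
        n = int(round(delay_ms * self.sample_rate / 1000.0))
        if n < 0:
            raise ConfigError("delay must be non-negative")
        return Waveform(np.concatenate([np.zeros(n), self.samples]), self.sample_rate)


def _check_band(name: str, band: tuple, nyquist: float) -> None:
    low, high = band
    if not (0 < low < high < nyquist):
        raise ConfigError(
            f"{name} must satisfy 0 < low < high < Nyquist ({nyquist:g} Hz); got {band}"
        )


@dataclass(frozen=True)
class PipelineConfig:
    """Every knob of the pipeline, with defaults for laptop free-field trials.

    Frequency plan
    --------------
    The stimulus is band-stop filtered over ``stim_stopband`` so it cannot
    leak into the tapping range. Finger taps on a laptop produce a crisp
    broadband sound with most energy in ``tap_band``. Markers are loud
    band-limited sounds confined to ``marker_band``; ``test_band`` sits one
    octave below and is used to tell markers (all energy in the marker band)
    from taps and noise (similar energy in both bands).

    Marker layout
    -------------
    ``markers_per_block`` marker sounds of ``marker_duration_ms`` each,
    separated by ``marker_gap_ms`` of silence, form a block; one block is
    placed before and one after the stimulus, with ``padding_ms`` of silence
    between block and stimulus.
    """

    sample_rate: int = 44100

    # frequency plan (Hz)
    stim_stopband: tuple = (50.0, 500.0)
    tap_band: tuple = (80.0, 500.0)
    marker_band: tuple = (200.0, 340.0)
    test_band: tuple = (100.0, 170.0)

    # marker layout (ms unless noted)
    markers_per_block: int = 3
    marker_duration_ms: float = 250.0
    marker_gap_ms: float = 500.0
    padding_ms: float = 500.0
    marker_amplitude: float = 0.95

    # onset extraction
    onset_threshold_frac: float = 0.1
    min_onset_gap_ms: float = 100.0
    envelope_window_ms: float = 5.0

    # marker enhancement
    enhance_window_ms: float = 75.0
    boost_gain: float = 4.0
    attenuation_gain: float = 1.0
    ratio_threshold: float = 3.0
    marker_match_tolerance_ms: float = 50.0

    # tap <-> stimulus pairing; None = min(250 ms, half the median IOI)
    match_window_ms: float | None = None

    # failing criteria
    min_markers_detected_frac: float = 1.0
    max_marker_error_ms: float = 10.0
    min_tap_ratio: float = 0.5
    max_tap_ratio: float = 2.0

    def __post_init__(self) -> None:
        nyq = self.sample_rate / 2.0
        for name in ("stim_stopband", "tap_band", "marker_band", "test_band"):
            band = tuple(float(x) for x in getattr(self, name))
            object.__setattr__(self, name, band)
            _check_band(name, band, nyq)
        if not (self.stim_stopband[0] <= self.tap_band[0]
                and self.tap_band[1] <= self.stim_stopband[1]):
            raise ConfigError("stim_stopband must cover tap_band")
        if not (0 < self.marker_amplitude <= 1):
            raise ConfigError("marker_amplitude must be in (0, 1]")
        for name in ("marker_duration_ms", "marker_gap_ms", "padding_ms",
                     "min_onset_gap_ms", "envelope_window_ms",
                     "enhance_window_ms", "max_marker_error_ms",
                     "marker_match_tolerance_ms"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.markers_per_block < 1:
            raise ConfigError("markers_per_block must be >= 1")
        if not (0 < self.onset_threshold_frac < 1):
            raise ConfigError("onset_threshold_frac must be in (0, 1)")
        if not (0 < self.min_markers_detected_frac <= 1):
            raise ConfigError("min_markers_detected_frac must be in (0, 1]")
        if not (0 <= self.min_tap_ratio <= self.max_tap_ratio):
            raise ConfigError("tap ratio bounds must satisfy 0 <= min <= max")

    # --- derived layout quantities -------------------------------------

    @property
    def block_duration_ms(self) -> float:
        """Duration of one marker block (markers plus inter-marker gaps)."""
        n = self.markers_per_block
        return n * self.marker_duration_ms + (n - 1) * self.marker_gap_ms

    def block_marker_offsets_ms(self) -> np.ndarray:
        """Marker start times within one block, relative to block start."""
        step = self.marker_duration_ms + self.marker_gap_ms
        return np.arange(self.markers_per_block) * step

    # --- (de)serialization ---------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        for name in ("stim_stopband", "tap_band", "marker_band", "test_band"):
            d[name] = list(d[name])
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        d = dict(d)
        for name in ("stim_stopband", "tap_band", "marker_band", "test_band"):
            if name in d:
                d[name] = tuple(d[name])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        try:
            d = json.loads(Path(path).read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise InputError(f"cannot read config {path}: {exc}") from exc
        return cls.from_dict(d)

    def with_(self, **kwargs) -> "PipelineConfig":
        """Functional update (``dataclasses.replace`` convenience)."""
        return replace(self, **kwargs)
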
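"""Realignment, tap-stimulus pairing, trial diagnostics, end-to-end analysis.

The sound card guarantees that all events in one recording share a precise
common clock, but the recording's start time relative to playback is
unknown (sound-card/OS latency). The first detected marker therefore serves
as the single frame of reference: the known stimulus onsets are shifted so
that the first known marker coincides with the first detected one. Taps are
already on the recording timeline and stay put. The asynchrony of a matched
pair is A_n = R_n - S_n (response minus stimulus onset); negative values
mean anticipation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig, QualityError, Waveform
from .onsets import ChannelSet, detect_markers, extract_onsets, split_channels
from .stimulus import PreparedStimulus, _ms_to_samples
from .stats import SMSMetrics, compute_metrics

__all__ = [
    "AlignedTrial",
    "TrialDiagnostics",
    "realign",
    "match_taps",
    "local_iois",
    "evaluate_trial",
    "analyze_recording",
]


@dataclass(frozen=True)
class AlignedTrial:
    """Realigned onsets, matched tap-stimulus pairs and their asynchronies."""

    realigned_stim_onsets: np.ndarray
    realigned_tap_onsets: np.ndarray
    matches: list  # (stim index, tap index) pairs
    asynchronies: np.ndarray
    detected_markers: np.ndarray = field(default_factory=lambda: np.array([]))
    offset_ms: float = 0.0

    def to_dict(self) -> dict:
        return {
            "realigned_stim_onsets": self.realigned_stim_onsets.tolist(),
            "realigned_tap_onsets": self.realigned_tap_onsets.tolist(),
            "matches": [[int(i), int(j)] for i, j in self.matches],
            "asynchronies": self.asynchronies.tolist(),
            "detected_markers": self.detected_markers.tolist(),
            "offset_ms": self.offset_ms,
        }


@dataclass(frozen=True)
class TrialDiagnostics:
    """Per-trial quality summary and failing-criteria verdict."""

    n_markers_detected: int
    n_markers_expected: int
    marker_error_ms: float
    n_taps_detected: int
    n_stim_onsets: int
    n_matched: int
    pct_detected_taps: float
    pct_detected_markers: float
    passed: bool
    fail_reasons: tuple = ()

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["fail_reasons"] = list(self.fail_reasons)
        d["marker_error_ms"] = (None if np.isnan(self.marker_error_ms)
                                else self.marker_error_ms)
        return d


def realign(prepared: PreparedStimulus, detected_markers: np.ndarray,
            detected_taps: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Shift the known stimulus onsets onto the recording timeline.

    offset = first detected marker - first known marker. Returns
    (realigned stimulus onsets, tap onsets unchanged, offset in ms).
    """
    detected_markers = np.asarray(detected_markers, dtype=np.float64)
    if detected_markers.size == 0:
        raise QualityError("no detected markers: alignment impossible")
    offset = float(detected_markers[0] - prepared.marker_onsets[0])
    return prepared.stim_onsets + offset, np.asarray(detected_taps,
                                                     dtype=np.float64), offset


def match_taps(stim_onsets: np.ndarray, tap_onsets: np.ndarray,
               match_window_ms: float) -> list[tuple[int, int]]:
    """Greedy nearest-neighbour pairing of taps to stimulus onsets.

    Candidate pairs within ``match_window_ms`` are taken in order of
    increasing |tap - stim|; each onset is used at most once. Equidistant
    ties resolve to the earlier tap. Returns (stim index, tap index) pairs
    sorted by stimulus index.
    """
    stim = np.asarray(stim_onsets, dtype=np.float64)
    taps = np.asarray(tap_onsets, dtype=np.float64)
    if stim.size == 0 or taps.size == 0:
        return []
    diff = np.abs(taps[None, :] - stim[:, None])
    cand = np.argwhere(diff <= match_window_ms)
    # sort by distance, then earlier tap to break exact ties
    order = np.lexsort((cand[:, 1], diff[cand[:, 0], cand[:, 1]]))
    used_s, used_t, matches = set(), set(), []
    for i, j in cand[order]:
        if i in used_s or j in used_t:
            continue
        used_s.add(i)
        used_t.add(j)
        matches.append((int(i), int(j)))
    matches.sort()
    return matches


def local_iois(stim_onsets: np.ndarray, matches: list) -> np.ndarray:
    """Local inter-onset interval for each matched stimulus onset.

    For music with variable IOI the phase of a tap is judged against the
    interval that follows its stimulus onset; the final onset reuses the
    preceding interval.
    """
    stim = np.asarray(stim_onsets, dtype=np.float64)
    if stim.size < 2:
        return np.full(len(matches), np.nan)
    diffs = np.diff(stim)
    iois = np.concatenate([diffs, [diffs[-1]]])
    return np.array([iois[i] for i, _ in matches])


def _resolve_match_window(config: PipelineConfig,
                          stim_onsets: np.ndarray) -> float:
    if config.match_window_ms is not None:
        return config.match_window_ms
    if stim_onsets.size >= 2:
        return float(min(250.0, np.median(np.diff(stim_onsets)) / 2.0))
    return 250.0


def evaluate_trial(n_markers_detected: int, n_markers_expected: int,
                   marker_error_ms: float, n_taps_detected: int,
                   n_stim_onsets: int, n_matched: int,
                   config: PipelineConfig) -> TrialDiagnostics:
    """Apply the failing criteria and assemble the diagnostics record.

    A trial fails when markers are missing (incompatible hardware or noise
    cancellation), the marker timing error is too large, or the ratio of
    detected taps to stimulus onsets falls outside the plausible range
    (non-tappers, or hardware registering spurious events).
    """
    reasons = []
    needed = int(np.ceil(config.min_markers_detected_frac * n_markers_expected))
    if n_markers_detected < needed:
        reasons.append("markers_missing")
    if np.isnan(marker_error_ms) or marker_error_ms > config.max_marker_error_ms:
        reasons.append("marker_error")
    tap_ratio = n_taps_detected / n_stim_onsets if n_stim_onsets else 0.0
    if tap_ratio < config.min_tap_ratio:
        reasons.append("too_few_taps")
    elif tap_ratio > config.max_tap_ratio:
        reasons.append("too_many_taps")
    pct_taps = 100.0 * n_matched / n_stim_onsets if n_stim_onsets else 0.0
    pct_markers = (100.0 * n_markers_detected / n_markers_expected
                   if n_markers_expected else 0.0)
    return TrialDiagnostics(
        n_markers_detected=n_markers_detected,
        n_markers_expected=n_markers_expected,
        marker_error_ms=marker_error_ms,
        n_taps_detected=n_taps_detected,
        n_stim_onsets=n_stim_onsets,
        n_matched=n_matched,
        pct_detected_taps=pct_taps,
        pct_detected_markers=pct_markers,
        passed=not reasons,
        fail_reasons=tuple(reasons),
    )


def _mask_intervals(wave: Waveform, starts_ms: np.ndarray,
                    duration_ms: float, pre_ms: float = 10.0,
                    post_ms: float = 50.0) -> Waveform:
    """Zero out the given time intervals (used to blank marker segments)."""
    samples = wave.samples.copy()
    fs = wave.sample_rate
    for s in starts_ms:
        i0 = max(0, _ms_to_samples(s - pre_ms, fs))
        i1 = min(samples.size, _ms_to_samples(s + duration_ms + post_ms, fs))
        samples[i0:i1] = 0.0
    return Waveform(samples, fs)


def analyze_recording(recording: Waveform, prepared: PreparedStimulus,
                      config: PipelineConfig | None = None
                      ) -> tuple[AlignedTrial, TrialDiagnostics, SMSMetrics]:
    """Run the full analysis on one trial recording.

    Pipeline: split channels -> detect markers -> extract taps (marker
    segments blanked out of the tap channel, since the marker band lies
    inside the tap band) -> realign via the first marker -> pair taps with
    stimulus onsets -> diagnostics and performance metrics. Deterministic
    given its inputs. If the markers cannot be detected the trial is
    reported as failed (diagnostics are always returned) with empty
    alignment and NaN metrics.
    """
    config = config or prepared.config
    channels = split_channels(recording, config)
    n_expected = prepared.marker_onsets.size
    try:
        markers, marker_error = detect_markers(channels, prepared, config)
    except QualityError:
        diag = evaluate_trial(0, n_expected, float("nan"), 0,
                              prepared.stim_onsets.size, 0, config)
        empty = np.array([], dtype=np.float64)
        trial = AlignedTrial(empty, empty, [], empty)
        return trial, diag, compute_metrics(empty, empty, empty)

    tap_channel = _mask_intervals(channels.tap_channel, markers,
                                  config.marker_duration_ms)
    taps = extract_onsets(tap_channel, config)
    stim, taps, offset = realign(prepared, markers, taps)
    window = _resolve_match_window(config, prepared.stim_onsets)
    matches = match_taps(stim, taps, window)
    asyncs = np.array([taps[j] - stim[i] for i, j in matches])
    trial = AlignedTrial(stim, taps, matches, asyncs, markers, offset)
    diag = evaluate_trial(markers.size, n_expected, marker_error,
                          taps.size, stim.size, len(matches), config)
    matched_taps = np.array([taps[j] for _, j in matches])
    metrics = compute_metrics(asyncs, matched_taps, local_iois(stim, matches))
    return trial, diag, metrics
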
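"""Simulation-based validation of the whole pipeline.

These routines re-create, with the virtual participant/device, the
calibration protocol used to establish the pipeline's timing accuracy:

* part 1 — four trials of 100 metronome clicks (IOIs 250/500/750/1000 ms),
  no taps: how accurately are the realigned stimulus onsets recovered?
* part 2 — the same four trials with a virtual tapper synchronizing once
  per click: how accurately are tap onsets recovered?
* part 3 — two trials of 20 clicks (IOIs 500/1000 ms) with taps in
  anti-phase, so clicks, markers and taps must be separated from a single
  recording.

``timing_accuracy_benchmark`` pools the absolute recovery error over many
randomized trials (random start delay, noise) for markers, stimulus onsets
and taps together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import analyze_recording, match_taps
from .config import PipelineConfig
from .simulate import (GroundTruth, VirtualDevice, VirtualParticipant,
                       render_recording, simulate_taps)
from .stimulus import PreparedStimulus, make_isochronous_stimulus, prepare_stimulus

__all__ = [
    "prepare_metronome_trial",
    "run_validation_suite",
    "timing_accuracy_benchmark",
]

PART12_IOIS = (250.0, 500.0, 750.0, 1000.0)
PART3_IOIS = (500.0, 1000.0)


def prepare_metronome_trial(ioi_ms: float, n_clicks: int,
                            config: PipelineConfig,
                            seed: int = 0) -> PreparedStimulus:
    """Build a prepared metronome stimulus (clicks plus marker blocks)."""
    wave, onsets = make_isochronous_stimulus(ioi_ms, n_clicks, config)
    return prepare_stimulus(wave, onsets, config, seed=seed)


def _count_within(recovered: np.ndarray, truth: np.ndarray,
                  tol_ms: float) -> tuple[int, np.ndarray]:
    """Matched count and per-match |error| between two onset lists."""
    matches = match_taps(truth, recovered, tol_ms)
    errors = np.array([abs(recovered[j] - truth[i]) for i, j in matches])
    return len(matches), errors


def _analyze_trial(prepared: PreparedStimulus, tap_times, device,
                   config: PipelineConfig):
    recording, truth = render_recording(prepared, tap_times, device)
    trial, diag, metrics = analyze_recording(recording, prepared, config)
    return recording, truth, trial, diag, metrics


def run_validation_suite(config: PipelineConfig | None = None,
                         seed: int = 0, n_clicks: int = 100,
                         n_clicks_part3: int = 20,
                         tol_ms: float = 5.0) -> dict:
    """Run the three-part validation protocol; returns a report dict.

    The report holds, per part, the number of comparable onsets, the number
    recovered within ``tol_ms`` of ground truth, and latency mean/SD of the
    recovery errors.
    """
    config = config or PipelineConfig()
    rng = np.random.default_rng(seed)
    report: dict = {"parts": {}}

    def part_report(counts, totals, errors):
        pooled = np.concatenate(errors) if errors else np.array([])
        return {
            "n_expected": int(sum(totals)),
            "n_recovered": int(sum(counts)),
            "latency_mean_ms": float(pooled.mean()) if pooled.size else None,
            "latency_sd_ms": float(pooled.std(ddof=1)) if pooled.size > 1 else None,
        }

    # part 1: stimulus only ------------------------------------------------
    counts, totals, errors = [], [], []
    for ioi in PART12_IOIS:
        prepared = prepare_metronome_trial(ioi, n_clicks, config,
                                           seed=int(rng.integers(2 ** 31)))
        device = VirtualDevice(start_delay_ms=float(rng.uniform(50, 500)),
                               snr_db=30.0, seed=int(rng.integers(2 ** 31)))
        _, truth, trial, _, _ = _analyze_trial(prepared, [], device, config)
        signed = trial.realigned_stim_onsets - truth.stim_onsets
        n_ok = int(np.sum(np.abs(signed) <= tol_ms))
        counts.append(n_ok)
        totals.append(truth.stim_onsets.size)
        errors.append(np.abs(signed))
    report["parts"]["1_stimuli"] = part_report(counts, totals, errors)

    # part 2: synchronized virtual tapper ---------------------------------
    counts, totals, errors = [], [], []
    for ioi in PART12_IOIS:
        prepared = prepare_metronome_trial(ioi, n_clicks, config,
                                           seed=int(rng.integers(2 ** 31)))
        participant = VirtualParticipant(miss_prob=0.0,
                                         seed=int(rng.integers(2 ** 31)))
        taps, asyncs = simulate_taps(prepared.stim_onsets, participant)
        device = VirtualDevice(start_delay_ms=float(rng.uniform(50, 500)),
                               snr_db=30.0, seed=int(rng.integers(2 ** 31)))
        _, truth, trial, _, _ = _analyze_trial(prepared, taps, device, config)
        n_ok, errs = _count_within(trial.realigned_tap_onsets,
                                   truth.tap_onsets, tol_ms)
        counts.append(n_ok)
        totals.append(truth.tap_onsets.size)
        errors.append(errs)
    report["parts"]["2_tapping"] = part_report(counts, totals, errors)

    # part 3: anti-phase taps (channel-separation stress test) ------------
    counts, totals, errors = [], [], []
    for ioi in PART3_IOIS:
        prepared = prepare_metronome_trial(ioi, n_clicks_part3, config,
                                           seed=int(rng.integers(2 ** 31)))
        taps = prepared.stim_onsets + ioi / 2.0
        device = VirtualDevice(start_delay_ms=float(rng.uniform(50, 500)),
                               snr_db=30.0, seed=int(rng.integers(2 ** 31)))
        _, truth, trial, _, _ = _analyze_trial(prepared, taps, device, config)
        n_ok, errs = _count_within(trial.realigned_tap_onsets,
                                   truth.tap_onsets, tol_ms)
        counts.append(n_ok)
        totals.append(truth.tap_onsets.size)
        errors.append(errs)
    report["parts"]["3_tapping_antiphase"] = part_report(counts, totals, errors)
    return report


def timing_accuracy_benchmark(config: PipelineConfig | None = None,
                              n_trials: int = 50, seed: int = 0,
                              ioi_ms: float = 500.0, n_clicks: int = 20,
                              snr_db: float = 20.0,
                              max_delay_ms: float = 1000.0,
                              match_tol_ms: float = 50.0) -> dict:
    """Pooled absolute timing error over randomized simulated trials.

    Each trial uses a random recording start delay in [0, ``max_delay_ms``],
    additive noise at ``snr_db`` and a fresh virtual tapper. The pooled
    error combines |recovered - true| for detected markers, realigned
    stimulus onsets and detected taps.
    """
    config = config or PipelineConfig()
    rng = np.random.default_rng(seed)
    prepared = prepare_metronome_trial(ioi_ms, n_clicks, config, seed=seed)
    all_errors, per_component = [], {"markers": [], "stimulus": [], "taps": []}
    n_failed = 0
    for _ in range(n_trials):
        participant = VirtualParticipant(seed=int(rng.integers(2 ** 31)))
        taps, _ = simulate_taps(prepared.stim_onsets, participant)
        device = VirtualDevice(start_delay_ms=float(rng.uniform(0, max_delay_ms)),
                               snr_db=snr_db,
                               seed=int(rng.integers(2 ** 31)))
        _, truth, trial, diag, _ = _analyze_trial(prepared, taps, device, config)
        if trial.detected_markers.size == 0:
            n_failed += 1
            continue
        _, marker_err = _count_within(trial.detected_markers,
                                      truth.marker_onsets, match_tol_ms)
        stim_err = np.abs(trial.realigned_stim_onsets - truth.stim_onsets)
        _, tap_err = _count_within(trial.realigned_tap_onsets,
                                   truth.tap_onsets, match_tol_ms)
        per_component["markers"].append(marker_err)
        per_component["stimulus"].append(stim_err)
        per_component["taps"].append(tap_err)
        all_errors.extend([marker_err, stim_err, tap_err])
    pooled = np.concatenate(all_errors) if all_errors else np.array([])
    report = {
        "n_trials": n_trials,
        "n_failed": n_failed,
        "n_onsets_pooled": int(pooled.size),
        "mean_abs_error_ms": float(pooled.mean()) if pooled.size else None,
        "sd_abs_error_ms": float(pooled.std(ddof=1)) if pooled.size > 1 else None,
        "max_abs_error_ms": float(pooled.max()) if pooled.size else None,
    }
    for name, errs in per_component.items():
        e = np.concatenate(errs) if errs else np.array([])
        report[f"mean_abs_error_{name}_ms"] = float(e.mean()) if e.size else None
    return report
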
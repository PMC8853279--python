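"""Failing criteria: how bad recordings are excluded automatically.

Unsupervised experiments need per-trial quality control. Three recordings
are analyzed: a good one, one from a device whose noise cancellation
removed the marker sounds, and one from a participant who never tapped.
The pipeline always returns diagnostics; ``passed`` and ``fail_reasons``
say whether and why a trial should be excluded.

Run:  python examples/04_quality_control.py
"""

import tapalign as ta

config = ta.PipelineConfig()
prepared = ta.prepare_metronome_trial(500.0, 20, config, seed=1)
participant = ta.VirtualParticipant(seed=2)
taps, _ = ta.simulate_taps(prepared.stim_onsets, participant)


def report(label, recording):
    _, diag, _ = ta.analyze_recording(recording, prepared, config)
    verdict = "PASS" if diag.passed else f"FAIL {list(diag.fail_reasons)}"
    print(f"{label:24s}: {verdict}")
    print(f"{'':24s}  markers {diag.n_markers_detected}/"
          f"{diag.n_markers_expected}, taps {diag.n_taps_detected} "
          f"for {diag.n_stim_onsets} clicks")


good = ta.VirtualDevice(start_delay_ms=300.0, snr_db=20.0, seed=3)
rec, _ = ta.render_recording(prepared, taps, good)
report("compliant trial", rec)

cancelling = ta.VirtualDevice(start_delay_ms=300.0, snr_db=20.0,
                              marker_attenuation=0.0, seed=3)
rec, _ = ta.render_recording(prepared, taps, cancelling)
report("noise-cancelling device", rec)

silent = ta.VirtualDevice(start_delay_ms=300.0, snr_db=20.0, seed=3)
rec, _ = ta.render_recording(prepared, [], silent)
report("non-tapper", rec)
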
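"""Shared fixtures: a default config and one fully simulated trial.

The simulated trial is session-scoped because rendering and analyzing a
~15 s recording is the expensive part of the suite; tests only read from
it.
"""

import numpy as np
import pytest

import tapalign as ta


@pytest.fixture(scope="session")
def config():
    return ta.PipelineConfig()


@pytest.fixture(scope="session")
def prepared_metronome(config):
    """20 clicks at 500 ms IOI wrapped in marker blocks."""
    return ta.prepare_metronome_trial(500.0, 20, config, seed=1)


@pytest.fixture(scope="session")
def simulated_trial(config, prepared_metronome):
    """One clean trial: virtual tapper, 270 ms start delay, 20 dB SNR."""
    participant = ta.VirtualParticipant(seed=2)
    taps, asyncs = ta.simulate_taps(prepared_metronome.stim_onsets, participant)
    device = ta.VirtualDevice(start_delay_ms=270.0, snr_db=20.0, seed=3)
    recording, truth = ta.render_recording(prepared_metronome, taps, device,
                                           asyncs)
    return {
        "prepared": prepared_metronome,
        "recording": recording,
        "truth": truth,
        "participant": participant,
        "device": device,
    }


@pytest.fixture(scope="session")
def analyzed_trial(config, simulated_trial):
    trial, diag, metrics = ta.analyze_recording(
        simulated_trial["recording"], simulated_trial["prepared"], config)
    return {"trial": trial, "diag": diag, "metrics": metrics,
            **simulated_trial}
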
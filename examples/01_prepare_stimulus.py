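"""Prepare a stimulus for free-field presentation.

A raw stimulus cannot be timed from a laptop recording: the recording
starts at an unknown moment relative to playback. ``prepare_stimulus``
therefore (1) removes the 50-500 Hz band from the stimulus so it cannot be
mistaken for taps or markers, and (2) brackets it with two blocks of three
loud 200-340 Hz marker sounds. The markers are later re-detected in the
recording and serve as the common clock.

Run:  python examples/01_prepare_stimulus.py
"""

import numpy as np

import tapalign as ta

config = ta.PipelineConfig()
print(f"sample rate          : {config.sample_rate} Hz")
print(f"stimulus stop band   : {config.stim_stopband} Hz (removed)")
print(f"marker band          : {config.marker_band} Hz")

# a 10-click metronome at 600 ms IOI as the raw stimulus
wave, onsets = ta.make_isochronous_stimulus(ioi_ms=600.0, n_clicks=10,
                                            config=config)
print(f"\nraw stimulus         : {wave.duration_ms:.0f} ms, "
      f"{onsets.size} clicks at {np.diff(onsets)[0]:.0f} ms IOI")

prepared = ta.prepare_stimulus(wave, onsets, config, seed=0)
print(f"prepared waveform    : {prepared.waveform.duration_ms:.0f} ms")
print(f"marker onsets (ms)   : {np.round(prepared.marker_onsets, 1)}")
print(f"first click moved to : {prepared.stim_onsets[0]:.1f} ms "
      "(after the start marker block + padding)")

# the marker sound itself: all of its energy sits inside the marker band
marker = ta.generate_marker_sound(config, seed=0)
freqs = np.fft.rfftfreq(marker.samples.size, 1 / config.sample_rate)
power = np.abs(np.fft.rfft(marker.samples)) ** 2
in_band = power[(freqs >= 200) & (freqs <= 340)].sum() / power.sum()
print(f"\nmarker sound         : {marker.duration_ms:.0f} ms, "
      f"{100 * in_band:.1f} % of energy in 200-340 Hz")

ta.write_wav("/tmp/prepared_demo.wav", prepared.waveform)
print("\nprepared WAV written to /tmp/prepared_demo.wav")
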
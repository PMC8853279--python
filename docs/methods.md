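# Methods

This document describes the measurement model behind `tapalign`, the
rationale for every default parameter, the numerical choices that keep
onset estimates unbiased at the millisecond level, and the scope and
limitations of the simulator used for validation.

## 1. Measurement model

### 1.1 The timing problem

A sensorimotor-synchronization (SMS) trial needs the signed asynchrony

```
A_n = R_n − S_n
```

between each tap onset `R_n` and its paired stimulus onset `S_n`
(negative = anticipation), with an error budget of a few milliseconds —
human asynchrony SDs are 10–40 ms, and systematic biases of even 5 ms
distort model fits. On consumer hardware the latency between *playing* a
sound and *registering* a keypress or audio timestamp varies by tens of
milliseconds across machines and sessions, so absolute software clocks
are useless at this accuracy.

The free-field trick: record the played stimulus **and** the tap sounds
with the same microphone. Every event in the recording then shares one
sound-card clock; only the recording's start time relative to playback is
unknown. A known, loud, re-detectable sound — the **marker** — anchors
the two timelines: once the first marker is found in the recording,

```
offset = first detected marker − first known marker position
```

and the entire preregistered stimulus-onset list is shifted by `offset`
onto the recording timeline ("virtual onsets": stimulus onsets are never
extracted from audio, which also works for music where onsets are hard to
detect acoustically). Tap onsets are already on the recording timeline.

### 1.2 Frequency plan

All separation is spectral. Defaults (all configurable):

| band | range (Hz) | role |
| --- | --- | --- |
| stimulus stop band | 50–500 | removed from the stimulus before playback |
| tap band | 80–500 | where finger-tap energy concentrates |
| marker band | 200–340 | the markers' exclusive band |
| test band | 100–170 | one octave below the markers, for discrimination |

Because the stimulus has no 50–500 Hz content after preparation, anything
in the tap band during the stimulus is a tap; because taps are broadband
while markers are strictly band-limited, comparing marker-band against
test-band energy tells them apart.

### 1.3 Pipeline stages

1. **Stimulus preparation.** Order-4 zero-phase Butterworth band-stop
   (50–500 Hz) on the stimulus; two marker blocks (3 markers each,
   250 ms long, 500 ms gaps) prepended and appended with 500 ms padding;
   the onset list is shifted by block + padding = 2250 ms. The second
   block allows a drift/termination check and makes truncated recordings
   detectable.
2. **Channel separation.** Order-4 zero-phase Butterworth band-passes
   produce the tap, marker and test channels.
3. **Marker enhancement.** Causal sliding-window energies (75 ms) of the
   marker and test channels are normalized by their band widths (energy
   *density* per Hz). Samples where the marker density exceeds
   `ratio_threshold` (3) times the test density *for the majority of the
   following window* get gain 4, others gain 1. Density normalization
   makes a spectrally flat event score ≈1 regardless of band widths;
   the majority vote rejects isolated excursions of the noisy ratio, so
   taps and noise are never boosted while 250 ms markers always are.
4. **Onset extraction** (shared by markers and taps). The channel is
   rectified and smoothed with a causal 5 ms moving average; the
   threshold is 0.1 × the envelope maximum (relative → invariant to
   recording gain); an onset is the first sample of each supra-threshold
   excursion; excursions closer than 100 ms merge, keeping the first.
5. **Marker detection.** Candidate onsets from the enhanced channel
   (50 ms refractory — the pattern match below supplies structure) are
   filtered to those inside boosted regions (without this, the relative
   threshold would latch onto noise when markers are absent), then
   matched to the known inter-marker interval pattern anchored at each
   candidate in turn; the earliest anchor matching all markers within
   ±50 ms wins. Each matched onset is then refined by cross-correlating
   the marker channel with the known marker waveform (band-passed) in a
   ±50 ms window — the correlation peak is invariant to gain and
   additive noise and removes the attack-shape bias of threshold
   detection (sample-exact in simulation).
6. **Realignment and tap extraction.** Stimulus onsets are shifted by
   the first-marker offset. Marker intervals (−10/+50 ms guard) are
   blanked out of the tap channel — the marker band lies inside the tap
   band — and tap onsets extracted.
7. **Matching.** Greedy nearest-neighbour pairing of taps to stimulus
   onsets by increasing |Δt| within a window of min(250 ms, median
   IOI/2); each onset is used at most once; equidistant ties go to the
   earlier tap.
8. **Diagnostics (failing criteria).** A trial fails if fewer than all
   6 markers are found (`markers_missing` — noise-cancelling hardware),
   the mean |detected − expected| inter-marker deviation exceeds 10 ms
   (`marker_error` — resampling/drift), or the detected-tap to
   stimulus-onset ratio leaves [0.5, 2] (`too_few_taps` /
   `too_many_taps` — non-compliance or spurious events). Diagnostics are
   always returned; the CLI maps failure to exit code 2.

### 1.4 Performance statistics

For the matched asynchronies the package computes:

* **Mean and SD** (ddof = 1).
* **Mean resultant vector length** `R = |mean(exp(i·2π·A_n/IOI_n))|`,
  using each tap's local IOI — the standard circular-statistics
  concentration measure, in [0, 1].
* **Vorberg–Wing decomposition.** The linear phase-correction model
  `A_{n+1} = (1−α)A_n + T_n + M_{n+1} − M_n` with timekeeper noise
  `T ~ N(0, σ_T²)` and motor noise `M ~ N(0, σ_M²)` implies, with
  `β = 1−α` and `γ(k)` the lag-k autocovariance:
  `γ(2) = β·γ(1)`, `σ_M² = β·γ(0) − γ(1)`,
  `σ_T² = (1−β²)·γ(0) − 2(1−β)·σ_M²`. Plugging in biased (1/n) sample
  autocovariances gives a closed-form method-of-moments estimator.
  Degenerate inputs are flagged rather than silently mis-fit: series
  shorter than 5 (`vw_too_short`); |γ̂(1)| below its own white-noise
  sampling scale 2·γ̂(0)/√n (`vw_degenerate`, α reported as 1, the
  white-noise limit); β̂ outside (−1, 1) (`vw_unstable_beta`, clipped);
  negative variance estimates (`vw_clipped`, set to 0).
* **Lag-1 autocorrelations** of asynchronies and inter-tap intervals.
  Under i.i.d. tap jitter on an isochronous grid the ITI lag-1 tends to
  −0.5 (differenced white noise), a classic sanity check.

## 2. Parameters

All defaults live in `PipelineConfig` (frozen dataclass, JSON round-trip,
validated on construction).

| parameter | default | unit | rationale |
| --- | --- | --- | --- |
| `sample_rate` | 44100 | Hz | CD standard; one sample = 0.023 ms, far below the error budget |
| `stim_stopband` | 50–500 | Hz | keeps the stimulus out of the tap and marker bands |
| `tap_band` | 80–500 | Hz | impact sounds of a fingertip on a chassis |
| `marker_band` | 200–340 | Hz | inside the tap band (markers survive the same microphone), narrow enough to be exclusive |
| `test_band` | 100–170 | Hz | one octave below the marker band; broadband taps excite it, markers do not |
| `markers_per_block` / blocks | 3 / 2 | — | redundancy against single-marker corruption; end block checks drift |
| `marker_duration_ms` | 250 | ms | long enough for sustained-dominance detection and a sharp correlation peak |
| `marker_gap_ms` | 500 | ms | separates markers beyond the refractory period |
| `padding_ms` | 500 | ms | keeps stimulus energy out of the marker blocks |
| `marker_amplitude` | 0.95 | — | markers must dominate the recording without clipping |
| `onset_threshold_frac` | 0.1 | — | relative threshold → gain invariance; 10 % clears noise floors at SNR ≥ 20 dB |
| `envelope_window_ms` | 5 | ms | smooths rectification ripple while adding < 1 ms of onset bias |
| `min_onset_gap_ms` | 100 | ms | one event per tap: shorter than any plausible inter-tap interval, longer than tap ring-down |
| `enhance_window_ms` | 75 | ms | energy-ratio stability: a 70 Hz-wide test band needs ~2·B·T ≈ 10 degrees of freedom |
| `boost_gain` / `attenuation_gain` | 4 / 1 | — | boosted markers set the envelope maximum; unboosted content stays intact for template refinement |
| `ratio_threshold` | 3 | — | density ratio: flat events score ≈1, markers ≫10; 3 splits the gap with margin |
| `marker_match_tolerance_ms` | 50 | ms | pattern-match tolerance; also the marker-candidate refractory |
| `max_marker_error_ms` | 10 | ms | inter-marker deviations beyond this imply clock drift or resampling |
| `min/max_tap_ratio` | 0.5 / 2 | — | non-tappers and spurious-event screens |
| `match_window_ms` | None (auto) | ms | min(250, median IOI/2): half an IOI is the identifiability limit |

Simulator defaults: `VirtualParticipant(mean_async=−25, alpha=0.25,
sigma_t=15, sigma_m=8, miss_prob=0)` — typical human values for metronome
tapping; `VirtualDevice(start_delay_ms=250, snr_db=30,
marker_attenuation=1, tap_gain=0.5)` — a reasonable laptop; validation
uses 20 dB for stress.

## 3. Numerical choices

* **Zero-phase filtering** (`sosfiltfilt`, second-order sections): no
  group delay, so filtered onsets are not shifted; SOS avoids the
  numerical blow-up of high-order transfer functions at 44.1 kHz with
  sub-500 Hz corners.
* **Causal envelopes with a zero-padded past**: the cumulative-sum
  moving average divides by the full window even near t = 0, so the
  estimate ramps up instead of amplifying the recording's first samples
  into spurious onsets.
* **Synthetic sounds are generated causally** (`sosfilt` steady state,
  taking the tail of a longer noise stream): a `sosfiltfilt`-generated
  burst would carry acausal pre-ring that biases threshold onsets early.
  Attack ramps (5 ms fade on markers, 2 ms raised-cosine on taps) tame
  the broadband splash of instantaneous steps, which otherwise leaks
  across bands.
* **Template refinement by FFT cross-correlation** (`fftconvolve`): the
  matched filter is the minimum-variance estimator for a known waveform
  in noise; it removes the ~1–3 ms attack-shape bias of envelope
  thresholds and is exact on the sample grid in simulation.
* **Everything on the sample grid**: onsets are reported as
  sample_index × 1000/fs; no sub-sample interpolation is attempted since
  one sample (0.023 ms) is two orders of magnitude below the budget.
* **Seeded `numpy` Generators everywhere**: every stochastic element
  (marker noise, tap sounds, participant, device) takes a seed; identical
  seeds give bit-identical recordings.

## 4. Simulator scope and limitations

The simulator's purpose is **validating the analysis pipeline**, not
reproducing human audio. It renders: start-delay silence (sound-card/OS
latency), the prepared stimulus with optional marker attenuation
(noise-cancellation hardware), tap sounds at known times, white Gaussian
noise at a target SNR, and hard limiting to [−1, 1] with the clipped
fraction reported. The virtual participant implements the Vorberg–Wing
model with a stationary initial asynchrony and independent tap omissions.

Known limitations:

* Tap sounds are a stylized damped oscillation + band-limited rattle;
  real finger taps vary in spectrum, amplitude and duration from tap to
  tap and across surfaces.
* Room acoustics are absent: no reverberation, no microphone frequency
  response, no automatic gain control. Real devices can compress or gate
  the signal nonlinearly.
* Noise is white and stationary; real recordings contain speech, hum and
  impulsive interference that could defeat the relative threshold.
* The clock is ideal: no resampling drift between playback and capture
  (real drift would trip the `marker_error` criterion rather than be
  corrected).
* The participant model has constant parameters per trial — no fatigue,
  tempo drift, phase wandering or off-beat strategies other than the
  scripted anti-phase case.

Consequently, simulated accuracy numbers are best-case bounds: they
establish that the *algorithms* are unbiased and robust to gain, delay
and stationary noise, not that any particular laptop achieves them.

## 5. Problem sizes and runtimes

Chosen for a laptop-class machine (single CPU):

* One trial: ~15 s of audio at 44.1 kHz (~650 k samples); full analysis
  ≈ 0.3 s.
* Validation suite: parts 1 and 2 use 4 trials × 100 clicks at IOIs
  250/500/750/1000 ms (400 onsets each), part 3 uses 2 × 20 anti-phase
  taps; ≈ 20 s total.
* Timing benchmark: 50 randomized trials (start delay uniform in
  0–1000 ms, 20 dB SNR, 20 clicks at 500 ms), pooling ~2300 onsets;
  ≈ 10 s.
* Statistical property tests run the Vorberg–Wing grid at n = 10⁵ taps
  per series, where method-of-moments sampling error is well inside the
  15 % tolerance.

Full test suite: ≈ 40 s. `scripts/acceptance.py`: ≈ 30 s.
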
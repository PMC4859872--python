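# Methods

This note documents the models, algorithms and design choices behind
beatkit, module by module, including what the synthetic data does and does
not emulate and which defaults are assumptions rather than derivations.

## Synthetic ECG with controllable RSA (`beatkit.synth`)

**Beat placement.** Beats are generated by integral pulse frequency
modulation (IPFM): the instantaneous interval is
RR(t) = RR̄ − A·sin(2π f_b t) with RR̄ the mean interval (default 1000 ms),
A the RSA modulation depth (`rsa_gain_ms`) and f_b the breathing frequency
(`breathing_rate_bpm`/60). The rate 1000/RR(t) is integrated on a 1 ms grid
(trapezoidal; O(dt²) error, far below a millisecond over five minutes) and a
beat is emitted at each unit crossing by linear inversion of the monotone
integral. The first beat is pinned at t = 0 and beats lie strictly in
[0, T), which removes off-by-one ambiguity from every beat-count test. IPFM
is the standard generative model coupling a modulating signal to beat
timing; it makes the ground truth exact and puts the tachogram's dominant
spectral peak exactly at f_b. With A = 0 the generator degenerates to an
exact metronome. Optional white RR jitter (`rr_jitter_ms`, default 0) is
added on top for less idealised tachograms.

**Validity bounds.** `mean_rr_ms − rsa_gain_ms` must exceed 200 ms so the
instantaneous interval stays positive and physiological, and `fs_hz` must be
at least twice the template bandwidth (~40 Hz, set by the sharpest QRS
Gaussian, σ = 8–12 ms). The default 260 samples/s matches the wearable
front-end this package models.

**Rendering.** Each beat is a fixed sum of five Gaussians approximating the
P, Q, R, S, T waves (R amplitude 1 mV, the dominant deflection of lead I),
evaluated at each beat's sub-sample phase so beat times need not fall on the
sample grid. The annotation marks the R-apex sample — the argmax of the
clean rendition within ±50 ms of the beat time — which is the quantity a
detector is scored against. The template is configurable; its bandwidth is a
choice, not a derivation, since the emulated sensor's analog bandwidth is
unspecified.

**Noise.** Additive and orthogonal to the clean signal: a baseline-wander
sinusoid (default 0.25 Hz, emulating respiration/motion drift), a powerline
sinusoid (default 50 Hz) and white Gaussian noise, each with amplitude in
mV. All randomness flows from one integer seed through named SeedSequence
branches, so records, noise and task items are independently reproducible.

**What the simulator does not emulate:** ectopy and arrhythmia, QRS
morphology change, electrode-motion transients, muscle noise with 1/f
structure, amplitude modulation of the ECG by respiration, or sensor
quantisation/dropouts. Passing detector tests on this data therefore bound
the *algorithmic* behaviour (thresholding, streaming, localisation), not
clinical robustness; the MIT-BIH benchmark harness exists precisely to
measure the latter on real recordings.

## Streaming R-peak detection (`beatkit.detect`)

The detector is a Pan–Tompkins-style chain, the de-facto standard whose
published performance bracket matches single-lead wearables of this class:

1. Band-pass 5–15 Hz (2nd-order Butterworth, causal `lfilter` with carried
   state) — isolates QRS energy, removes baseline and T-wave bulk.
2. Five-point derivative FIR, then squaring — slope emphasis, polarity
   erased (an inverted lead detects identically).
3. Moving-window integration over 150 ms — one smooth energy peak per QRS.
4. Candidate peaks are strict local maxima of the integrated signal
   (one-sample lookahead). Each is classified against the adaptive threshold
   THR = NPKI + 0.25(SPKI − NPKI), with SPKI/NPKI the exponentially updated
   signal/noise peak estimates (1/8 update, classic constants), subject to a
   200 ms refractory period. If the gap since the last QRS exceeds 1.66× the
   running average RR (last 8 intervals), search-back re-examines rejected
   candidates at half threshold.
5. Localisation maps the integrator peak to the R apex: largest band-passed
   magnitude in the preceding 225 ms, refined to the raw sample with the
   largest deviation from the local window mean. The refinement cancels the
   band-pass group delay; on clean synthetic records the located index
   equals the ground-truth apex exactly.

**Streaming contract.** All filters carry `lfilter` state, and every
per-sample decision depends only on absolute sample position and causally
available values, so detections are invariant to chunk partitioning by
construction (verified for 1-, 13-, 260-sample and whole-record chunks).
History buffers are trimmed to a 3 s lookback behind the scan position:
memory is bounded regardless of stream length. Thresholds are initialised
from the first 2 s of signal (SPKI = 0.5·max, NPKI = 0.1·max of the
integrated signal), during which candidates are buffered and then replayed;
records shorter than the warm-up return an empty annotation with a warning.
At end of stream the chain is flushed with 0.5 s of zeros so the last beat's
integrator peak is still scanned; emission latency is bounded by the
warm-up/search-back horizon (≤ 2 s).

No dedicated T-wave discrimination rule is implemented: at 260 Hz the
squared-derivative energy of a T wave is orders of magnitude below a QRS,
and the adaptive noise estimate absorbs it. This is a known simplification
relative to the original algorithm.

**Evaluation.** Beat matching is greedy in time order: each detection takes
the nearest unmatched reference beat within the tolerance window (default
150 ms, the ANSI/AAMI EC57 convention; ties break toward the earlier
reference beat, for determinism). Degenerate ratios (no detections, or no
reference beats) are reported as 0 with an explicit flag rather than NaN.
The WFDB benchmark pools summed TP/FP/FN into gross statistics, reports
per-record results so any record-subset convention can be compared, and
skips unreadable records loudly.

## RR processing and time-domain HRV (`beatkit.hrv`)

Artifact filtering flags, never deletes: intervals outside 300–2000 ms fail
the absolute bound; the survivors are then tested against the 5-interval
running median of the surviving intervals (shrinking centred window), with
>30% deviation flagged. Computing the median over bound-passing intervals
only prevents one gross artifact from dragging its neighbours past the 30%
rule. The thresholds are conventional tachogram-cleaning values, chosen
once; the biofeedback loop needs robustness, not optimal ectopy science.

Metrics follow the standard time-domain definitions with two conventions
made explicit because they change results: SDNN uses the *population*
standard deviation (matching common HRV tooling, and the brute-force oracle
in the tests), and pNN50 uses strictly greater than 50 ms. Successive
differences that span a flagged interval are excluded from RMSSD/pNN50.
Mean HR, SDNN, RMSSD and pNN50 are the chosen metric set — the standard
minimal time-domain panel; the emulated app commits to "time-domain HRV"
without enumerating it, so this is a documented assumption.

The instantaneous HR waveform assigns 60000/RR at each interval's second
beat time, interpolates linearly and resamples at 4 Hz over a trailing 60 s
window (both configurable); linear interpolation at a few Hz is the standard
tachogram-resampling choice and is smooth enough for display and for the
periodogram below. Fewer than two usable beats raises a typed
"unavailable" error — the display shows nothing rather than garbage.

## Biofeedback scoring (`beatkit.biofeedback`)

The pacer is a deterministic piecewise schedule over the cycle
C = 60/breaths_per_min with inhale/hold/exhale fractions 0.4/0.1/0.5. The
app being emulated shows a single "hold" cue without stating its position or
length, so the single post-inhale hold is a choice and the fractions are
configurable. Rates outside 4–12 breaths/min are rejected as outside any
plausible pacing protocol.

The goal waveform is baseline + A·sin(2π f_p t − π/2): baseline from the
mean of the user's recent HR (default 70 bpm when none exists, flagged),
amplitude √2·std of the linearly detrended recent waveform (exact for a
sinusoid, robust to the window cutting a cycle mid-phase) with a 2 bpm
floor, phase at HR minimum rising at inhale onset. Whether a real app fixes
the amplitude or derives it from the user is unknown; both are supported.

The coherence score mechanizes the visual "does my waveform match the goal"
judgement so it can be tested: linear detrend (otherwise slow drift
dominates low-frequency power), boxcar periodogram over the 60 s window
(bin width 1/60 Hz), then score = power within ±0.015 Hz of f_p divided by
power in 0.04–0.4 Hz (the LF+HF HRV range). The ±0.015 Hz half-width is the
narrowest band that still separates 6 from 8 breaths/min at this resolution.
Attainment = score ≥ 0.6 with the spectral peak inside the target band; 0.6
is a configurable threshold chosen as a clearly-above-noise concentration
(white noise scores ~0.05–0.08). A numerically empty band (constant HR)
scores 0 via a relative power floor rather than dividing round-off by
round-off.

## Session protocol (`beatkit.session`)

Lessons 1–5 each pair one physical and one cognitive task (rotating so all
five task kinds appear across the program), difficulty equal to the lesson
index, pacer tapering 10 → 6 breaths/min linearly across lessons. The taper
and the linear difficulty scaling are assumptions — the emulated protocol
states only that difficulty increases and that pacing is adjustable.

Stage durations: stress is exactly 60 s per task (the stated task length);
baseline 120 s and recovery 300 s are declared defaults, since only the
overall session length is known. A baseline stage is included although the
core exercise is stress/recovery/review: a "stress minus rest" delta needs a
rest reference. The state machine is immutable and strictly ordered
(baseline → stress → recovery → review → done); beats are assigned to stages
by timestamp against the stage windows, so a whole session can be fed in one
call or beat-by-beat with identical results, and overshoot past a boundary
credits the next stage. Reviews recompute per-stage metrics from the stored
segments (so they are exactly reproducible), report within-lesson deltas
(stress−baseline, recovery−stress) and append recovery metrics to the
between-lesson trend; missing segments are named, never silently zeroed.

Cognitive items are generated, not authored: arithmetic chains (operand
count 2+level, magnitude ≤ 10·level) and letter-pattern sequences, at
6 + 4·(level−1) items/min, each carrying its correct answer and the raw
operands so tests re-evaluate every answer independently. Physical tasks are
timers only — the emulated system verifies nothing about their execution
either.

## I/O and pipeline (`beatkit.io`)

The CSV dialect is self-describing (`# fs_hz=260` header, then
`sample_index,time_s,voltage_mv`), 0-based indices, seconds, millivolts.
WFDB support is implemented natively: text .hea headers, signal formats 16
and 212 (the MIT-BIH format; 12-bit two's-complement pairs packed 2-per-3
bytes), and MIT .atr annotations (10-bit interval words, SKIP/AUX/NUM/SUB/
CHN control codes), with non-beat symbols dropped when building a beat
reference. Byte-level worked examples frozen in the tests pin the format
arithmetic. Reports embed the effective configuration and seed, so any
published number is reproducible from its report file alone.

## Problem sizes in tests and the acceptance script

Synthetic records of 30–300 s at 260 Hz (≈8k–78k samples, ≈30–300 beats)
exercise every code path including warm-up, search-back and window-full
coherence; 10 seeded records per detector claim and 1000 random series for
the metric-oracle check give stable statistics while the whole suite runs in
seconds. The MIT-BIH benchmark is the one check needing external data
(~100 MB, 48 half-hour records) and runs only when `./mitdb` is present.

## Known limitations

- No beat classification: every detection is treated as a normal beat; on
  arrhythmic records the RR filter, not the detector, is the only guard.
- Artifact handling flags intervals but does not interpolate or correct
  them, so heavily corrupted segments simply become metrics-unavailable.
- The coherence score is a power ratio at fixed band edges; it is not a
  resonance-frequency search and does not adapt the target band to the
  user.
- The synthetic generator's idealisations listed above mean synthetic
  pass rates upper-bound real-world detector performance.
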
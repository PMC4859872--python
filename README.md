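# beatkit

Signal-processing toolkit for wearable single-lead ECG heart-rate-variability
(HRV) biofeedback, modelled on a chest-patch sensor + mobile-app system for
behavioral neurocardiac training (BNT): guided stress-reactivity/recovery
sessions in which slow paced breathing (6–10 breaths/min) elicits respiratory
sinus arrhythmia (RSA) and the user steers their own heart-rate waveform
toward a sinusoidal goal.

It is written for engineers and researchers prototyping such systems: every
stage of the app's signal chain is a library function with a matching CLI
verb, and a synthetic ECG generator with exact ground-truth beat annotations
replaces the live Bluetooth stream so the whole chain is testable end to end.

## What it computes

**Streaming R-peak detection.** A Pan–Tompkins-style chain — band-pass
5–15 Hz, five-point derivative, squaring, 150 ms moving-window integration,
adaptive signal/noise thresholds (SPKI/NPKI), 200 ms refractory period and
RR-gap search-back — operating on chunked input with bounded state. Feeding a
record in chunks of any size yields the same detections as one pass, the
contract a live sensor stream (260 samples/s, no on-sensor memory) requires.
A beat-matching harness (greedy one-to-one matching within a 150 ms tolerance
window, the ANSI/AAMI EC57 convention) computes sensitivity Se = TP/(TP+FN)
and positive predictivity +P = TP/(TP+FP), per record and pooled, including
over WFDB databases such as MIT-BIH.

**Time-domain HRV.** From R-peak times t_i, the RR series RR_i = t_{i+1}−t_i
(ms) is artifact-filtered (absolute bounds 300–2000 ms plus a 30% running-
median rule) and summarised by mean HR = 60000/mean(RR), SDNN (population SD
of the normal intervals), RMSSD = sqrt(mean(ΔRR²)) and pNN50 (% of successive
differences with |ΔRR| > 50 ms).

**Biofeedback.** The instantaneous HR tachogram 60000/RR is resampled at 4 Hz
over a trailing 1-minute window — the waveform the app displays — and scored
against the paced-breathing goal: the coherence score is the fraction of
spectral power within ±0.015 Hz of the pacer frequency f_p = breaths/60
relative to the 0.04–0.4 Hz band, with goal attainment at score ≥ 0.6. A
configurable inhale/hold/exhale pacer and a sinusoidal goal waveform complete
the display model.

**Session protocol.** A five-lesson state machine: baseline → stress (one or
more 1-minute tasks: seated leg raise, fist clench, serial
addition/subtraction/letters, difficulty rising with lesson index) →
paced-breathing recovery → performance review with within-lesson metric
deltas and a between-lesson recovery trend.

**Synthetic ECG.** Integral pulse frequency modulation over the instantaneous
interval RR(t) = RR̄ − A·sin(2π f_b t) places beats with exact timing; a
Gaussian-bump P-QRS-T template renders them at any sampling rate; baseline
wander, powerline hum and white noise are additive and seeded.

## Worked example

Generate five minutes of ECG with 100 ms RSA at 6 breaths/min, detect beats,
evaluate against ground truth, and score the biofeedback loop:

```sh
beatkit synth --duration 300 --rr 1000 --rsa 100 --breath 6 --fs 260 \
              --seed 42 --out rec.csv --ann rec.beats.csv
beatkit detect --in rec.csv --out peaks.csv
beatkit eval --detected peaks.csv --reference rec.beats.csv --tol-ms 150
beatkit pipeline --synth-duration 300 --synth-rsa 100 --breath 6 --seed 42 \
                 --report report.json
```

The eval step prints

```json
{"TP": 302, "FP": 0, "FN": 0, "sensitivity": 1.0,
 "positive_predictivity": 1.0, "tolerance_ms": 150.0}
```

— all 302 simulated beats found, none spurious, at the 150 ms matching
tolerance. The pipeline report contains

```json
"metrics": {"mean_hr_bpm": 60.30, "sdnn_ms": 69.54,
            "rmssd_ms": 42.83, "pnn50_pct": 36.33, "n_intervals": 301},
"coherence": {"score": 0.995, "peak_frequency_hz": 0.1, "attained": true}
```

meaning the detected tachogram oscillates almost entirely at the paced
0.1 Hz breathing frequency (99.5% of band power), the SDNN of ~70 ms
reflecting the injected 100 ms RSA modulation — the "quasi-sinusoidal heart
rate" a well-paced user is trained to produce. `beatkit session-sim
--lesson 3 --seed 11 --report lesson3.json` runs a whole simulated lesson
and writes its performance review.

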
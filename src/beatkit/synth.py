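"""Synthetic RSA-modulated ECG with exact ground-truth beat annotations.

Stands in for the wearable's live stream: paced breathing at 6-10 breaths/min
modulates the instantaneous RR interval sinusoidally (respiratory sinus
arrhythmia), beats are placed by integral pulse frequency modulation (IPFM),
and each beat is rendered as a P-QRS-T template at the configured sampling
rate (260 samples/s by default, the wearable's front-end rate).  Noise —
baseline wander, powerline hum, white Gaussian — is additive and fully
seeded, so every record is reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .detect import BeatAnnotation, ConfigurationError, ECGRecord
from .hrv import RRSeries

#: Minimum instantaneous RR in ms for the config to count as physiological.
MIN_INSTANT_RR_MS = 200.0
#: Highest frequency content of the default beat template (sharpest Gaussian
#: has sigma 8 ms; its spectrum is negligible beyond ~40 Hz).
TEMPLATE_MAX_FREQ_HZ = 40.0


@dataclass(frozen=True)
class NoiseConfig:
    """Additive noise model: two sinusoids plus white Gaussian noise.

    All amplitudes in mV (zero amplitudes yield a noise-free record);
    frequencies in Hz.  Baseline wander emulates respiration/motion drift,
    the powerline term mains interference.
    """

    baseline_wander_mv: float = 0.0
    baseline_wander_hz: float = 0.25
    powerline_mv: float = 0.0
    powerline_hz: float = 50.0
    gaussian_sd_mv: float = 0.0

    def __post_init__(self) -> None:
        for name in ("baseline_wander_mv", "powerline_mv", "gaussian_sd_mv"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    @property
    def silent(self) -> bool:
        return (
            self.baseline_wander_mv == 0
            and self.powerline_mv == 0
            and self.gaussian_sd_mv == 0
        )


#: Default beat template: Gaussian bumps (amplitude mV, centre s relative to
#: the R apex, width s) approximating P, Q, R, S and T waves of lead I.
DEFAULT_TEMPLATE = (
    (0.15, -0.200, 0.025),  # P
    (-0.10, -0.028, 0.010),  # Q
    (1.00, 0.000, 0.012),  # R
    (-0.15, 0.030, 0.010),  # S
    (0.30, 0.250, 0.060),  # T
)


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic recording.

    ``mean_rr_ms - rsa_gain_ms`` must exceed 200 ms so the instantaneous RR
    stays positive and physiological; ``fs_hz`` must be at least twice the
    template bandwidth.  ``rr_jitter_ms`` adds seeded white jitter to each
    interval on top of the RSA modulation (0 = deterministic tachogram).
    """

    duration_s: float
    mean_rr_ms: float = 1000.0
    rsa_gain_ms: float = 0.0
    breathing_rate_bpm: float = 6.0
    fs_hz: float = 260.0
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    seed: int = 0
    rr_jitter_ms: float = 0.0
    template: tuple = DEFAULT_TEMPLATE

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ConfigurationError("duration_s must be > 0")
        if self.rsa_gain_ms < 0:
            raise ConfigurationError("rsa_gain_ms must be >= 0")
        if not self.mean_rr_ms - self.rsa_gain_ms > MIN_INSTANT_RR_MS:
            raise ConfigurationError(
                "mean_rr_ms - rsa_gain_ms must exceed "
                f"{MIN_INSTANT_RR_MS:g} ms (got "
                f"{self.mean_rr_ms - self.rsa_gain_ms:g} ms)"
            )
        if not self.breathing_rate_bpm > 0:
            raise ConfigurationError("breathing_rate_bpm must be > 0")
        if self.fs_hz < 2 * TEMPLATE_MAX_FREQ_HZ:
            raise ConfigurationError(
                f"fs_hz must be at least {2 * TEMPLATE_MAX_FREQ_HZ:g} Hz "
                "(twice the beat-template bandwidth)"
            )
        if self.rr_jitter_ms < 0:
            raise ConfigurationError("rr_jitter_ms must be >= 0")

    @property
    def breathing_freq_hz(self) -> float:
        return self.breathing_rate_bpm / 60.0


def generate_rr_series(config: SynthConfig) -> RRSeries:
    """Generate beat times by integral pulse frequency modulation.

    The instantaneous rate is r(t) = 1000/RR(t) beats/s with
    RR(t) = mean_rr_ms - rsa_gain_ms * sin(2*pi*f_b*t); the integral of r is
    accumulated on a 1 ms grid and a beat is emitted at every unit crossing.
    The first beat is pinned at t = 0 and beats lie strictly within
    [0, duration_s).  With ``rsa_gain_ms = 0`` this degenerates to an exact
    metronome at ``mean_rr_ms``.
    """
    f_b = config.breathing_freq_hz
    dt = 1e-3  # integration grid, s
    t = np.arange(0.0, config.duration_s + dt, dt)
    rr_ms = config.mean_rr_ms - config.rsa_gain_ms * np.sin(2 * math.pi * f_b * t)
    rate = 1000.0 / rr_ms  # beats per second
    # Trapezoidal cumulative integral of the rate; exact for constant rate,
    # O(dt^2) otherwise — far below a millisecond over five minutes.
    integral = np.concatenate(
        [[0.0], np.cumsum(0.5 * (rate[1:] + rate[:-1]) * np.diff(t))]
    )
    n_beats = int(np.floor(integral[-1]))
    beat_times = [0.0]
    # Invert the monotone integral at each unit crossing k = 1, 2, ...
    ks = np.arange(1, n_beats + 1, dtype=float)
    idx = np.searchsorted(integral, ks, side="left")
    for k, i in zip(ks, idx):
        if i >= integral.size:
            break
        lo = i - 1
        frac = (k - integral[lo]) / (integral[i] - integral[lo])
        tb = t[lo] + frac * (t[i] - t[lo])
        # Strict half-open [0, T); the epsilon guards against a grid-rounding
        # crossing landing a hair inside T.
        if tb < config.duration_s - 1e-6:
            beat_times.append(float(tb))
    times = np.array(beat_times)
    if config.rr_jitter_ms > 0:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x7172]))
        jitter = rng.normal(0.0, config.rr_jitter_ms / 1000.0, times.size - 1)
        intervals = np.diff(times) + jitter
        intervals = np.maximum(intervals, MIN_INSTANT_RR_MS / 1000.0)
        times = np.concatenate([[0.0], np.cumsum(intervals)])
        times = times[times < config.duration_s]
    return RRSeries.from_beat_times(times)


def _render_template(config: SynthConfig) -> tuple[np.ndarray, int]:
    """Sample the beat template on the record grid around offset 0.

    Returns the template samples and the index (within the template array)
    of the R-apex sample.
    """
    half_s = 0.40  # template support, s, either side of the R apex
    n_half = int(round(half_s * config.fs_hz))
    tt = np.arange(-n_half, n_half + 1) / config.fs_hz
    wave = np.zeros_like(tt)
    for amp, mu, sigma in config.template:
        wave += amp * np.exp(-0.5 * ((tt - mu) / sigma) ** 2)
    return wave, n_half


def render_ecg(rr: RRSeries, config: SynthConfig) -> tuple[ECGRecord, BeatAnnotation]:
    """Render an RR series as a single-lead ECG with ground-truth annotations.

    A P-QRS-T template is centred at every beat time; the annotation marks
    the R-apex sample of each placed template (the argmax of the clean
    rendition near the beat time).  Record length is
    ``ceil(duration_s * fs_hz)`` samples.  Noise is applied per
    ``config.noise`` with randomness derived from ``config.seed``.
    """
    if len(rr) == 0 and rr.beat_times_s.size == 0:
        raise ConfigurationError("RR series is empty")
    n = int(math.ceil(config.duration_s * config.fs_hz))
    beat_times = rr.beat_times_s
    if np.any(beat_times >= config.duration_s) or np.any(beat_times < 0):
        raise ConfigurationError("beat times must lie within [0, duration_s)")
    clean = np.zeros(n)
    template, n_half = _render_template(config)
    apex_search = int(round(0.05 * config.fs_hz))
    apices = np.empty(beat_times.size, dtype=np.int64)
    for k, tb in enumerate(beat_times):
        centre = tb * config.fs_hz  # fractional sample of the R apex
        start = int(math.floor(centre)) - n_half
        # Resample the template at this beat's sub-sample phase.
        offs = (np.arange(start, start + template.size) - centre) / config.fs_hz
        wave = np.zeros_like(offs)
        for amp, mu, sigma in config.template:
            wave += amp * np.exp(-0.5 * ((offs - mu) / sigma) ** 2)
        lo = max(0, start)
        hi = min(n, start + wave.size)
        if hi > lo:
            clean[lo:hi] += wave[lo - start : hi - start]
        nominal = int(round(centre))
        w_lo = max(0, nominal - apex_search)
        w_hi = min(n, nominal + apex_search + 1)
        apices[k] = w_lo + int(np.argmax(clean[w_lo:w_hi]))
    record = ECGRecord(clean, config.fs_hz, record_id=f"synth-{config.seed}")
    if not config.noise.silent:
        record = add_noise(record, config.noise, seed=config.seed)
    annotation = BeatAnnotation(apices, config.fs_hz)
    return record, annotation


def add_noise(record: ECGRecord, noise: NoiseConfig, seed: int) -> ECGRecord:
    """Add baseline wander, powerline hum and white Gaussian noise.

    Output has the same length and sampling rate; with an all-zero
    :class:`NoiseConfig` the samples are returned unchanged.  Fixed seed,
    identical output.
    """
    if noise.silent:
        return record
    t = np.arange(record.n_samples) / record.fs_hz
    out = record.samples.copy()
    if noise.baseline_wander_mv > 0:
        out += noise.baseline_wander_mv * np.sin(
            2 * math.pi * noise.baseline_wander_hz * t
        )
    if noise.powerline_mv > 0:
        out += noise.powerline_mv * np.sin(2 * math.pi * noise.powerline_hz * t)
    if noise.gaussian_sd_mv > 0:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x0E17]))
        out += rng.normal(0.0, noise.gaussian_sd_mv, record.n_samples)
    return ECGRecord(out, record.fs_hz, record.record_id)


def synthesize(config: SynthConfig) -> tuple[ECGRecord, BeatAnnotation, RRSeries]:
    """Convenience wrapper: RR generation plus rendering in one call."""
    rr = generate_rr_series(config)
    record, annotation = render_ecg(rr, config)
    return record, annotation, rr
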
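"""Breathing pacer, goal waveform, and coherence scoring of the HR waveform.

The biofeedback loop asks the user to pace breathing against a visual cue;
paced breathing at 6-10 breaths/min elicits respiratory sinus arrhythmia, so
a well-paced user shows a quasi-sinusoidal heart-rate waveform at the pacer
frequency.  The app leaves "did I match the goal?" to the user's eye; here
the judgement is mechanized as a spectral-concentration (coherence) score —
the fraction of heart-rate spectral power inside a narrow band around the
pacer frequency, relative to the 0.04-0.4 Hz band that spans LF+HF heart
rate variability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .detect import ConfigurationError
from .hrv import HRWaveform

#: Spectral band over which total HRV power is measured (LF + HF), Hz.
BAND_LO_HZ = 0.04
BAND_HI_HZ = 0.40
#: Half-width of the target band centred on the pacer frequency, Hz.
TARGET_HALF_WIDTH_HZ = 0.015
#: Coherence score at or above this counts as goal attainment.
ATTAINMENT_THRESHOLD = 0.6
#: Goal-waveform amplitude never drops below this floor, bpm.
AMPLITUDE_FLOOR_BPM = 2.0
DEFAULT_BASELINE_BPM = 70.0


class ScoreUnavailable(RuntimeError):
    """The HR window is incomplete; no coherence score can be formed."""


@dataclass(frozen=True)
class PacerConfig:
    """Breathing pacer: rate plus the inhale/hold/exhale split of one cycle.

    The single hold is placed after the inhale; the fractions are
    configurable because where (or whether) the hold sits in the cycle is a
    UI convention, not physiology.
    """

    breaths_per_min: float = 6.0
    inhale_frac: float = 0.4
    hold_frac: float = 0.1
    exhale_frac: float = 0.5

    def __post_init__(self) -> None:
        if not 4.0 <= self.breaths_per_min <= 12.0:
            raise ConfigurationError(
                f"breaths_per_min must be in [4, 12], got {self.breaths_per_min}"
            )
        fracs = (self.inhale_frac, self.hold_frac, self.exhale_frac)
        if any(f < 0 for f in fracs):
            raise ConfigurationError("phase fractions must be >= 0")
        if not math.isclose(sum(fracs), 1.0, abs_tol=1e-9):
            raise ConfigurationError(
                f"phase fractions must sum to 1, got {sum(fracs):g}"
            )

    @property
    def cycle_s(self) -> float:
        return 60.0 / self.breaths_per_min

    @property
    def frequency_hz(self) -> float:
        return self.breaths_per_min / 60.0


@dataclass(frozen=True)
class PacerState:
    """Instantaneous pacer cue: which phase, how far through it, which cycle."""

    phase: str  # "inhale" | "hold" | "exhale"
    phase_progress: float  # in [0, 1)
    cycle_index: int


def pacer_at(config: PacerConfig, t: float) -> PacerState:
    """Evaluate the deterministic pacer schedule at time ``t`` seconds.

    Within each cycle of length C = 60/breaths_per_min: inhale on
    [0, i*C), hold on [i*C, (i+h)*C), exhale on [(i+h)*C, C).  Zero-length
    phases are skipped; progress resets to 0 at each phase boundary.
    """
    if t < 0:
        raise ConfigurationError(f"t must be >= 0, got {t}")
    c = config.cycle_s
    cycle = int(math.floor(t / c + 1e-12))
    u = t - cycle * c
    if u < 0:  # guard against floating slop at a cycle boundary
        u, cycle = 0.0, cycle
    bounds = (
        ("inhale", 0.0, config.inhale_frac * c),
        ("hold", config.inhale_frac * c, (config.inhale_frac + config.hold_frac) * c),
        ("exhale", (config.inhale_frac + config.hold_frac) * c, c),
    )
    for name, lo, hi in bounds:
        if hi > lo and lo - 1e-12 <= u < hi - 1e-12 * (hi == c):
            if u < lo:
                u = lo
            return PacerState(
                phase=name,
                phase_progress=(u - lo) / (hi - lo),
                cycle_index=cycle,
            )
    # u landed at (or within floating slop of) the cycle end: next cycle start.
    first = next(name for name, lo, hi in bounds if hi > lo)
    return PacerState(phase=first, phase_progress=0.0, cycle_index=cycle + 1)


def pacer_schedule(
    config: PacerConfig, duration_s: float, dt_s: float = 0.25
) -> list[tuple[float, PacerState]]:
    """Sample the pacer schedule on a regular grid (for UI/CSV export)."""
    if not duration_s > 0 or not dt_s > 0:
        raise ConfigurationError("duration_s and dt_s must be > 0")
    ts = np.arange(0.0, duration_s, dt_s)
    return [(float(t), pacer_at(config, float(t))) for t in ts]


@dataclass(frozen=True)
class GoalWaveform:
    """Target HR sinusoid shown alongside the live waveform.

    g(t) = baseline + amplitude * sin(2*pi*frequency*t + phase), with t = 0
    at a pacer inhale onset.  ``is_default`` marks a goal built without any
    observed HR (fallback baseline).
    """

    frequency_hz: float
    amplitude_bpm: float
    baseline_bpm: float
    phase_rad: float = -math.pi / 2  # HR minimum, rising, at inhale onset
    is_default: bool = False

    def __post_init__(self) -> None:
        if not self.amplitude_bpm > 0:
            raise ConfigurationError("amplitude_bpm must be > 0")
        if not 0.05 < self.frequency_hz < 0.25:
            raise ConfigurationError(
                "frequency_hz must be in (0.05, 0.25) — the valid pacer range"
            )

    def sample(self, t: np.ndarray) -> np.ndarray:
        return self.baseline_bpm + self.amplitude_bpm * np.sin(
            2 * math.pi * self.frequency_hz * np.asarray(t) + self.phase_rad
        )


def make_goal(
    config: PacerConfig,
    recent_hr: HRWaveform | None,
    amplitude_floor_bpm: float = AMPLITUDE_FLOOR_BPM,
) -> GoalWaveform:
    """Build the goal waveform from the pacer and the user's recent HR.

    Baseline is the mean of the recent waveform; amplitude is the observed
    oscillation amplitude (sqrt(2) times the standard deviation of the
    linearly detrended waveform — exact for a pure sinusoid, robust to the
    window cutting a cycle mid-phase), never below the configured floor.
    With no HR available a default goal at 70 bpm is returned, flagged as
    such.
    """
    if recent_hr is None or recent_hr.hr_bpm.size == 0:
        return GoalWaveform(
            frequency_hz=config.frequency_hz,
            amplitude_bpm=amplitude_floor_bpm,
            baseline_bpm=DEFAULT_BASELINE_BPM,
            is_default=True,
        )
    x = recent_hr.hr_bpm
    baseline = float(np.mean(x))
    detrended = sps.detrend(x, type="linear") if x.size > 1 else x - baseline
    observed = math.sqrt(2.0) * float(np.std(detrended))
    return GoalWaveform(
        frequency_hz=config.frequency_hz,
        amplitude_bpm=max(amplitude_floor_bpm, observed),
        baseline_bpm=baseline,
    )


@dataclass(frozen=True)
class CoherenceScore:
    """Spectral concentration of the HR waveform at the pacer frequency."""

    score: float
    peak_frequency_hz: float
    attained: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ConfigurationError("score must lie in [0, 1]")


def coherence(hr: HRWaveform, config: PacerConfig) -> CoherenceScore:
    """Score how much HR spectral power sits at the pacer frequency.

    The waveform (which must span a full window) is detrended (mean and
    linear trend removed), its periodogram taken over the window, and the
    score formed as power within ±0.015 Hz of the pacer frequency divided by
    total power in [0.04, 0.4] Hz.  ``peak_frequency_hz`` is the argmax bin
    in that band; attainment requires score >= 0.6 *and* the peak within the
    target band.  A spectrally empty band scores 0.
    """
    if not hr.full:
        raise ScoreUnavailable(
            f"need a full {hr.window_s:g} s window at {hr.resample_fs_hz:g} Hz "
            f"({int(round(hr.window_s * hr.resample_fs_hz))} samples), "
            f"got {hr.hr_bpm.size}"
        )
    x = sps.detrend(hr.hr_bpm, type="linear")
    freqs, power = sps.periodogram(x, fs=hr.resample_fs_hz, window="boxcar")
    band = (freqs >= BAND_LO_HZ) & (freqs <= BAND_HI_HZ)
    f_p = config.frequency_hz
    target = band & (np.abs(freqs - f_p) <= TARGET_HALF_WIDTH_HZ)
    total = float(power[band].sum())
    # Relative floor: detrending a constant waveform leaves only float
    # round-off, which must score 0, not a ratio of numerical noise.
    floor = 1e-12 * max(1.0, float(np.mean(hr.hr_bpm)) ** 2)
    if total <= floor:
        return CoherenceScore(score=0.0, peak_frequency_hz=0.0, attained=False)
    score = float(power[target].sum()) / total
    score = min(1.0, max(0.0, score))
    peak = float(freqs[band][np.argmax(power[band])])
    attained = score >= ATTAINMENT_THRESHOLD and abs(peak - f_p) <= TARGET_HALF_WIDTH_HZ
    return CoherenceScore(score=score, peak_frequency_hz=peak, attained=attained)
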
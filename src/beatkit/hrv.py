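"""RR series, artifact filtering, instantaneous heart rate, time-domain HRV.

Conventions used throughout (stated once, relied on everywhere):

* RR intervals in milliseconds, beat times in seconds, heart rate in bpm.
* SDNN is the *population* standard deviation of the normal-to-normal
  intervals, matching the convention of common HRV tooling.
* pNN50 counts successive differences strictly greater than 50 ms.
* Successive differences that span a flagged (artifact) interval are excluded
  from RMSSD/pNN50 so artifacts do not leak into the difference statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detect import BeatAnnotation, ConfigurationError

#: Absolute physiological bounds on a credible RR interval, ms.
RR_MIN_MS = 300.0
RR_MAX_MS = 2000.0
#: Maximum relative deviation from the 5-interval running median.
RR_MEDIAN_DEV = 0.30

DEFAULT_RESAMPLE_FS_HZ = 4.0
DEFAULT_WINDOW_S = 60.0


class WaveformUnavailable(RuntimeError):
    """Too few usable beats to form a heart-rate waveform (show nothing,
    never garbage)."""


class MetricsUnavailable(RuntimeError):
    """Too few usable intervals to compute HRV metrics."""


@dataclass(frozen=True)
class RRSeries:
    """Beat times and inter-beat intervals, the substrate of HRV analysis.

    ``intervals_ms[i]`` is the interval ending at ``beat_times_s[i+1]``;
    ``flags[i]`` marks it as an artifact (excluded from metrics but retained
    in the series).
    """

    beat_times_s: np.ndarray
    intervals_ms: np.ndarray
    flags: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        t = np.asarray(self.beat_times_s, dtype=float)
        rr = np.asarray(self.intervals_ms, dtype=float)
        flags = (
            np.zeros(rr.size, dtype=bool)
            if self.flags is None
            else np.asarray(self.flags, dtype=bool)
        )
        object.__setattr__(self, "beat_times_s", t)
        object.__setattr__(self, "intervals_ms", rr)
        object.__setattr__(self, "flags", flags)
        if rr.size != max(t.size - 1, 0):
            raise ConfigurationError(
                f"expected {max(t.size - 1, 0)} intervals for {t.size} beats, "
                f"got {rr.size}"
            )
        if flags.size != rr.size:
            raise ConfigurationError("flags must have one entry per interval")
        if rr.size:
            derived = np.diff(t) * 1000.0
            if not np.allclose(derived, rr, rtol=0, atol=1e-6):
                raise ConfigurationError(
                    "intervals_ms inconsistent with beat_times_s"
                )
            if np.any(rr <= 0):
                raise ConfigurationError("all intervals must be positive")

    @classmethod
    def from_beat_times(cls, beat_times_s, flags=None) -> "RRSeries":
        t = np.asarray(beat_times_s, dtype=float)
        return cls(t, np.diff(t) * 1000.0, flags)

    def __len__(self) -> int:
        return int(self.intervals_ms.size)

    @property
    def unflagged_ms(self) -> np.ndarray:
        return self.intervals_ms[~self.flags]


@dataclass(frozen=True)
class HRWaveform:
    """Uniformly resampled instantaneous heart rate over a trailing window.

    This is the biofeedback display signal: a 1-minute rolling view of heart
    rate in which respiratory sinus arrhythmia shows as a quasi-sinusoid.
    """

    hr_bpm: np.ndarray
    resample_fs_hz: float = DEFAULT_RESAMPLE_FS_HZ
    window_s: float = DEFAULT_WINDOW_S
    t_start_s: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "hr_bpm", np.asarray(self.hr_bpm, dtype=float))

    @property
    def times_s(self) -> np.ndarray:
        return self.t_start_s + np.arange(self.hr_bpm.size) / self.resample_fs_hz

    @property
    def full(self) -> bool:
        return self.hr_bpm.size == int(round(self.window_s * self.resample_fs_hz))


@dataclass(frozen=True)
class HRVMetrics:
    """Time-domain HRV summary of a segment."""

    mean_hr_bpm: float
    sdnn_ms: float
    rmssd_ms: float
    pnn50_pct: float
    n_intervals: int

    def as_dict(self) -> dict:
        return {
            "mean_hr_bpm": self.mean_hr_bpm,
            "sdnn_ms": self.sdnn_ms,
            "rmssd_ms": self.rmssd_ms,
            "pnn50_pct": self.pnn50_pct,
            "n_intervals": self.n_intervals,
        }


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def beats_to_rr(annotation: BeatAnnotation) -> RRSeries:
    """Convert R-peak sample indices into beat times and RR intervals.

    No artifact filtering is applied here; see :func:`filter_rr`.
    """
    if len(annotation) < 2:
        raise MetricsUnavailable(
            f"need at least 2 beats to form an RR series, got {len(annotation)}"
        )
    return RRSeries.from_beat_times(annotation.times_s)


def filter_rr(rr: RRSeries) -> RRSeries:
    """Flag artifact intervals; the series itself is retained unchanged.

    Two rules: (1) absolute bounds — intervals outside [300, 2000] ms are not
    credible sinus beats; (2) intervals deviating more than 30% from the
    5-interval running median of the bound-passing intervals (shrinking,
    centred window).  Bound-flagged intervals are excluded before the median
    is formed so a single gross artifact cannot drag its neighbours out.
    """
    x = rr.intervals_ms
    flags = (x < RR_MIN_MS) | (x > RR_MAX_MS)
    surviving = np.flatnonzero(~flags)
    vals = x[surviving]
    for j, i in enumerate(surviving):
        window = vals[max(0, j - 2) : j + 3]
        med = float(np.median(window))
        if med > 0 and abs(x[i] - med) / med > RR_MEDIAN_DEV:
            flags[i] = True
    return RRSeries(rr.beat_times_s, rr.intervals_ms, flags)


def instantaneous_hr(
    rr: RRSeries,
    resample_fs_hz: float = DEFAULT_RESAMPLE_FS_HZ,
    window_s: float = DEFAULT_WINDOW_S,
) -> HRWaveform:
    """Resample instantaneous heart rate over the trailing window.

    HR = 60000/RR is assigned at each interval's second beat time, linearly
    interpolated, and sampled uniformly at ``resample_fs_hz`` over the last
    ``window_s`` seconds.  Before the first beat pair the waveform holds the
    first value.  Raises :class:`WaveformUnavailable` with fewer than two
    unflagged intervals in the window.
    """
    if not resample_fs_hz > 0 or not window_s > 0:
        raise ConfigurationError("resample_fs_hz and window_s must be > 0")
    ok = ~rr.flags
    t_hr = rr.beat_times_s[1:][ok]
    hr = 60000.0 / rr.intervals_ms[ok]
    t_end = rr.beat_times_s[-1] if rr.beat_times_s.size else 0.0
    t0 = max(0.0, t_end - window_s)
    in_window = t_hr >= t0
    if int(np.count_nonzero(in_window)) < 2:
        raise WaveformUnavailable(
            "need at least 2 unflagged intervals inside the window"
        )
    n = int(round((t_end - t0) * resample_fs_hz))
    grid = t0 + np.arange(n) / resample_fs_hz
    wave = np.interp(grid, t_hr, hr)  # holds endpoints outside [t_hr0, t_hrN]
    return HRWaveform(
        hr_bpm=wave,
        resample_fs_hz=float(resample_fs_hz),
        window_s=float(window_s),
        t_start_s=float(t0),
    )


def time_domain_metrics(rr: RRSeries) -> HRVMetrics:
    """Compute mean HR, SDNN, RMSSD and pNN50 over the unflagged intervals.

    Raises :class:`MetricsUnavailable` with fewer than two unflagged
    intervals.  RMSSD/pNN50 use only successive pairs where both intervals
    are adjacent in the original series and unflagged.
    """
    ok = ~rr.flags
    nn = rr.intervals_ms[ok]
    if nn.size < 2:
        raise MetricsUnavailable(
            f"need at least 2 unflagged intervals, got {nn.size}"
        )
    mean_rr = float(np.mean(nn))
    sdnn = float(np.std(nn))  # population SD
    pair_ok = ok[1:] & ok[:-1]
    diffs = np.diff(rr.intervals_ms)[pair_ok]
    if diffs.size:
        rmssd = float(np.sqrt(np.mean(diffs**2)))
        pnn50 = 100.0 * float(np.count_nonzero(np.abs(diffs) > 50.0)) / diffs.size
    else:
        rmssd = 0.0
        pnn50 = 0.0
    return HRVMetrics(
        mean_hr_bpm=60000.0 / mean_rr,
        sdnn_ms=sdnn,
        rmssd_ms=rmssd,
        pnn50_pct=pnn50,
        n_intervals=int(nn.size),
    )
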
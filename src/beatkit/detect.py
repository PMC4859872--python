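"""Streaming R-peak detection and beat-matching evaluation.

The detector is a Pan-Tompkins-style chain (band-pass 5-15 Hz, five-point
derivative, squaring, 150 ms moving-window integration, adaptive signal/noise
thresholds with a 200 ms refractory period and RR-based search-back) operating
on chunked input with bounded internal state, so an unbounded live stream and a
whole stored record yield identical detections.  The wearable this models
streams single-lead ECG at 260 samples/s and keeps no history on the sensor;
all memory therefore lives in :class:`DetectorState`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

log = logging.getLogger("beatkit.detect")

#: Matching tolerance convention for beat-by-beat comparison (ANSI/AAMI EC57).
DEFAULT_TOLERANCE_MS = 150.0
#: Physiological refractory period: no two QRS complexes closer than this.
REFRACTORY_S = 0.200
#: Moving-window integration length, sized to a wide QRS complex.
MWI_WINDOW_S = 0.150
#: Duration of the threshold learning phase before any beat is emitted.
WARMUP_S = 2.0
#: Search-back triggers when the current RR gap exceeds this multiple of the
#: running average RR.
SEARCHBACK_RR_FACTOR = 1.66


class ConfigurationError(ValueError):
    """Raised when an operation is invoked with an invalid configuration."""


@dataclass(frozen=True)
class ECGRecord:
    """Uniformly sampled single-lead voltage trace.

    Parameters
    ----------
    samples:
        Voltage in millivolts.
    fs_hz:
        Sampling rate in samples per second.
    record_id:
        Free-form label (file stem, database record name, ...).
    """

    samples: np.ndarray
    fs_hz: float
    record_id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if not self.fs_hz > 0:
            raise ConfigurationError(f"fs_hz must be > 0, got {self.fs_hz}")
        if samples.ndim != 1:
            raise ConfigurationError("samples must be one-dimensional")
        if samples.size and not np.all(np.isfinite(samples)):
            raise ConfigurationError("samples must all be finite")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


@dataclass(frozen=True)
class BeatAnnotation:
    """Ordered R-peak sample indices for a record sampled at ``fs_hz``."""

    sample_indices: np.ndarray
    fs_hz: float

    def __post_init__(self) -> None:
        idx = np.asarray(self.sample_indices, dtype=np.int64)
        object.__setattr__(self, "sample_indices", idx)
        if not self.fs_hz > 0:
            raise ConfigurationError(f"fs_hz must be > 0, got {self.fs_hz}")
        if idx.size and np.any(np.diff(idx) <= 0):
            raise ConfigurationError("sample_indices must be strictly increasing")
        if idx.size and idx[0] < 0:
            raise ConfigurationError("sample_indices must be non-negative")

    def __len__(self) -> int:
        return int(self.sample_indices.size)

    @property
    def times_s(self) -> np.ndarray:
        """Beat times in seconds from record start."""
        return self.sample_indices / self.fs_hz


# ---------------------------------------------------------------------------
# Streaming detector
# ---------------------------------------------------------------------------


def _design_chain(fs_hz: float):
    """Causal filter chain coefficients for a given sampling rate."""
    nyq = fs_hz / 2.0
    b_bp, a_bp = sps.butter(2, [5.0 / nyq, 15.0 / nyq], btype="band")
    # Five-point derivative, classic Pan-Tompkins FIR.
    b_der = np.array([2.0, 1.0, 0.0, -1.0, -2.0]) * (fs_hz / 8.0)
    n_mwi = max(1, int(round(MWI_WINDOW_S * fs_hz)))
    b_mwi = np.ones(n_mwi) / n_mwi
    return (b_bp, a_bp), b_der, b_mwi


@dataclass
class DetectorState:
    """Bounded internal state of the streaming detector.

    Holds filter delay lines, running signal/noise peak estimates, the adaptive
    threshold, the last detection position, and a short ring buffer of the
    band-passed and integrated signals needed for peak localisation and
    search-back.  Memory use is independent of how much signal has streamed by.
    """

    fs_hz: float
    n_consumed: int = 0
    spki: float = 0.0
    npki: float = 0.0
    last_qrs_mwi_idx: int = -10**18
    last_emitted_idx: int = -10**18
    rr_recent: list = field(default_factory=list)
    warmed_up: bool = False
    finalized: bool = False

    def __post_init__(self) -> None:
        if not self.fs_hz > 0:
            raise ConfigurationError(f"fs_hz must be > 0, got {self.fs_hz}")
        (b_bp, a_bp), b_der, b_mwi = _design_chain(self.fs_hz)
        self._b_bp, self._a_bp = b_bp, a_bp
        self._b_der, self._b_mwi = b_der, b_mwi
        self._zi_bp = np.zeros(max(len(b_bp), len(a_bp)) - 1)
        self._zi_der = np.zeros(len(b_der) - 1)
        self._zi_mwi = np.zeros(len(b_mwi) - 1)
        self.refractory_n = int(round(REFRACTORY_S * self.fs_hz))
        self.warmup_n = int(round(WARMUP_S * self.fs_hz))
        # History length: enough for localisation windows plus search-back over
        # a long RR gap (bounded at 3 s of signal).
        self._hist_n = int(round(3.0 * self.fs_hz))
        self._raw_hist = np.zeros(0)
        self._bp_hist = np.zeros(0)
        self._mwi_hist = np.zeros(0)
        self._hist_start = 0  # absolute index of _*_hist[0]
        self._scan_pos = 0  # next absolute index to test as a local maximum
        self._warmup_candidates: list[tuple[int, float]] = []
        self._candidates_since_qrs: list[tuple[int, float]] = []

    # -- threshold ---------------------------------------------------------

    @property
    def threshold(self) -> float:
        return self.npki + 0.25 * (self.spki - self.npki)

    def _avg_rr_n(self) -> float:
        if not self.rr_recent:
            return 1.0 * self.fs_hz  # assume 60 bpm until measured
        return float(np.mean(self.rr_recent[-8:]))

    # -- internal helpers --------------------------------------------------

    def _append_history(
        self, raw: np.ndarray, bp: np.ndarray, mwi: np.ndarray
    ) -> None:
        self._raw_hist = np.concatenate([self._raw_hist, raw])
        self._bp_hist = np.concatenate([self._bp_hist, bp])
        self._mwi_hist = np.concatenate([self._mwi_hist, mwi])

    def _trim_history(self) -> None:
        # Keep a full lookback window behind the scan position; anything
        # older can never be consulted again.
        excess = (self._scan_pos - self._hist_n) - self._hist_start
        if excess > 0:
            self._raw_hist = self._raw_hist[excess:]
            self._bp_hist = self._bp_hist[excess:]
            self._mwi_hist = self._mwi_hist[excess:]
            self._hist_start += excess

    def _hist(self, arr: np.ndarray, abs_idx: int) -> float:
        return float(arr[abs_idx - self._hist_start])

    def _locate_r(self, mwi_idx: int) -> int:
        """Map an MWI peak to the R-apex sample.

        The integrator output lags the QRS, so first take the largest
        band-passed magnitude excursion in the window preceding the MWI
        peak, then refine to the raw sample with the largest deviation from
        the local window mean.  Both steps use magnitudes, keeping the
        location polarity-independent; the raw refinement removes the
        band-pass group delay.
        """
        w = int(round((MWI_WINDOW_S + 0.075) * self.fs_hz))
        lo = max(self._hist_start, mwi_idx - w)
        seg = self._bp_hist[lo - self._hist_start : mwi_idx + 1 - self._hist_start]
        if seg.size == 0:
            return mwi_idx
        bp_idx = lo + int(np.argmax(np.abs(seg)))
        r_lo = max(self._hist_start, bp_idx - int(round(0.20 * self.fs_hz)))
        r_hi = min(self._hist_start + self._raw_hist.size, bp_idx + 1)
        raw = self._raw_hist[r_lo - self._hist_start : r_hi - self._hist_start]
        if raw.size == 0:
            return bp_idx
        return r_lo + int(np.argmax(np.abs(raw - raw.mean())))

    def _emit(self, mwi_idx: int, out: list[int]) -> None:
        r_idx = self._locate_r(mwi_idx)
        if r_idx - self.last_emitted_idx < self.refractory_n:
            return
        if self.last_qrs_mwi_idx > -(10**17):
            rr = mwi_idx - self.last_qrs_mwi_idx
            self.rr_recent.append(rr)
            if len(self.rr_recent) > 8:
                self.rr_recent = self.rr_recent[-8:]
        self.last_qrs_mwi_idx = mwi_idx
        self.last_emitted_idx = r_idx
        self._candidates_since_qrs = []
        out.append(r_idx)

    def _classify(self, idx: int, v: float, out: list[int]) -> None:
        """Adaptive-threshold decision for one candidate MWI peak."""
        # Search-back: long gap since the last QRS -> revisit rejected peaks.
        gap_limit = SEARCHBACK_RR_FACTOR * self._avg_rr_n()
        if (
            self.last_qrs_mwi_idx > -(10**17)
            and idx - self.last_qrs_mwi_idx > gap_limit
            and self._candidates_since_qrs
        ):
            back = [
                (i, val)
                for (i, val) in self._candidates_since_qrs
                if val > 0.5 * self.threshold
                and i - self.last_qrs_mwi_idx > self.refractory_n
            ]
            if back:
                bi, bv = max(back, key=lambda t: t[1])
                self.spki = 0.25 * bv + 0.75 * self.spki
                self._emit(bi, out)
        if v > self.threshold and idx - self.last_qrs_mwi_idx > self.refractory_n:
            self.spki = 0.125 * v + 0.875 * self.spki
            self._emit(idx, out)
        else:
            self.npki = 0.125 * v + 0.875 * self.npki
            self._candidates_since_qrs.append((idx, v))
            if len(self._candidates_since_qrs) > 64:
                self._candidates_since_qrs = self._candidates_since_qrs[-64:]

    def _scan(self, out: list[int]) -> None:
        """Advance over MWI samples whose right neighbour is available."""
        end = self._hist_start + self._mwi_hist.size - 1  # need idx+1
        while self._scan_pos < end:
            i = self._scan_pos
            if i >= self._hist_start + 1:
                prev = self._hist(self._mwi_hist, i - 1)
                cur = self._hist(self._mwi_hist, i)
                nxt = self._hist(self._mwi_hist, i + 1)
                if cur > prev and cur >= nxt and cur > 0:
                    if not self.warmed_up:
                        self._warmup_candidates.append((i, cur))
                    else:
                        self._classify(i, cur, out)
            self._scan_pos += 1
            if not self.warmed_up and self._scan_pos >= self.warmup_n:
                self._finish_warmup(out)

    def _finish_warmup(self, out: list[int]) -> None:
        """Initialise thresholds from the first two seconds, then replay."""
        seg = self._mwi_hist[: self.warmup_n - self._hist_start]
        peak = float(seg.max(initial=0.0))
        self.spki = 0.5 * peak
        self.npki = 0.1 * peak
        self.warmed_up = True
        for i, v in self._warmup_candidates:
            self._classify(i, v, out)
        self._warmup_candidates = []


def process_chunk(
    state: DetectorState, chunk: np.ndarray
) -> tuple[DetectorState, list[int]]:
    """Consume one chunk of samples, returning newly detected R-peak indices.

    Emitted indices are absolute (stream-global) and strictly increasing;
    detection output is invariant to how the stream is partitioned into
    chunks, because every per-sample decision depends only on absolute sample
    position and causally filtered values carried in ``state``.
    """
    if state.finalized:
        raise ConfigurationError("detector already finalized")
    x = np.asarray(chunk, dtype=float).ravel()
    out: list[int] = []
    if x.size == 0:
        return state, out
    bp, state._zi_bp = sps.lfilter(state._b_bp, state._a_bp, x, zi=state._zi_bp)
    der, state._zi_der = sps.lfilter(state._b_der, [1.0], bp, zi=state._zi_der)
    sq = der * der
    mwi, state._zi_mwi = sps.lfilter(state._b_mwi, [1.0], sq, zi=state._zi_mwi)
    state._append_history(x, bp, mwi)
    state.n_consumed += x.size
    state._scan(out)
    state._trim_history()
    return state, out


def finalize(state: DetectorState, n_samples: int | None = None) -> list[int]:
    """Flush the detector at end of stream.

    Pads the chain with 0.5 s of zeros so integrator peaks from beats near the
    record end are still scanned, then discards any localisation outside the
    true record.  ``n_samples`` bounds emitted indices (defaults to the number
    of samples consumed).
    """
    if state.finalized:
        return []
    n_real = state.n_consumed if n_samples is None else n_samples
    pad = np.zeros(int(round(0.5 * state.fs_hz)))
    _, out = process_chunk(state, pad)
    state.finalized = True
    return [i for i in out if i < n_real]


def detect_rpeaks(record: ECGRecord) -> BeatAnnotation:
    """Batch R-peak detection: identical to streaming the record through
    :func:`process_chunk` and flushing with :func:`finalize`."""
    state = DetectorState(fs_hz=record.fs_hz)
    if record.n_samples < state.warmup_n:
        log.warning(
            "record %r shorter than detector warm-up (%d < %d samples); "
            "returning empty annotation",
            record.record_id,
            record.n_samples,
            state.warmup_n,
        )
        return BeatAnnotation(np.empty(0, dtype=np.int64), record.fs_hz)
    _, idx = process_chunk(state, record.samples)
    idx += finalize(state, n_samples=record.n_samples)
    return BeatAnnotation(np.asarray(sorted(idx), dtype=np.int64), record.fs_hz)


# ---------------------------------------------------------------------------
# Beat-matching evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DetectionEvaluation:
    """Tolerance-window beat-matching statistics.

    ``sensitivity`` = TP/(TP+FN), ``positive_predictivity`` = TP/(TP+FP).
    A degenerate ratio (zero denominator) is reported as 0.0 with the
    corresponding flag set, so aggregation never silently propagates NaN.
    """

    true_positives: int
    false_positives: int
    false_negatives: int
    tolerance_ms: float
    sensitivity_degenerate: bool = False
    ppv_degenerate: bool = False

    @property
    def sensitivity(self) -> float:
        d = self.true_positives + self.false_negatives
        return self.true_positives / d if d else 0.0

    @property
    def positive_predictivity(self) -> float:
        d = self.true_positives + self.false_positives
        return self.true_positives / d if d else 0.0


def evaluate_detections(
    detected: BeatAnnotation,
    reference: BeatAnnotation,
    tolerance_ms: float = DEFAULT_TOLERANCE_MS,
) -> DetectionEvaluation:
    """Match detected against reference beats one-to-one.

    Detections are walked in time order; each matches the nearest unmatched
    reference beat within the tolerance window (ties broken toward the earlier
    reference beat).  Unmatched detections count as false positives, unmatched
    reference beats as false negatives.
    """
    if detected.fs_hz != reference.fs_hz:
        raise ConfigurationError(
            f"sampling rates differ: detected {detected.fs_hz} Hz "
            f"vs reference {reference.fs_hz} Hz"
        )
    if not tolerance_ms > 0:
        raise ConfigurationError("tolerance_ms must be > 0")
    tol_n = tolerance_ms * detected.fs_hz / 1000.0
    ref = reference.sample_indices
    used = np.zeros(ref.size, dtype=bool)
    tp = 0
    for d in detected.sample_indices:
        if ref.size == 0:
            break
        dist = np.abs(ref.astype(float) - d)
        dist[used] = np.inf
        j = int(np.argmin(dist))  # argmin takes the first (earlier) on ties
        if dist[j] <= tol_n:
            used[j] = True
            tp += 1
    fp = len(detected) - tp
    fn = len(reference) - tp
    return DetectionEvaluation(
        true_positives=tp,
        false_positives=fp,
        false_negatives=fn,
        tolerance_ms=float(tolerance_ms),
        sensitivity_degenerate=(tp + fn) == 0,
        ppv_degenerate=(tp + fp) == 0,
    )


@dataclass(frozen=True)
class BenchmarkResult:
    """Per-record and pooled (gross) beat-matching statistics."""

    per_record: dict
    gross: DetectionEvaluation
    skipped: tuple = ()


def aggregate_evaluations(
    evaluations: dict[str, DetectionEvaluation], tolerance_ms: float
) -> DetectionEvaluation:
    """Pool per-record counts into gross statistics (summed TP/FP/FN)."""
    tp = sum(e.true_positives for e in evaluations.values())
    fp = sum(e.false_positives for e in evaluations.values())
    fn = sum(e.false_negatives for e in evaluations.values())
    return DetectionEvaluation(
        true_positives=tp,
        false_positives=fp,
        false_negatives=fn,
        tolerance_ms=float(tolerance_ms),
        sensitivity_degenerate=(tp + fn) == 0,
        ppv_degenerate=(tp + fp) == 0,
    )


def run_benchmark(
    record_paths: list,
    tolerance_ms: float = DEFAULT_TOLERANCE_MS,
) -> BenchmarkResult:
    """Run the detector over a set of WFDB records with reference annotations.

    ``record_paths`` are WFDB base paths (no extension).  Non-beat annotation
    symbols are excluded from the reference by the reader.  Unreadable records
    are skipped with a logged warning and listed in the result; an empty
    record set is an error, never a silent zero.
    """
    from .io import read_wfdb  # local import avoids a module cycle

    paths = list(record_paths)
    if not paths:
        raise ConfigurationError("benchmark called with an empty record set")
    per_record: dict[str, DetectionEvaluation] = {}
    skipped = []
    for p in paths:
        try:
            record, reference = read_wfdb(p)
        except Exception as exc:  # noqa: BLE001 - any read failure skips
            log.warning("skipping unreadable record %s: %s", p, exc)
            skipped.append((str(p), str(exc)))
            continue
        if len(reference) == 0:
            log.warning("record %s has no reference beats; skipping", p)
            skipped.append((str(p), "no reference beats"))
            continue
        detected = detect_rpeaks(record)
        key = record.record_id or str(p)
        if key in per_record:
            key = f"{key}#{len(per_record)}"
        per_record[key] = evaluate_detections(detected, reference, tolerance_ms)
    if not per_record:
        raise ConfigurationError("no readable records in benchmark set")
    gross = aggregate_evaluations(per_record, tolerance_ms)
    return BenchmarkResult(per_record=per_record, gross=gross, skipped=tuple(skipped))
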
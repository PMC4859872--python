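"""File formats, pipeline configuration, and the composed pipeline.

Formats
-------
* ECG CSV: self-describing comment header ``# fs_hz=260`` followed by
  ``sample_index,time_s,voltage_mv`` rows.  Diff-friendly; round-trips
  sample-identically.
* Peaks / RR CSV: same comment-header dialect.
* WFDB: PhysioNet .hea/.dat/.atr, the format of the MIT-BIH Arrhythmia
  Database.  Signal formats 16 (16-bit little-endian) and 212 (packed
  12-bit pairs, the MIT-BIH native format) are supported; annotations use
  the MIT format with non-beat symbols dropped when building a beat
  reference.

Sample indices are 0-based throughout; beat times are seconds from record
start.  Logging goes to standard error, reports to files only.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import biofeedback, hrv, synth
from .detect import BeatAnnotation, ConfigurationError, ECGRecord, detect_rpeaks

log = logging.getLogger("beatkit.io")


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------


def _read_header_meta(lines: list[str]) -> dict:
    meta = {}
    for line in lines:
        if not line.startswith("#"):
            break
        body = line[1:].strip()
        if "=" in body:
            k, v = body.split("=", 1)
            meta[k.strip()] = v.strip()
    return meta


def write_ecg_csv(record: ECGRecord, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs_hz={record.fs_hz:g}\n")
        if record.record_id:
            fh.write(f"# record_id={record.record_id}\n")
        fh.write("sample_index,time_s,voltage_mv\n")
        for i, v in enumerate(record.samples):
            fh.write(f"{i},{i / record.fs_hz:.6f},{v:.6f}\n")


def read_ecg_csv(path, fs_hz: float | None = None) -> ECGRecord:
    """Read the ECG CSV dialect.

    The sampling rate comes from the ``# fs_hz=`` header line; an explicit
    ``fs_hz`` argument may supply it when the header lacks one, but a
    conflict between the two is an error.  Malformed rows raise with their
    line number.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    meta = _read_header_meta(lines)
    header_fs = float(meta["fs_hz"]) if "fs_hz" in meta else None
    if header_fs is not None and fs_hz is not None and header_fs != fs_hz:
        raise ConfigurationError(
            f"{path}: fs_hz={header_fs:g} in header conflicts with "
            f"requested {fs_hz:g}"
        )
    eff_fs = header_fs if header_fs is not None else fs_hz
    if eff_fs is None:
        raise ConfigurationError(
            f"{path}: no fs_hz header line and no sampling rate given"
        )
    samples = []
    seen_header = False
    for lineno, line in enumerate(lines, start=1):
        if line.startswith("#") or not line.strip():
            continue
        if not seen_header:
            if line.strip() != "sample_index,time_s,voltage_mv":
                raise ConfigurationError(
                    f"{path}:{lineno}: unexpected column header {line!r}"
                )
            seen_header = True
            continue
        parts = line.split(",")
        if len(parts) != 3:
            raise ConfigurationError(
                f"{path}:{lineno}: expected 3 columns, got {len(parts)}"
            )
        try:
            samples.append(float(parts[2]))
        except ValueError as exc:
            raise ConfigurationError(
                f"{path}:{lineno}: non-numeric voltage {parts[2]!r}"
            ) from exc
    return ECGRecord(np.asarray(samples), eff_fs, record_id=meta.get("record_id", path.stem))


def write_peaks_csv(annotation: BeatAnnotation, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs_hz={annotation.fs_hz:g}\n")
        fh.write("sample_index\n")
        for i in annotation.sample_indices:
            fh.write(f"{int(i)}\n")


def read_peaks_csv(path, fs_hz: float | None = None) -> BeatAnnotation:
    path = Path(path)
    lines = path.read_text().splitlines()
    meta = _read_header_meta(lines)
    header_fs = float(meta["fs_hz"]) if "fs_hz" in meta else None
    if header_fs is not None and fs_hz is not None and header_fs != fs_hz:
        raise ConfigurationError(f"{path}: fs_hz conflict")
    eff_fs = header_fs if header_fs is not None else fs_hz
    if eff_fs is None:
        raise ConfigurationError(f"{path}: no fs_hz header line and none given")
    idx = []
    for lineno, line in enumerate(lines, start=1):
        if line.startswith("#") or not line.strip() or line.strip() == "sample_index":
            continue
        try:
            idx.append(int(line.strip()))
        except ValueError as exc:
            raise ConfigurationError(
                f"{path}:{lineno}: non-integer sample index {line!r}"
            ) from exc
    return BeatAnnotation(np.asarray(idx, dtype=np.int64), eff_fs)


def write_rr_csv(rr: hrv.RRSeries, path) -> None:
    """Columns beat_time_s,rr_ms,flag; the first beat carries an empty rr."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("beat_time_s,rr_ms,flag\n")
        fh.write(f"{rr.beat_times_s[0]:.6f},,\n")
        for t, x, f in zip(rr.beat_times_s[1:], rr.intervals_ms, rr.flags):
            fh.write(f"{t:.6f},{x:.3f},{int(f)}\n")


def read_rr_csv(path) -> hrv.RRSeries:
    path = Path(path)
    times, flags = [], []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith("#") or not line.strip() or line.startswith("beat_time_s"):
            continue
        parts = line.split(",")
        if len(parts) != 3:
            raise ConfigurationError(f"{path}:{lineno}: expected 3 columns")
        times.append(float(parts[0]))
        if parts[1].strip():
            flags.append(bool(int(parts[2])))
    t = np.asarray(times)
    return hrv.RRSeries(t, np.diff(t) * 1000.0, np.asarray(flags, dtype=bool))


# ---------------------------------------------------------------------------
# WFDB (.hea / .dat / .atr)
# ---------------------------------------------------------------------------

#: MIT annotation codes that denote beats (QRS complexes); other codes are
#: rhythm/signal-quality/non-beat events and are dropped from beat references.
_BEAT_CODES = {1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 25, 34, 35, 38}
_CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 25: "e", 34: "n",
    35: "x", 38: "f",
}
_SYMBOL_TO_CODE = {v: k for k, v in _CODE_TO_SYMBOL.items()}
# Non-beat symbols commonly seen in .atr files (mapped for writing fixtures).
_SYMBOL_TO_CODE.update({"~": 14, "|": 16, "+": 28, '"': 22})


def write_wfdb(
    record: ECGRecord,
    annotation: BeatAnnotation | None,
    basepath,
    gain: float = 200.0,
    symbols: list[str] | None = None,
) -> None:
    """Write a single-channel WFDB record (format 16) plus a .atr annotation.

    ``gain`` is in adu/mV.  ``symbols`` optionally assigns an annotation
    symbol per index (default all 'N', the synthetic normal beat).
    """
    base = Path(basepath)
    name = base.name
    adu = np.clip(np.round(record.samples * gain), -32768, 32767).astype("<i2")
    first = int(adu[0]) if adu.size else 0
    base.with_suffix(".hea").write_text(
        f"{name} 1 {record.fs_hz:g} {record.n_samples}\n"
        f"{name}.dat 16 {gain:g}/mV 16 0 {first} 0 0 ECG\n"
    )
    base.with_suffix(".dat").write_bytes(adu.tobytes())
    if annotation is not None:
        _write_atr(base.with_suffix(".atr"), annotation, symbols)


def _write_atr(path: Path, annotation: BeatAnnotation, symbols=None) -> None:
    if symbols is None:
        symbols = ["N"] * len(annotation)
    if len(symbols) != len(annotation):
        raise ConfigurationError("one symbol per annotation index required")
    words = bytearray()
    prev = 0
    for idx, sym in zip(annotation.sample_indices, symbols):
        code = _SYMBOL_TO_CODE.get(sym)
        if code is None:
            raise ConfigurationError(f"unknown annotation symbol {sym!r}")
        delta = int(idx) - prev
        prev = int(idx)
        if delta >= 1024:
            # SKIP (code 59): 4-byte interval, PDP-11 long (high word first).
            words += int(59 << 10).to_bytes(2, "little")
            words += ((delta >> 16) & 0xFFFF).to_bytes(2, "little")
            words += (delta & 0xFFFF).to_bytes(2, "little")
            delta = 0
        words += ((code << 10) | (delta & 0x3FF)).to_bytes(2, "little")
    words += (0).to_bytes(2, "little")  # EOF
    path.write_bytes(bytes(words))


def _read_atr(path: Path) -> tuple[np.ndarray, list[str]]:
    data = path.read_bytes()
    indices: list[int] = []
    symbols: list[str] = []
    t = 0
    i = 0
    pending_skip = 0
    while i + 1 < len(data):
        word = int.from_bytes(data[i : i + 2], "little")
        i += 2
        code = word >> 10
        interval = word & 0x3FF
        if code == 0 and interval == 0:
            break  # EOF
        if code == 59:  # SKIP: long interval in the next 4 bytes
            hi = int.from_bytes(data[i : i + 2], "little")
            lo = int.from_bytes(data[i + 2 : i + 4], "little")
            i += 4
            pending_skip += (hi << 16) | lo
            continue
        if code in (60, 61, 62):  # NUM / SUB / CHN modifiers: no time
            continue
        if code == 63:  # AUX: interval is a byte count, padded to even
            i += interval + (interval & 1)
            continue
        t += interval + pending_skip
        pending_skip = 0
        symbols.append(_CODE_TO_SYMBOL.get(code, "?"))
        indices.append(t)
    return np.asarray(indices, dtype=np.int64), symbols


def _parse_hea(path: Path):
    lines = [
        ln
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    rec = lines[0].split()
    name = rec[0].split("/")[0]
    n_sig = int(rec[1])
    fs = float(rec[2].split("/")[0]) if len(rec) > 2 else 250.0
    n_samp = int(rec[3]) if len(rec) > 3 else 0
    sigs = []
    for ln in lines[1 : 1 + n_sig]:
        f = ln.split()
        fmt = int(f[1].split("x")[0].split(":")[0].split("+")[0])
        gain_field = f[2] if len(f) > 2 else "200"
        gain_part = gain_field.split("/")[0]
        if "(" in gain_part:
            g, b = gain_part.split("(")
            gain = float(g)
            baseline = int(b.rstrip(")"))
        else:
            gain = float(gain_part)
            baseline = int(f[4]) if len(f) > 4 else 0  # adc zero
        if gain == 0:
            gain = 200.0  # WFDB convention for "unspecified"
        sigs.append({"file": f[0], "fmt": fmt, "gain": gain, "baseline": baseline})
    return name, n_sig, fs, n_samp, sigs


def _decode_212(raw: bytes, n_values: int) -> np.ndarray:
    """Unpack WFDB format 212: two 12-bit samples per 3 bytes."""
    b = np.frombuffer(raw, dtype=np.uint8)
    n_triplets = b.size // 3
    b = b[: n_triplets * 3].reshape(-1, 3).astype(np.int32)
    s0 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    s1 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    out = np.empty(2 * n_triplets, dtype=np.int32)
    out[0::2] = s0
    out[1::2] = s1
    out[out > 2047] -= 4096  # 12-bit two's complement
    return out[:n_values]


def read_wfdb(record_path) -> tuple[ECGRecord, BeatAnnotation]:
    """Read the first ECG channel of a WFDB record plus its beat reference.

    ``record_path`` is the base path without extension.  Annotation beat
    symbols become the reference; non-beat symbols are dropped.  A missing
    .atr file yields an empty annotation with a warning; a truncated signal
    file is an error.
    """
    base = Path(record_path)
    hea = base.with_suffix(".hea")
    if not hea.exists():
        raise ConfigurationError(f"missing header file {hea}")
    name, n_sig, fs, n_samp, sigs = _parse_hea(hea)
    if n_sig < 1:
        raise ConfigurationError(f"{hea}: no signals declared")
    sig0 = sigs[0]
    dat = base.parent / sig0["file"]
    if not dat.exists():
        raise ConfigurationError(f"missing signal file {dat}")
    raw = dat.read_bytes()
    n_values = n_samp * n_sig if n_samp else None
    if sig0["fmt"] == 16:
        avail = len(raw) // 2
        if n_values is not None and avail < n_values:
            raise ConfigurationError(
                f"{dat}: truncated signal file ({avail} < {n_values} values)"
            )
        flat = np.frombuffer(raw, dtype="<i2")[: n_values or (len(raw) // 2)]
    elif sig0["fmt"] == 212:
        avail = (len(raw) // 3) * 2
        if n_values is not None and avail < n_values:
            raise ConfigurationError(
                f"{dat}: truncated signal file ({avail} < {n_values} values)"
            )
        flat = _decode_212(raw, n_values if n_values is not None else avail)
    else:
        raise ConfigurationError(f"{dat}: unsupported WFDB format {sig0['fmt']}")
    channel = np.asarray(flat, dtype=float).reshape(-1, n_sig)[:, 0]
    samples_mv = (channel - sig0["baseline"]) / sig0["gain"]
    record = ECGRecord(samples_mv, fs, record_id=name)
    atr = base.with_suffix(".atr")
    if not atr.exists():
        log.warning("no annotation file for %s; returning empty annotation", base)
        return record, BeatAnnotation(np.empty(0, dtype=np.int64), fs)
    indices, symbols = _read_atr(atr)
    keep = np.asarray(
        [_SYMBOL_TO_CODE.get(s, -1) in _BEAT_CODES for s in symbols], dtype=bool
    )
    return record, BeatAnnotation(indices[keep], fs)


# ---------------------------------------------------------------------------
# Pipeline configuration and the composed pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PipelineConfig:
    """Effective configuration echoed into every report for reproducibility."""

    fs_hz: float = 260.0
    resample_fs_hz: float = 4.0
    tolerance_ms: float = 150.0
    breaths_per_min: float = 6.0
    window_s: float = 60.0
    seed: int = 0
    verbosity: str = "info"

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def run_pipeline(config: PipelineConfig, source) -> dict:
    """Detect -> HRV -> coherence on one input; returns the JSON-able report.

    ``source`` is a path to an ECG CSV, a WFDB base path, or a
    :class:`~beatkit.synth.SynthConfig` for a fully synthetic run.  A record
    with too few beats yields a report with explicit ``unavailable`` markers
    rather than fabricated numbers.
    """
    if isinstance(source, synth.SynthConfig):
        record, _, _ = synth.synthesize(source)
        source_desc = {"kind": "synth", **dataclasses.asdict(source)}
        source_desc["noise"] = dataclasses.asdict(source.noise)
        source_desc.pop("template", None)
    else:
        p = Path(source)
        if p.suffix == ".csv":
            record = read_ecg_csv(p, fs_hz=None if _csv_has_fs(p) else config.fs_hz)
        elif p.with_suffix(".hea").exists():
            record, _ = read_wfdb(p)
        else:
            raise ConfigurationError(f"cannot read input {source!r}")
        source_desc = {"kind": "file", "path": str(source)}
    report: dict = {
        "config": config.as_dict(),
        "source": source_desc,
        "record": {"n_samples": record.n_samples, "fs_hz": record.fs_hz,
                   "duration_s": record.duration_s},
    }
    annotation = detect_rpeaks(record)
    report["n_peaks"] = len(annotation)
    try:
        rr = hrv.filter_rr(hrv.beats_to_rr(annotation))
    except hrv.MetricsUnavailable as exc:
        report["metrics"] = {"unavailable": str(exc)}
        report["coherence"] = {"unavailable": "no RR series"}
        return report
    report["n_flagged_intervals"] = int(rr.flags.sum())
    try:
        report["metrics"] = hrv.time_domain_metrics(rr).as_dict()
    except hrv.MetricsUnavailable as exc:
        report["metrics"] = {"unavailable": str(exc)}
    pacer = biofeedback.PacerConfig(breaths_per_min=config.breaths_per_min)
    try:
        wave = hrv.instantaneous_hr(rr, config.resample_fs_hz, config.window_s)
        score = biofeedback.coherence(wave, pacer)
        report["coherence"] = {
            "score": score.score,
            "peak_frequency_hz": score.peak_frequency_hz,
            "attained": score.attained,
            "pacer_frequency_hz": pacer.frequency_hz,
        }
    except (hrv.WaveformUnavailable, biofeedback.ScoreUnavailable) as exc:
        report["coherence"] = {"unavailable": str(exc)}
    return report


def _csv_has_fs(path: Path) -> bool:
    with Path(path).open() as fh:
        for line in fh:
            if not line.startswith("#"):
                return False
            if line[1:].strip().startswith("fs_hz"):
                return True
    return False
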
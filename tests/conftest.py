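import numpy as np
import pytest

import beatkit as bk


@pytest.fixture(scope="session")
def metronome_record():
    """60 s noise-free record with one beat per second (unmodulated RR)."""
    cfg = bk.SynthConfig(duration_s=60.0, mean_rr_ms=1000.0, seed=0)
    record, annotation, rr = bk.synthesize(cfg)
    return cfg, record, annotation, rr


@pytest.fixture(scope="session")
def rsa_record():
    """300 s noise-free record with 100 ms RSA at 6 breaths/min."""
    cfg = bk.SynthConfig(
        duration_s=300.0, rsa_gain_ms=100.0, breathing_rate_bpm=6.0, seed=1
    )
    record, annotation, rr = bk.synthesize(cfg)
    return cfg, record, annotation, rr


@pytest.fixture(scope="session")
def rsa_detected_rr(rsa_record):
    """Detector-derived, artifact-filtered RR series of the RSA record."""
    _, record, _, _ = rsa_record
    return bk.filter_rr(bk.beats_to_rr(bk.detect_rpeaks(record)))


def random_rr_series(rng, n=None):
    """A plausible random RR series for oracle-equivalence checks."""
    n = n or int(rng.integers(5, 120))
    intervals = rng.uniform(400.0, 1500.0, size=n)
    times = np.concatenate([[0.0], np.cumsum(intervals) / 1000.0])
    flags = rng.random(n) < 0.1
    rr = bk.RRSeries.from_beat_times(times)
    return bk.RRSeries(rr.beat_times_s, rr.intervals_ms, flags)
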
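"""Streaming R-peak detector and beat-matching evaluation."""

import numpy as np
import pytest

import beatkit as bk
from beatkit.detect import ConfigurationError


def stream_in_chunks(record, chunk_size):
    state = bk.DetectorState(fs_hz=record.fs_hz)
    idx = []
    if chunk_size is None:
        state, idx = bk.process_chunk(state, record.samples)
    else:
        for i in range(0, record.n_samples, chunk_size):
            state, new = bk.process_chunk(state, record.samples[i : i + chunk_size])
            idx += new
    idx += bk.finalize(state, record.n_samples)
    return idx


def brute_force_match(detected, reference, tol_n):
    """Independent matching oracle: greedy nearest-unmatched over all pairs."""
    used = set()
    tp = 0
    for d in detected:
        best, best_dist = None, None
        for j, r in enumerate(reference):
            if j in used:
                continue
            dist = abs(int(r) - int(d))
            if dist <= tol_n and (best_dist is None or dist < best_dist):
                best, best_dist = j, dist
        if best is not None:
            used.add(best)
            tp += 1
    return tp, len(detected) - tp, len(reference) - tp


class TestStreaming:
    def test_flat_signal_yields_nothing(self):
        record = bk.ECGRecord(np.zeros(260 * 30), 260.0)
        assert len(bk.detect_rpeaks(record)) == 0

    def test_clean_record_all_beats_within_40ms(self, metronome_record):
        _, record, annotation, _ = metronome_record
        detected = bk.detect_rpeaks(record)
        assert len(detected) == 60
        err_ms = (
            np.abs(detected.sample_indices - annotation.sample_indices)
            / record.fs_hz
            * 1000.0
        )
        assert err_ms.max() <= 40.0

    @pytest.mark.parametrize("chunk_size", [1, 13, 260, None])
    def test_chunk_size_invariance(self, metronome_record, chunk_size):
        _, record, _, _ = metronome_record
        whole = list(bk.detect_rpeaks(record).sample_indices)
        assert stream_in_chunks(record, chunk_size) == whole

    def test_chunk_size_invariance_with_rsa_and_noise(self):
        cfg = bk.SynthConfig(
            duration_s=120.0,
            rsa_gain_ms=100.0,
            noise=bk.NoiseConfig(gaussian_sd_mv=0.05),
            seed=12,
        )
        record, _, _ = bk.synthesize(cfg)
        whole = stream_in_chunks(record, None)
        for chunk in (13, 260):
            assert stream_in_chunks(record, chunk) == whole

    def test_emitted_indices_strictly_increasing(self, rsa_record):
        _, record, _, _ = rsa_record
        idx = np.asarray(stream_in_chunks(record, 130))
        assert np.all(np.diff(idx) > 0)

    def test_refractory_respected(self, rsa_record):
        _, record, _, _ = rsa_record
        detected = bk.detect_rpeaks(record)
        gaps_s = np.diff(detected.sample_indices) / record.fs_hz
        assert gaps_s.min() >= 0.200

    def test_short_record_empty_with_warning(self, caplog):
        record = bk.ECGRecord(np.zeros(10), 260.0)
        with caplog.at_level("WARNING", logger="beatkit.detect"):
            out = bk.detect_rpeaks(record)
        assert len(out) == 0
        assert any("warm-up" in m for m in caplog.messages)

    def test_inverted_polarity_detects_all_beats(self, metronome_record):
        _, record, annotation, _ = metronome_record
        flipped = bk.ECGRecord(-record.samples, record.fs_hz)
        ev = bk.evaluate_detections(bk.detect_rpeaks(flipped), annotation, 150.0)
        assert ev.sensitivity == 1.0
        assert ev.positive_predictivity == 1.0

    def test_noise_free_perfect_scores(self, rsa_record):
        _, record, annotation, _ = rsa_record
        ev = bk.evaluate_detections(bk.detect_rpeaks(record), annotation, 150.0)
        assert ev.sensitivity == 1.0
        assert ev.positive_predictivity == 1.0

    def test_sensitivity_degrades_monotonically_with_noise(self):
        base = bk.SynthConfig(duration_s=120.0, rsa_gain_ms=100.0, seed=21)
        rr = bk.generate_rr_series(base)
        clean, annotation = bk.render_ecg(rr, base)
        sens = []
        for sd in (0.0, 0.05, 0.2, 0.5):
            noisy = bk.add_noise(clean, bk.NoiseConfig(gaussian_sd_mv=sd), seed=21)
            ev = bk.evaluate_detections(bk.detect_rpeaks(noisy), annotation, 150.0)
            sens.append(ev.sensitivity)
        assert all(a >= b for a, b in zip(sens, sens[1:]))

    def test_fs_validation(self):
        with pytest.raises(ConfigurationError):
            bk.DetectorState(fs_hz=0.0)


class TestEvaluate:
    def test_worked_example(self):
        detected = bk.BeatAnnotation(np.array([100, 400, 700]), 260.0)
        reference = bk.BeatAnnotation(np.array([102, 398, 705, 900]), 260.0)
        ev = bk.evaluate_detections(detected, reference, 150.0)
        assert (ev.true_positives, ev.false_positives, ev.false_negatives) == (3, 0, 1)
        assert ev.sensitivity == pytest.approx(0.75)
        assert ev.positive_predictivity == pytest.approx(1.0)

    def test_identity(self):
        ann = bk.BeatAnnotation(np.arange(0, 2600, 260), 260.0)
        ev = bk.evaluate_detections(ann, ann, 150.0)
        assert ev.sensitivity == 1.0 and ev.positive_predictivity == 1.0
        assert ev.false_positives == 0 and ev.false_negatives == 0

    def test_empty_detections_degenerate_flag(self):
        empty = bk.BeatAnnotation(np.empty(0, dtype=int), 260.0)
        ref = bk.BeatAnnotation(np.array([100, 200]), 260.0)
        ev = bk.evaluate_detections(empty, ref, 150.0)
        assert ev.sensitivity == 0.0
        assert ev.positive_predictivity == 0.0
        assert ev.ppv_degenerate

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            ref = np.cumsum(rng.integers(150, 350, size=40))
            jitter = rng.integers(-60, 60, size=ref.size)
            det = np.unique(ref + jitter)
            ev = bk.evaluate_detections(
                bk.BeatAnnotation(det, 260.0), bk.BeatAnnotation(ref, 260.0), 150.0
            )
            tol_n = 150.0 * 260.0 / 1000.0
            tp, fp, fn = brute_force_match(det, ref, tol_n)
            assert (ev.true_positives, ev.false_positives, ev.false_negatives) == (
                tp,
                fp,
                fn,
            )

    def test_mismatched_fs_rejected(self):
        a = bk.BeatAnnotation(np.array([1]), 260.0)
        b = bk.BeatAnnotation(np.array([1]), 360.0)
        with pytest.raises(ConfigurationError):
            bk.evaluate_detections(a, b, 150.0)


class TestBenchmark:
    @pytest.fixture()
    def wfdb_dir(self, tmp_path):
        for seed in (1, 2, 3):
            cfg = bk.SynthConfig(
                duration_s=60.0, rsa_gain_ms=80.0, seed=seed,
                noise=bk.NoiseConfig(gaussian_sd_mv=0.03),
            )
            record, annotation, _ = bk.synthesize(cfg)
            bk.write_wfdb(record, annotation, tmp_path / f"rec{seed}")
        return tmp_path

    def test_gross_equals_pooled_counts(self, wfdb_dir):
        paths = sorted(p.with_suffix("") for p in wfdb_dir.glob("*.hea"))
        result = bk.run_benchmark(paths, 150.0)
        tp = sum(e.true_positives for e in result.per_record.values())
        fp = sum(e.false_positives for e in result.per_record.values())
        fn = sum(e.false_negatives for e in result.per_record.values())
        assert result.gross.true_positives == tp
        assert result.gross.sensitivity == pytest.approx(tp / (tp + fn))
        assert result.gross.positive_predictivity == pytest.approx(tp / (tp + fp))

    def test_empty_set_is_an_error(self):
        with pytest.raises(ConfigurationError):
            bk.run_benchmark([], 150.0)

    def test_duplicated_record_pooling_invariance(self, wfdb_dir):
        path = sorted(p.with_suffix("") for p in wfdb_dir.glob("*.hea"))[0]
        single = bk.run_benchmark([path], 150.0)
        double = bk.run_benchmark([path, path], 150.0)
        assert double.gross.sensitivity == pytest.approx(single.gross.sensitivity)
        assert double.gross.positive_predictivity == pytest.approx(
            single.gross.positive_predictivity
        )

    def test_unreadable_record_skipped(self, wfdb_dir, caplog):
        with caplog.at_level("WARNING", logger="beatkit.detect"):
            paths = sorted(p.with_suffix("") for p in wfdb_dir.glob("*.hea"))
            result = bk.run_benchmark(paths + [wfdb_dir / "missing"], 150.0)
        assert len(result.skipped) == 1
        assert len(result.per_record) == 3
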
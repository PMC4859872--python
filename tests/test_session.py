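"""Session protocol engine: lessons, stage machine, review, task items."""

import numpy as np
import pytest

import beatkit as bk
from beatkit.detect import ConfigurationError
from beatkit.session import COGNITIVE_KINDS, TaskItem


def constant_rr_segment(t0, duration, rr_ms=1000.0):
    times = np.arange(t0, t0 + duration, rr_ms / 1000.0)
    return bk.RRSeries.from_beat_times(times)


def rsa_rr_segment(t0, duration, gain_ms=80.0, freq_hz=0.1, mean_ms=1000.0):
    times = [t0]
    t = t0
    while True:
        rr = mean_ms - gain_ms * np.sin(2 * np.pi * freq_hz * (t - t0))
        t += rr / 1000.0
        if t >= t0 + duration:
            break
        times.append(t)
    return bk.RRSeries.from_beat_times(np.array(times))


class TestBuildLesson:
    def test_difficulty_equals_index(self):
        for i in (1, 5):
            lesson = bk.build_lesson(i)
            assert all(t.difficulty_level == i for t in lesson.tasks)

    def test_deterministic(self):
        assert bk.build_lesson(3) == bk.build_lesson(3)

    def test_every_lesson_has_physical_and_cognitive(self):
        for i in range(1, 6):
            modalities = {t.modality for t in bk.build_lesson(i).tasks}
            assert modalities == {"physical", "cognitive"}

    def test_pacer_taper_monotone_decreasing(self):
        rates = [bk.build_lesson(i).pacer.breaths_per_min for i in range(1, 6)]
        assert rates[0] == 10.0 and rates[-1] == 6.0
        assert all(a > b for a, b in zip(rates, rates[1:]))

    def test_difficulty_monotone_over_lessons(self):
        levels = [
            max(t.difficulty_level for t in bk.build_lesson(i).tasks)
            for i in range(1, 6)
        ]
        assert all(a < b for a, b in zip(levels, levels[1:]))

    @pytest.mark.parametrize("index", [0, 6, -1])
    def test_out_of_range_rejected(self, index):
        with pytest.raises(ConfigurationError):
            bk.build_lesson(index)


class TestStateMachine:
    def test_stage_sequence_and_boundaries(self):
        lesson = bk.build_lesson(1)
        state = bk.start_session(lesson)
        assert state.stage == "baseline"
        b = lesson.baseline_duration_s
        state = bk.advance(state, constant_rr_segment(0.0, b), b)
        assert state.stage == "stress"
        s = lesson.stress_duration_s
        assert s == pytest.approx(60.0 * len(lesson.tasks))
        state = bk.advance(state, constant_rr_segment(b, s), s)
        assert state.stage == "recovery"
        r = lesson.recovery_duration_s
        state = bk.advance(state, rsa_rr_segment(b + s, r), r)
        assert state.stage == "review"

    def test_overshoot_carried_forward(self):
        lesson = bk.build_lesson(1)
        state = bk.start_session(lesson)
        b = lesson.baseline_duration_s
        state = bk.advance(state, constant_rr_segment(0.0, b + 10.0), b + 10.0)
        assert state.stage == "stress"
        assert state.stage_elapsed_s == pytest.approx(10.0)

    def test_advance_terminal_rejected(self):
        lesson = bk.build_lesson(1)
        state = bk.start_session(lesson)
        total = (
            lesson.baseline_duration_s
            + lesson.stress_duration_s
            + lesson.recovery_duration_s
        )
        state = bk.advance(state, constant_rr_segment(0.0, total), total)
        assert state.stage == "review"
        with pytest.raises(ConfigurationError):
            bk.advance(state, constant_rr_segment(total, 1.0), 1.0)
        done = bk.finish(state)
        assert done.stage == "done"
        with pytest.raises(ConfigurationError):
            bk.advance(done, constant_rr_segment(total, 1.0), 1.0)

    def test_out_of_order_timestamps_rejected(self):
        state = bk.start_session(bk.build_lesson(1))
        state = bk.advance(state, constant_rr_segment(0.0, 30.0), 30.0)
        with pytest.raises(ConfigurationError):
            bk.advance(state, constant_rr_segment(10.0, 5.0), 5.0)

    def test_beats_assigned_to_stage_windows(self):
        lesson = bk.build_lesson(2)
        state = bk.start_session(lesson)
        total = (
            lesson.baseline_duration_s
            + lesson.stress_duration_s
            + lesson.recovery_duration_s
        )
        # feed everything in one go: beats must still land per stage window
        state = bk.advance(state, constant_rr_segment(0.0, total), total)
        for stage, (lo, hi) in (
            ("baseline", (0.0, lesson.baseline_duration_s)),
            (
                "stress",
                (
                    lesson.baseline_duration_s,
                    lesson.baseline_duration_s + lesson.stress_duration_s,
                ),
            ),
        ):
            seg = state.segment(stage)
            assert seg is not None
            assert seg.beat_times_s[0] >= lo and seg.beat_times_s[-1] < hi


class TestReview:
    @staticmethod
    def completed_state(baseline_gain=0.0, recovery_gain=80.0):
        lesson = bk.build_lesson(1)
        state = bk.start_session(lesson)
        b, s, r = (
            lesson.baseline_duration_s,
            lesson.stress_duration_s,
            lesson.recovery_duration_s,
        )
        state = bk.advance(state, rsa_rr_segment(0.0, b, baseline_gain), b)
        state = bk.advance(state, constant_rr_segment(b, s, rr_ms=750.0), s)
        state = bk.advance(state, rsa_rr_segment(b + s, r, recovery_gain), r)
        return state

    def test_recovery_sdnn_exceeds_baseline(self):
        review = bk.review(self.completed_state())
        base = review.per_stage["baseline"].sdnn_ms
        rec = review.per_stage["recovery"].sdnn_ms
        assert rec > base
        delta = review.within_lesson_deltas["recovery_minus_stress"]["sdnn_ms"]
        assert delta == pytest.approx(
            rec - review.per_stage["stress"].sdnn_ms
        )

    def test_identical_segments_zero_deltas(self):
        lesson = bk.build_lesson(1)
        state = bk.start_session(lesson)
        total = (
            lesson.baseline_duration_s
            + lesson.stress_duration_s
            + lesson.recovery_duration_s
        )
        state = bk.advance(state, constant_rr_segment(0.0, total), total)
        review = bk.review(state)
        for delta in review.within_lesson_deltas.values():
            for v in delta.values():
                assert v == pytest.approx(0.0, abs=1e-9)

    def test_metrics_reproducible_from_stored_segments(self):
        state = self.completed_state()
        review = bk.review(state)
        for stage in ("baseline", "stress", "recovery"):
            recomputed = bk.time_domain_metrics(
                bk.filter_rr(state.segment(stage))
            )
            assert review.per_stage[stage] == recomputed

    def test_between_lesson_trend_ordering(self):
        reviews = []
        for i in (1, 2, 3):
            state = self.completed_state()
            state = bk.SessionState(
                lesson=bk.build_lesson(i),
                stage=state.stage,
                elapsed_s=state.elapsed_s,
                segments=state.segments,
            )
            reviews.append(bk.review(state, history=reviews))
        trend = reviews[-1].between_lesson_trend
        assert [i for i, _ in trend] == [1, 2, 3]
        assert all(m is not None for _, m in trend)

    def test_missing_segment_reported_not_zeroed(self):
        lesson = bk.build_lesson(1)
        state = bk.start_session(lesson)
        total = (
            lesson.baseline_duration_s
            + lesson.stress_duration_s
            + lesson.recovery_duration_s
        )
        # beats only during recovery: baseline and stress segments are empty
        b, s = lesson.baseline_duration_s, lesson.stress_duration_s
        seg = constant_rr_segment(b + s, lesson.recovery_duration_s)
        state = bk.advance(state, seg, total)
        review = bk.review(state)
        assert set(review.missing_stages) == {"baseline", "stress"}
        assert review.per_stage["baseline"] is None
        assert review.within_lesson_deltas == {}

    def test_review_requires_review_stage(self):
        state = bk.start_session(bk.build_lesson(1))
        with pytest.raises(ConfigurationError):
            bk.review(state)


class TestSerialTaskItems:
    @pytest.mark.parametrize("kind", COGNITIVE_KINDS)
    def test_answers_reproducible_and_correct(self, kind):
        task = bk.StressTask(kind=kind, difficulty_level=2)
        items = bk.serial_task_items(task, seed=7)
        again = bk.serial_task_items(task, seed=7)
        assert items == again
        for item in items:
            assert item.answer in item.options
            if item.operation == "add":
                assert item.answer == sum(item.operands)
            elif item.operation == "subtract":
                assert item.answer == item.operands[0] - sum(item.operands[1:])
            else:
                start, step = item.operands
                shown = item.prompt.split()[:-1]
                assert item.answer == chr(ord("A") + start + len(shown) * step)

    def test_item_rate_scales_with_difficulty(self):
        n1 = len(bk.serial_task_items(
            bk.StressTask(kind="serial_addition", difficulty_level=1), seed=1
        ))
        n5 = len(bk.serial_task_items(
            bk.StressTask(kind="serial_addition", difficulty_level=5), seed=1
        ))
        assert n5 > n1

    def test_physical_task_rejected(self):
        with pytest.raises(ConfigurationError):
            bk.serial_task_items(bk.StressTask(kind="seated_leg_raise"), seed=0)
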
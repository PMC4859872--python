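"""Neurocardiac-training session protocol: lessons, stress tasks, review.

The training is delivered as 5 lessons.  Each lesson runs a stress
reactivity/recovery exercise: a resting baseline, one or more 1-minute
stress tasks (physical or cognitive), a guided paced-breathing recovery with
biofeedback, and a performance review comparing heart rate and time-domain
HRV within the lesson and across lessons.  Task difficulty rises with the
lesson index to counteract the training effect, and the pacer breathing rate
tapers from 10 down to 6 breaths/min as the user's skill grows.

A resting baseline stage is included even though the core exercise is
stress/recovery/review: quantifying "the effect of stress" needs a
pre-stress reference segment.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace

import numpy as np

from .biofeedback import PacerConfig
from .detect import ConfigurationError
from .hrv import HRVMetrics, MetricsUnavailable, RRSeries, filter_rr, time_domain_metrics

PHYSICAL_KINDS = ("seated_leg_raise", "fist_clench")
COGNITIVE_KINDS = ("serial_addition", "serial_subtraction", "serial_letters")
TASK_KINDS = PHYSICAL_KINDS + COGNITIVE_KINDS

STAGES = ("baseline", "stress", "recovery", "review", "done")

DEFAULT_BASELINE_S = 120.0
DEFAULT_RECOVERY_S = 300.0
DEFAULT_TASK_S = 60.0
#: Pacer breathing rate per lesson 1..5 (taper toward resonance breathing).
PACER_TAPER_BPM = (10.0, 9.0, 8.0, 7.0, 6.0)


@dataclass(frozen=True)
class StressTask:
    """One stress task: a 1-minute physical hold or cognitive item stream."""

    kind: str
    duration_s: float = DEFAULT_TASK_S
    difficulty_level: int = 1

    def __post_init__(self) -> None:
        if self.kind not in TASK_KINDS:
            raise ConfigurationError(f"unknown task kind {self.kind!r}")
        if not self.duration_s > 0:
            raise ConfigurationError("duration_s must be > 0")
        if self.difficulty_level < 1:
            raise ConfigurationError("difficulty_level must be >= 1")

    @property
    def modality(self) -> str:
        return "physical" if self.kind in PHYSICAL_KINDS else "cognitive"


@dataclass(frozen=True)
class SessionConfig:
    """Stage durations and the pacer taper for the whole program."""

    baseline_duration_s: float = DEFAULT_BASELINE_S
    recovery_duration_s: float = DEFAULT_RECOVERY_S
    task_duration_s: float = DEFAULT_TASK_S
    pacer_taper_bpm: tuple = PACER_TAPER_BPM

    def __post_init__(self) -> None:
        if len(self.pacer_taper_bpm) != 5:
            raise ConfigurationError("pacer_taper_bpm must list 5 lesson rates")


@dataclass(frozen=True)
class Lesson:
    """One of the 5 lessons: its task roster, pacer, and stage durations."""

    index: int
    tasks: tuple
    pacer: PacerConfig
    baseline_duration_s: float = DEFAULT_BASELINE_S
    recovery_duration_s: float = DEFAULT_RECOVERY_S

    def __post_init__(self) -> None:
        if not 1 <= self.index <= 5:
            raise ConfigurationError(f"lesson index must be 1..5, got {self.index}")
        if not self.tasks:
            raise ConfigurationError("lesson needs at least one task")

    @property
    def stress_duration_s(self) -> float:
        return float(sum(t.duration_s for t in self.tasks))


def build_lesson(index: int, config: SessionConfig | None = None) -> Lesson:
    """Deterministic lesson roster for a given lesson index (1..5).

    Every lesson pairs one physical and one cognitive task, rotating through
    the kinds so all five appear across the program; cognitive difficulty
    equals the lesson index and the pacer follows the configured taper.
    """
    config = config or SessionConfig()
    if not isinstance(index, int) or not 1 <= index <= 5:
        raise ConfigurationError(f"lesson index must be an integer in 1..5, got {index}")
    physical = StressTask(
        kind=PHYSICAL_KINDS[(index - 1) % len(PHYSICAL_KINDS)],
        duration_s=config.task_duration_s,
        difficulty_level=index,
    )
    cognitive = StressTask(
        kind=COGNITIVE_KINDS[(index - 1) % len(COGNITIVE_KINDS)],
        duration_s=config.task_duration_s,
        difficulty_level=index,
    )
    return Lesson(
        index=index,
        tasks=(physical, cognitive),
        pacer=PacerConfig(breaths_per_min=config.pacer_taper_bpm[index - 1]),
        baseline_duration_s=config.baseline_duration_s,
        recovery_duration_s=config.recovery_duration_s,
    )


@dataclass(frozen=True)
class SessionState:
    """Immutable protocol state; :func:`advance` returns the successor.

    Stages run strictly baseline -> stress -> recovery -> review -> done.
    Beat times accumulate into the active stage's segment; overshoot past a
    stage boundary is credited to the next stage.
    """

    lesson: Lesson
    stage: str = "baseline"
    elapsed_s: float = 0.0
    segments: dict = field(default_factory=dict)

    @property
    def stage_elapsed_s(self) -> float:
        lo, _ = self._stage_window(self.stage)
        return self.elapsed_s - lo

    def _stage_window(self, stage: str) -> tuple[float, float]:
        b = self.lesson.baseline_duration_s
        s = self.lesson.stress_duration_s
        r = self.lesson.recovery_duration_s
        windows = {
            "baseline": (0.0, b),
            "stress": (b, b + s),
            "recovery": (b + s, b + s + r),
            "review": (b + s + r, float("inf")),
            "done": (b + s + r, float("inf")),
        }
        return windows[stage]

    def segment(self, stage: str) -> RRSeries | None:
        times = self.segments.get(stage)
        if times is None or len(times) < 2:
            return None
        return RRSeries.from_beat_times(np.asarray(times))


def start_session(lesson: Lesson) -> SessionState:
    return SessionState(lesson=lesson)


def advance(state: SessionState, rr_segment: RRSeries, dt_s: float) -> SessionState:
    """Feed ``dt_s`` seconds of session time plus the beats observed in it.

    Beat timestamps are session-absolute and must be contiguous with what
    was fed before (out-of-order timestamps are an error).  The stage
    transitions exactly when its duration is reached — the stress stage ends
    at exactly the summed task duration (1 minute per task) — and any
    overshoot is credited to the next stage.
    """
    if state.stage in ("review", "done"):
        raise ConfigurationError(f"cannot advance a session in stage {state.stage!r}")
    if not dt_s > 0:
        raise ConfigurationError("dt_s must be > 0")
    times = rr_segment.beat_times_s
    last_seen = max(
        (ts[-1] for ts in state.segments.values() if ts), default=-float("inf")
    )
    if times.size and times[0] <= last_seen:
        raise ConfigurationError(
            f"rr_segment starts at {times[0]:g} s, before the last seen beat "
            f"at {last_seen:g} s"
        )
    if times.size and times[-1] > state.elapsed_s + dt_s + 1e-9:
        raise ConfigurationError("rr_segment extends beyond the advanced time")
    segments = {k: list(v) for k, v in state.segments.items()}
    # Assign each beat to the stage whose window contains its timestamp.
    for t in times:
        for stage in ("baseline", "stress", "recovery"):
            lo, hi = state._stage_window(stage)
            if lo <= t < hi:
                segments.setdefault(stage, []).append(float(t))
                break
    new_elapsed = state.elapsed_s + dt_s
    stage = state.stage
    while stage not in ("review", "done"):
        _, hi = state._stage_window(stage)
        if new_elapsed >= hi - 1e-9:
            stage = STAGES[STAGES.index(stage) + 1]
        else:
            break
    return replace(state, elapsed_s=new_elapsed, segments=segments, stage=stage)


@dataclass(frozen=True)
class PerformanceReview:
    """Within- and between-lesson comparison of per-stage HRV.

    ``within_lesson_deltas`` holds exact metric differences stress-baseline
    and recovery-stress; ``between_lesson_trend`` lists each lesson's
    recovery metrics in lesson order.  Stages whose segment was too short
    for metrics appear in ``missing_stages`` rather than as silent zeros.
    """

    lesson_index: int
    per_stage: dict  # stage -> HRVMetrics | None
    within_lesson_deltas: dict
    between_lesson_trend: tuple
    missing_stages: tuple = ()


def _metric_delta(a: HRVMetrics, b: HRVMetrics) -> dict:
    return {
        "mean_hr_bpm": a.mean_hr_bpm - b.mean_hr_bpm,
        "sdnn_ms": a.sdnn_ms - b.sdnn_ms,
        "rmssd_ms": a.rmssd_ms - b.rmssd_ms,
        "pnn50_pct": a.pnn50_pct - b.pnn50_pct,
    }


def review(state: SessionState, history: list | None = None) -> PerformanceReview:
    """Compute the per-stage metrics and deltas once the session reaches
    the review stage.

    Missing or too-short segments produce a partial review with the gap
    named explicitly.  ``history`` is the list of prior lessons'
    :class:`PerformanceReview` objects, ordered by lesson index; this
    lesson's recovery metrics are appended to the between-lesson trend.
    """
    if state.stage not in ("review", "done"):
        raise ConfigurationError(
            f"review requires the review stage, session is in {state.stage!r}"
        )
    history = list(history or [])
    per_stage: dict = {}
    missing = []
    for stage in ("baseline", "stress", "recovery"):
        seg = state.segment(stage)
        if seg is None:
            per_stage[stage] = None
            missing.append(stage)
            continue
        try:
            per_stage[stage] = time_domain_metrics(filter_rr(seg))
        except MetricsUnavailable:
            per_stage[stage] = None
            missing.append(stage)
    deltas: dict = {}
    if per_stage["stress"] is not None and per_stage["baseline"] is not None:
        deltas["stress_minus_baseline"] = _metric_delta(
            per_stage["stress"], per_stage["baseline"]
        )
    if per_stage["recovery"] is not None and per_stage["stress"] is not None:
        deltas["recovery_minus_stress"] = _metric_delta(
            per_stage["recovery"], per_stage["stress"]
        )
    trend = tuple(
        (r.lesson_index, r.per_stage.get("recovery")) for r in history
    ) + ((state.lesson.index, per_stage["recovery"]),)
    return PerformanceReview(
        lesson_index=state.lesson.index,
        per_stage=per_stage,
        within_lesson_deltas=deltas,
        between_lesson_trend=trend,
        missing_stages=tuple(missing),
    )


def finish(state: SessionState) -> SessionState:
    """Terminal transition review -> done."""
    if state.stage != "review":
        raise ConfigurationError(
            f"can only finish from the review stage, session is in {state.stage!r}"
        )
    return replace(state, stage="done")


# ---------------------------------------------------------------------------
# Cognitive task item generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TaskItem:
    """One multiple-choice item with its ground-truth answer.

    For arithmetic kinds ``operands``/``operation`` allow re-evaluating the
    expression; for letter patterns ``operands`` holds (start_ordinal, step).
    """

    prompt: str
    options: tuple
    answer: object
    operation: str
    operands: tuple


def _arithmetic_item(rng: np.random.Generator, kind: str, difficulty: int) -> TaskItem:
    n_ops = 2 + difficulty  # chain length grows with difficulty
    hi = 10 * difficulty
    operands = tuple(int(v) for v in rng.integers(1, hi + 1, size=n_ops))
    if kind == "serial_addition":
        answer = sum(operands)
        op, sym = "add", " + "
        prompt = sym.join(map(str, operands)) + " = ?"
    else:
        answer = operands[0] - sum(operands[1:])
        op, sym = "subtract", " - "
        prompt = sym.join(map(str, operands)) + " = ?"
    offsets = rng.choice(np.arange(1, 10), size=3, replace=False)
    signs = rng.choice([-1, 1], size=3)
    options = [answer] + [int(answer + s * o) for s, o in zip(signs, offsets)]
    order = rng.permutation(4)
    return TaskItem(
        prompt=prompt,
        options=tuple(options[i] for i in order),
        answer=answer,
        operation=op,
        operands=operands,
    )


def _letters_item(rng: np.random.Generator, difficulty: int) -> TaskItem:
    length = 3 + difficulty  # shown sequence length
    max_step = max(1, (26 - 1) // length)  # keep the answer inside A..Z
    step = int(rng.integers(1, min(2 + difficulty, max_step + 1)))
    start = int(rng.integers(0, 26 - step * length))
    seq = [string.ascii_uppercase[start + k * step] for k in range(length)]
    answer = string.ascii_uppercase[start + length * step]
    wrong = [c for c in string.ascii_uppercase if c != answer]
    distractors = rng.choice(len(wrong), size=3, replace=False)
    options = [answer] + [wrong[i] for i in distractors]
    order = rng.permutation(4)
    return TaskItem(
        prompt=" ".join(seq) + " ?",
        options=tuple(options[i] for i in order),
        answer=answer,
        operation="letter_pattern",
        operands=(start, step),
    )


def serial_task_items(task: StressTask, seed: int) -> list[TaskItem]:
    """Generate the seeded item stream for one cognitive stress task.

    The presentation rate scales with difficulty (6 items/min at level 1,
    +4 per level), so harder lessons demand faster answers; operand
    magnitude and chain/pattern length also grow with the level.
    """
    if task.modality != "cognitive":
        raise ConfigurationError(
            f"serial_task_items applies to cognitive tasks only, got {task.kind!r}"
        )
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, task.difficulty_level, TASK_KINDS.index(task.kind)])
    )
    per_min = 6 + 4 * (task.difficulty_level - 1)
    n = max(1, int(round(per_min * task.duration_s / 60.0)))
    items = []
    for _ in range(n):
        if task.kind == "serial_letters":
            items.append(_letters_item(rng, task.difficulty_level))
        else:
            items.append(_arithmetic_item(rng, task.kind, task.difficulty_level))
    return items
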
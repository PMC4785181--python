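"""Visual water task: trial scheduling and adaptive threshold assessment.

One "trial" is one swim toward one of two monitors; the positive stimulus
(S+) marks the platform side.  Side order is pseudorandom with no more than
three consecutive trials on one side.  After an error the animal repeats the
trial at the same level and side until correct; these correction trials are
logged but excluded from criterion evaluation and accuracy pooling.

Threshold assessment descends from the easiest stimulus in fixed steps
(contrast -10%, or SF +0.03 cpd).  At each level a criterion test is run:
pass on four consecutive correct choices or seven correct within a block of
ten consecutive trials, fail otherwise at block completion.  A failure while
descending marks a preliminary threshold; the level then backs off toward
easier stimuli until the criterion is passed again, and the descent repeats.
The assessment stops when two successive preliminary thresholds agree within
one step ("stable pattern of performance"); the final threshold is read from
the frequency-of-seeing curve pooled over all non-correction trials.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

from . import psychometrics
from .constants import (
    ACCURACY_CRITERION,
    BLOCK_SIZE,
    CONTRAST_START,
    CONTRAST_STEP,
    CRITERION_HITS,
    CRITERION_STREAK,
    SESSIONS_PER_DAY,
    SF_MAX,
    SF_START,
    SF_STEP,
    TRIALS_PER_SESSION,
)

if TYPE_CHECKING:  # avoid a runtime import cycle with the observer module
    from .observer import ObserverState

__all__ = [
    "Trial",
    "AssessmentConfig",
    "CriterionOutcome",
    "next_side",
    "criterion_test",
    "run_assessment",
    "trials_to_frame",
    "trials_to_csv",
    "trials_from_csv",
]

SIDES = ("left", "right")

PATTERN_TASKS = frozenset({"V_vs_H", "gaussian"})
DETECTION_TASKS = frozenset({"V_vs_G", "H_vs_G"})


def task_class(task: str) -> str:
    """Classify a task as pattern discrimination or visual detection."""
    if task in PATTERN_TASKS:
        return "pattern"
    if task in DETECTION_TASKS:
        return "detection"
    raise ValueError(f"unknown task {task!r}; known: "
                     f"{sorted(PATTERN_TASKS | DETECTION_TASKS)}")


@dataclass(frozen=True)
class Trial:
    """One swim: stimulus, platform side, choice and bookkeeping indices."""

    day: int
    session: int
    index: int                  # 0-based position in the full log
    task: str                   # V_vs_H | gaussian | V_vs_G | H_vs_G
    domain: str                 # "contrast" | "sf"
    level: float                # Michelson contrast in (0,1] or SF in cpd
    s_plus_side: str            # "left" | "right"
    choice: str
    correct: bool
    is_correction: bool
    animal_id: int = -1


def next_side(history: Sequence[str], rng: np.random.Generator) -> str:
    """Next platform side: fair coin, but never four in a row on one side.

    ``history`` is the ordered list of previous scheduled (non-correction)
    sides; correction trials reuse the previous side and do not count.
    """
    if len(history) >= 3 and history[-1] == history[-2] == history[-3]:
        forced = "right" if history[-1] == "left" else "left"
        return forced
    return SIDES[int(rng.integers(2))]


@dataclass(frozen=True)
class CriterionOutcome:
    status: str                 # "pass" | "fail" | "continue"
    trials: int                 # trials consumed by the decision


def criterion_test(outcomes: Sequence[bool],
                   streak: int = CRITERION_STREAK,
                   hits: int = CRITERION_HITS,
                   block_size: int = BLOCK_SIZE) -> CriterionOutcome:
    """Evaluate the sequential criterion test on ordered correctness flags.

    Pass as soon as ``streak`` consecutive correct choices occur or ``hits``
    correct choices accumulate; fail only at block completion; otherwise the
    block continues.
    """
    if len(outcomes) > block_size:
        raise ValueError(f"at most {block_size} outcomes per block")
    run = 0
    total = 0
    for i, ok in enumerate(outcomes):
        if ok:
            run += 1
            total += 1
        else:
            run = 0
        if run >= streak or total >= hits:
            return CriterionOutcome("pass", i + 1)
    if len(outcomes) == block_size:
        return CriterionOutcome("fail", block_size)
    return CriterionOutcome("continue", len(outcomes))


@dataclass(frozen=True)
class AssessmentConfig:
    """Parameters of the adaptive threshold assessment."""

    domain: str
    start_level: float
    step: float
    level_min: float
    level_max: float
    accuracy_criterion: float = ACCURACY_CRITERION
    block_size: int = BLOCK_SIZE
    criterion_streak: int = CRITERION_STREAK
    criterion_hits: int = CRITERION_HITS
    stability_tolerance_steps: int = 1
    stability_min_prelims: int = 4
    max_blocks: int = 200
    trials_per_session: int = TRIALS_PER_SESSION
    sessions_per_day: int = SESSIONS_PER_DAY
    max_easy_failures: int = 3
    include_corrections: bool = False

    def __post_init__(self):
        if not 0 < self.accuracy_criterion < 1:
            raise ValueError("accuracy criterion must be in (0, 1)")
        if self.step <= 0:
            raise ValueError("step must be positive")

    @classmethod
    def for_domain(cls, domain: str, **overrides) -> "AssessmentConfig":
        if domain == "contrast":
            base = cls(domain="contrast", start_level=CONTRAST_START,
                       step=CONTRAST_STEP, level_min=CONTRAST_STEP,
                       level_max=CONTRAST_START)
        elif domain == "sf":
            base = cls(domain="sf", start_level=SF_START, step=SF_STEP,
                       level_min=SF_START, level_max=SF_MAX)
        else:
            raise ValueError("domain must be 'contrast' or 'sf'")
        return replace(base, **overrides) if overrides else base

    def level(self, k: int) -> float:
        """Stimulus level at difficulty index k (k=0 is the easiest)."""
        if self.domain == "contrast":
            return round(self.start_level - k * self.step, 10)
        return round(self.start_level + k * self.step, 10)

    @property
    def k_max(self) -> int:
        if self.domain == "contrast":
            return int(round((self.start_level - self.level_min) / self.step))
        return int(round((self.level_max - self.start_level) / self.step))


class _TrialRecorder:
    """Builds the trial log with day/session bookkeeping."""

    def __init__(self, config: AssessmentConfig, task: str, animal_id: int,
                 day0: int = 1):
        self.config = config
        self.task = task
        self.animal_id = animal_id
        self.day0 = day0
        self.trials: list[Trial] = []
        self.side_history: list[str] = []
        self.n_scored = 0

    def _clock(self) -> tuple[int, int]:
        per_day = self.config.trials_per_session * self.config.sessions_per_day
        day = self.day0 + self.n_scored // per_day
        session = (self.n_scored // self.config.trials_per_session) \
            % self.config.sessions_per_day + 1
        return day, session

    def record(self, level: float, side: str, correct: bool,
               is_correction: bool) -> Trial:
        day, session = self._clock()
        t = Trial(day=day, session=session, index=len(self.trials),
                  task=self.task, domain=self.config.domain, level=level,
                  s_plus_side=side, choice=side if correct else
                  ("right" if side == "left" else "left"),
                  correct=correct, is_correction=is_correction,
                  animal_id=self.animal_id)
        self.trials.append(t)
        if not is_correction:
            self.side_history.append(side)
            self.n_scored += 1
        return t


def _run_block(p: float, level: float, rec: _TrialRecorder,
               rng: np.random.Generator, block_size: int | None = None,
               streak: int = CRITERION_STREAK,
               hits: int = CRITERION_HITS) -> CriterionOutcome:
    """Simulate one criterion block at a fixed level, with early stopping.

    After each scored error the forced correction trials (same level, same
    side, repeated until correct) are simulated and logged.
    """
    cfg = rec.config
    block_size = cfg.block_size if block_size is None else block_size
    outcomes: list[bool] = []
    for _ in range(block_size):
        side = next_side(rec.side_history, rng)
        correct = bool(rng.random() < p)
        rec.record(level, side, correct, is_correction=False)
        outcomes.append(correct)
        if not correct:
            for _ in range(10_000):  # p >= 0.5, terminates almost surely
                corr_ok = bool(rng.random() < p)
                rec.record(level, side, corr_ok, is_correction=True)
                if corr_ok:
                    break
        out = criterion_test(outcomes, streak=streak, hits=hits,
                             block_size=block_size)
        if out.status == "pass":
            return out
    return criterion_test(outcomes, streak=streak, hits=hits,
                          block_size=block_size)


def run_assessment(observer: "ObserverState", config: AssessmentConfig,
                   rng: np.random.Generator, eye: str = "both",
                   task: str = "V_vs_H", day0: int = 1,
                   ) -> tuple[list[Trial], psychometrics.ThresholdEstimate]:
    """Run the adaptive assessment on a simulated observer.

    Returns the full trial log (corrections flagged) and the threshold
    estimate read from the pooled frequency-of-seeing curve.  An observer
    that cannot reach criterion at the easiest stimulus yields an estimate
    flagged ``defined=False`` rather than an exception.
    """
    rec = _TrialRecorder(config, task, observer.animal_id, day0)
    k = 0
    direction = +1              # +1 toward harder stimuli, -1 toward easier
    prelims: list[int] = []
    easy_failures = 0
    ever_passed = False
    aborted_reason = None
    for _ in range(config.max_blocks):
        out = _run_block(
            observer.prob_correct(config.level(k), config.domain, eye, task),
            config.level(k), rec, rng,
            streak=config.criterion_streak, hits=config.criterion_hits)
        if out.status == "pass":
            ever_passed = True
            direction = +1
            if k < config.k_max:
                k += 1
        else:
            if k == 0:
                easy_failures += 1
                if not ever_passed and easy_failures >= config.max_easy_failures:
                    aborted_reason = "criterion not met at easiest stimulus"
                    break
            if direction == +1:
                prelims.append(k)
                # "repeated several times until a stable pattern": stop once
                # enough preliminary thresholds exist and the last two agree
                if (len(prelims) >= config.stability_min_prelims and
                        abs(prelims[-1] - prelims[-2])
                        <= config.stability_tolerance_steps):
                    break
            direction = -1
            if k > 0:
                k -= 1
    fos = psychometrics.build_fos(
        rec.trials, include_corrections=config.include_corrections,
        domain=config.domain)
    est = psychometrics.threshold_at_criterion(
        fos, criterion=config.accuracy_criterion)
    # an observer that cannot reach criterion at the easiest stimulus has no
    # threshold, whatever noisy crossings the rest of the curve shows
    easiest = int(np.argmax(fos.levels)) if config.domain == "contrast" \
        else int(np.argmin(fos.levels))
    if (est.defined and fos.n_trials[easiest] >= config.block_size
            and fos.accuracy[easiest] < config.accuracy_criterion):
        aborted_reason = "criterion not met at easiest stimulus"
    if aborted_reason and est.defined:
        # spurious crossing from very few trials; keep the flag honest
        est = replace(est, defined=False, threshold=float("nan"),
                      reason=aborted_reason)
    return rec.trials, est


# ---------------------------------------------------------------------------
# trial-log I/O

_CSV_COLUMNS = ["animal_id", "day", "session", "trial", "task", "domain",
                "level", "s_plus_side", "choice", "correct", "is_correction"]


def trials_to_frame(trials: Iterable[Trial]) -> pd.DataFrame:
    rows = [(t.animal_id, t.day, t.session, t.index, t.task, t.domain,
             t.level, t.s_plus_side, t.choice, t.correct, t.is_correction)
            for t in trials]
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def trials_to_csv(trials: Iterable[Trial], path) -> None:
    trials_to_frame(trials).to_csv(path, index=False)


def trials_from_csv(path) -> list[Trial]:
    df = pd.read_csv(path)
    return [
        Trial(day=int(r.day), session=int(r.session), index=int(r.trial),
              task=str(r.task), domain=str(r.domain), level=float(r.level),
              s_plus_side=str(r.s_plus_side), choice=str(r.choice),
              correct=bool(r.correct), is_correction=bool(r.is_correction),
              animal_id=int(r.animal_id))
        for r in df.itertuples()
    ]
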
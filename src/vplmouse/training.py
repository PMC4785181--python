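"""Near-threshold perceptual training (NCT / NSFT) and control conditions.

Training runs for 35 consecutive days, two 10-trial sessions per day by
default.  In the near-threshold modes the stimulus level tracks the animal's
current 70% point with the same criterion blocks and step sizes as the
assessment: a failed block eases the stimulus by one step, a passed block
hardens it by one step.  Control animals swim the same schedule at a fixed
easy stimulus (100% contrast or 0.12 cpd) and accrue essentially no
effective learning dose.

The daily trajectory value (CS or VA) is re-estimated from that day's own
trials; the post-training value is the arithmetic mean of the final four
daily values.  Control modes contain no criterion crossing in their daily
logs, so their pre/post values come from standard assessments run before
and after the training block, as in the study design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import psychometrics
from .observer import ObserverState, update_learning
from .task import AssessmentConfig, Trial, _run_block, _TrialRecorder, \
    run_assessment

__all__ = [
    "TrainingConfig",
    "LearningTrajectory",
    "run_training",
    "post_value",
    "simulate_retention",
    "trajectory_to_frame",
]

MODES = ("nct", "nsft", "control_contrast", "control_sf")


@dataclass(frozen=True)
class TrainingConfig:
    """Protocol parameters of one training regimen."""

    mode: str = "nsft"
    days: int = 35
    sessions_per_day: int = 2
    task: str = "V_vs_H"
    eye: str = "both"
    trained_sf: float = 0.33        # SF of the gratings during NCT
    assessment: AssessmentConfig | None = None

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.days < 1:
            raise ValueError("days must be >= 1")
        if self.sessions_per_day not in (2, 4):
            raise ValueError("sessions_per_day must be 2 or 4")

    @property
    def domain(self) -> str:
        return "contrast" if self.mode in ("nct", "control_contrast") else "sf"

    @property
    def is_control(self) -> bool:
        return self.mode.startswith("control")

    def assessment_config(self) -> AssessmentConfig:
        if self.assessment is not None:
            return self.assessment
        return AssessmentConfig.for_domain(
            self.domain, sessions_per_day=self.sessions_per_day)


@dataclass
class LearningTrajectory:
    """Per-day assessed values across training, in reporting units.

    Contrast-domain values are contrast sensitivities (1/threshold), SF
    values are acuities in cpd.  ``daily_values`` holds NaN for control
    days, whose logs contain no criterion crossing.
    """

    mode: str
    domain: str
    daily_values: list[float]
    daily_levels: list[list[float]]
    pre: float
    post: float
    animal_id: int = -1


def _report(threshold: float, domain: str) -> float:
    return psychometrics.contrast_sensitivity(threshold) \
        if domain == "contrast" else threshold


def _nearest_k(alpha: float, cfg: AssessmentConfig) -> int:
    if cfg.domain == "contrast":
        k = round((cfg.start_level - alpha) / cfg.step)
    else:
        k = round((alpha - cfg.start_level) / cfg.step)
    return int(min(max(k, 0), cfg.k_max))


def _daily_value(day_trials: list[Trial], cfg: AssessmentConfig) -> float:
    """Threshold read from one day's trials, with a bounded fallback.

    If the day's frequency-of-seeing curve has no 70% crossing (all levels
    above or all below criterion), the hardest / easiest level visited that
    day bounds the threshold and is reported in its place.
    """
    fos = psychometrics.build_fos(day_trials, domain=cfg.domain)
    est = psychometrics.threshold_at_criterion(fos, cfg.accuracy_criterion)
    if est.defined:
        return _report(est.threshold, cfg.domain)
    levels = fos.levels
    if est.reason == "floor not reached":
        bound = levels.min() if cfg.domain == "contrast" else levels.max()
    else:
        bound = levels.max() if cfg.domain == "contrast" else levels.min()
    return _report(float(bound), cfg.domain)


def run_training(observer: ObserverState, config: TrainingConfig,
                 rng: np.random.Generator, pre: float | None = None
                 ) -> LearningTrajectory:
    """Simulate one animal through a full training regimen.

    ``pre`` is the pre-training assessed value (CS or VA); when omitted a
    standard pre-training assessment is simulated.  The observer's learning
    state is updated in place after every session.
    """
    cfg = config.assessment_config()
    domain = config.domain
    if domain == "contrast":
        observer.reference_sf = config.trained_sf
    observer.begin_training(config.eye, config.task, domain)
    if pre is None:
        _, est = run_assessment(observer, cfg, rng, eye=config.eye,
                                task=config.task)
        if not est.defined:
            raise ValueError("pre-training threshold undefined for this "
                             "observer; cannot anchor training")
        pre = _report(est.threshold, domain)

    daily_values: list[float] = []
    daily_levels: list[list[float]] = []
    if config.is_control:
        k = 0                     # fixed easy stimulus throughout
    else:
        k = _nearest_k(observer.current_alpha(config.eye, config.task, domain),
                       cfg)
    for day in range(1, config.days + 1):
        day_trials: list[Trial] = []
        rec = _TrialRecorder(cfg, config.task, observer.animal_id, day0=day)
        for _ in range(config.sessions_per_day):
            session_start = rec.n_scored
            while rec.n_scored - session_start < cfg.trials_per_session:
                remaining = cfg.trials_per_session - (rec.n_scored
                                                      - session_start)
                block_size = min(cfg.block_size, remaining)
                p = observer.prob_correct(cfg.level(k), domain,
                                          config.eye, config.task)
                out = _run_block(p, cfg.level(k), rec, rng,
                                 block_size=block_size,
                                 streak=cfg.criterion_streak,
                                 hits=cfg.criterion_hits)
                if not config.is_control:
                    if out.status == "pass" and k < cfg.k_max:
                        k += 1
                    elif out.status == "fail" and k > 0:
                        k -= 1
                    # truncated, undecided blocks leave the level unchanged
            session_trials = rec.trials[len(day_trials):]
            update_learning(observer, session_trials)
            day_trials = list(rec.trials)
        daily_levels.append(sorted({t.level for t in day_trials}))
        if config.is_control:
            daily_values.append(math.nan)
        else:
            daily_values.append(_daily_value(day_trials, cfg))

    if config.is_control:
        _, est = run_assessment(observer, cfg, rng, eye=config.eye,
                                task=config.task)
        post = _report(est.threshold, domain) if est.defined else math.nan
    else:
        post = float(np.mean(daily_values[-4:])) if config.days >= 4 \
            else float(np.mean(daily_values))
    return LearningTrajectory(mode=config.mode, domain=domain,
                              daily_values=daily_values,
                              daily_levels=daily_levels, pre=float(pre),
                              post=post, animal_id=observer.animal_id)


def post_value(trajectory: LearningTrajectory) -> float:
    """Post-training value: arithmetic mean of the final four daily values."""
    vals = trajectory.daily_values
    if len(vals) < 4:
        raise ValueError("need at least 4 daily values")
    return float(np.mean(vals[-4:]))


def simulate_retention(observer: ObserverState, days: float,
                       half_life_days: float = 65.0) -> ObserverState:
    """Decay the learned improvement over a post-training retention gap.

    The fractional progress toward the asymptote decays with the given
    half-life (default 65 days, consistent with the 74%/63% retention seen
    at 28/45 days), implemented as an equivalent reduction of the effective
    dose.
    """
    if days < 0:
        raise ValueError("retention gap must be non-negative")
    if observer.trained_pathway is None:
        return observer
    u = observer.progress() * 0.5 ** (days / half_life_days)
    eye, _, domain = observer.trained_pathway
    tau = observer.profile.pathway(
        eye if eye in ("left", "right") else "left", domain).tau
    observer.dose = -tau * math.log1p(-min(u, 1 - 1e-12))
    return observer


def trajectory_to_frame(trajectories) -> pd.DataFrame:
    """Tidy per-animal per-day table (animal_id, day, assessed_value)."""
    rows = []
    for tr in trajectories if isinstance(trajectories, list) else [trajectories]:
        for day, val in enumerate(tr.daily_values, start=1):
            rows.append({"animal_id": tr.animal_id, "day": day,
                         "assessed_value": val})
    return pd.DataFrame(rows)
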
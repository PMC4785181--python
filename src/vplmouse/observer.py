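"""Synthetic mouse observers for the visual water task.

Each observer is a 2AFC decision maker with a logistic psychometric function
on the log10 stimulus axis, parameterised directly by its 70%-correct
threshold, plus a saturating learning rule driven by near-threshold practice.

Psychometric function.  With guess rate g = 0.5 and lapse rate lam,

    p(level) = g + (1 - g - lam) * logistic(beta * (z - z_alpha) + b0)

where z is log10(level) oriented so that easier stimuli give larger z
(higher contrast, lower SF) and the offset b0 is chosen so that
p(alpha) = 0.70 exactly; printed group thresholds therefore map one-to-one
onto alpha.

Learning rule.  Practice trials whose level lies within a proximity
bandwidth of the current threshold (on the log10 axis) increment an
effective dose d; the trained threshold relaxes exponentially from its
starting value toward its asymptote, alpha(d) = asym + (start - asym) *
exp(-d / tau).  Easy-stimulus control training (100% contrast, 0.12 cpd)
falls outside the bandwidth and confers ~zero dose, reproducing the
ineffectiveness of the control conditions.  Transfer to the untrained eye,
task or domain is a fixed fraction of the trained pathway's fractional
progress along its own start->asymptote span, which keeps every threshold
inside its physical range and makes the simulated transfer index track the
configured fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from types import MappingProxyType
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from .constants import ACCURACY_CRITERION, DEFAULT_LAPSE, GUESS_RATE
from .psychometrics import log_parabola_csf, solve_log_parabola
from .task import Trial, task_class

__all__ = [
    "PsychometricParams",
    "LearningParams",
    "ObserverProfile",
    "ObserverState",
    "p_correct",
    "simulate_choice",
    "update_learning",
    "make_profile",
    "make_cohort",
    "cohort_to_frame",
    "cohort_to_csv",
    "cohort_from_config",
    "PROFILE_NAMES",
]

EYES = ("left", "right")

# Asymmetric task transfer: pattern-discrimination practice drives a
# component usable by detection (TI = 0.90) but detection practice barely
# helps pattern discrimination (TI = 0.07).
DEFAULT_TASK_TRANSFER: Mapping[tuple[str, str], float] = MappingProxyType({
    ("pattern", "detection"): 0.90,
    ("detection", "pattern"): 0.07,
})

DEFAULT_INTEROCULAR_TRANSFER = 0.63
DEFAULT_CROSS_DOMAIN_TRANSFER = 1.0
DEFAULT_TAU = 200.0             # near-threshold trials
DEFAULT_BANDWIDTH = 0.3         # log10 units
# Slopes per log10 stimulus: the rise from chance to lapse-limited accuracy
# spans roughly two assessment steps in each domain, consistent with the
# sharp accuracy fall-off of published water-task frequency-of-seeing curves.
DEFAULT_BETA = {"contrast": 12.0, "sf": 36.0}


def _check_domain_level(domain: str, level) -> np.ndarray:
    level = np.asarray(level, dtype=float)
    if np.any(level <= 0):
        raise ValueError("stimulus level must be positive")
    if domain == "contrast" and np.any(level > 1):
        raise ValueError("Michelson contrast cannot exceed 1")
    return level


@dataclass(frozen=True)
class PsychometricParams:
    """Logistic 2AFC psychometric function anchored at the 70% point."""

    alpha: float                # threshold (contrast in (0,1] or SF in cpd)
    beta: float                 # slope per log10 stimulus unit
    domain: str                 # "contrast" | "sf"
    guess_rate: float = GUESS_RATE
    lapse_rate: float = DEFAULT_LAPSE

    def __post_init__(self):
        if self.guess_rate != GUESS_RATE:
            raise ValueError("2AFC guess rate is fixed at 0.5")
        if not 0 <= self.lapse_rate <= 0.1:
            raise ValueError("lapse rate must lie in [0, 0.1]")
        if self.beta <= 0:
            raise ValueError("slope must be positive")
        if self.domain not in ("contrast", "sf"):
            raise ValueError("domain must be 'contrast' or 'sf'")
        _check_domain_level(self.domain, self.alpha)


def p_correct(params: PsychometricParams, level):
    """Probability of a correct choice at a stimulus level (vectorised).

    Rises with contrast and falls with spatial frequency; equals the guess
    rate for vanishing contrast, 1 - lapse for very easy stimuli, and the
    70% criterion exactly at ``params.alpha``.
    """
    level = _check_domain_level(params.domain, level)
    sign = 1.0 if params.domain == "contrast" else -1.0
    z = sign * np.log10(level)
    z_alpha = sign * math.log10(params.alpha)
    span = 1.0 - params.guess_rate - params.lapse_rate
    b0 = logit((ACCURACY_CRITERION - params.guess_rate) / span)
    p = params.guess_rate + span * expit(params.beta * (z - z_alpha) + b0)
    return float(p) if np.isscalar(level) or p.ndim == 0 else p


@dataclass(frozen=True)
class LearningParams:
    """Learning dynamics of one (eye, domain) pathway."""

    alpha_start: float
    alpha_asymptote: float
    tau: float = DEFAULT_TAU
    proximity_bandwidth: float = DEFAULT_BANDWIDTH
    interocular_transfer_fraction: float = DEFAULT_INTEROCULAR_TRANSFER
    task_transfer_matrix: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: DEFAULT_TASK_TRANSFER)
    cross_domain_fraction: float = DEFAULT_CROSS_DOMAIN_TRANSFER

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not 0 <= self.interocular_transfer_fraction <= 1:
            raise ValueError("interocular transfer fraction must be in [0,1]")
        if any(not 0 <= f <= 1 for f in self.task_transfer_matrix.values()):
            raise ValueError("task transfer fractions must be in [0,1]")
        if not 0 <= self.cross_domain_fraction <= 1:
            raise ValueError("cross-domain fraction must be in [0,1]")


@dataclass(frozen=True)
class ObserverProfile:
    """Named, immutable preset describing a group of animals.

    ``learning`` maps (eye, domain) to the pathway's learning parameters;
    thresholds are group means and ``alpha_sd_log10`` the between-animal
    spread of log10 alpha.  Contrast-domain thresholds are calibrated at
    ``reference_sf`` (0.33 cpd); ``contrast_alpha_at`` interpolates them to
    other SFs along a log-parabola CSF.
    """

    name: str
    learning: Mapping[tuple[str, str], LearningParams]
    beta: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BETA))
    lapse_rate: float = DEFAULT_LAPSE
    alpha_sd_log10: float = 0.04
    reference_sf: float = 0.33
    csf_width: float = 1.5

    def pathway(self, eye: str, domain: str) -> LearningParams:
        return self.learning[(eye, domain)]

    def contrast_alpha_at(self, sf: float, eye: str = "left",
                          asymptote: bool = False) -> float:
        """Contrast threshold at an arbitrary SF via the log-parabola CSF.

        The curve is anchored at the profile's reference-SF threshold and at
        the naive 0.21-cpd group CS scaled by the same factor.
        """
        lp = self.pathway(eye, "contrast")
        a = lp.alpha_asymptote if asymptote else lp.alpha_start
        cs_ref = 1.0 / a
        # naive anchors: CS 3.75 at 0.33 cpd and 4.59 at 0.21 cpd; the second
        # anchor is scaled with the profile so the CSF shape is preserved.
        scale = cs_ref / 3.75
        peak_cs, peak_sf = solve_log_parabola(
            (self.reference_sf, cs_ref), (0.21, 4.59 * scale),
            width=self.csf_width)
        cs = float(log_parabola_csf(sf, peak_cs, peak_sf, self.csf_width))
        return min(1.0, 1.0 / max(cs, 1.0))


def _sym(contrast: LearningParams, sf: LearningParams
         ) -> dict[tuple[str, str], LearningParams]:
    """Both eyes share the same pathway parameters."""
    return {(eye, "contrast"): contrast for eye in EYES} | \
           {(eye, "sf"): sf for eye in EYES}


def _make_presets() -> dict[str, ObserverProfile]:
    naive_contrast = LearningParams(alpha_start=1 / 3.75,
                                    alpha_asymptote=1 / 7.05)
    naive_sf = LearningParams(alpha_start=0.47, alpha_asymptote=0.72)
    trained_contrast = LearningParams(alpha_start=1 / 7.05,
                                      alpha_asymptote=1 / 7.05)
    trained_sf = LearningParams(alpha_start=0.72, alpha_asymptote=0.72)
    presets = {
        "naive": ObserverProfile(
            "naive", _sym(naive_contrast, naive_sf), alpha_sd_log10=0.05),
        # control animals are drawn from the same population as naive ones;
        # their easy-stimulus training confers no effective dose.
        "control": ObserverProfile(
            "control", _sym(naive_contrast, naive_sf), alpha_sd_log10=0.05),
        "nct_trained": ObserverProfile(
            "nct_trained",
            _sym(trained_contrast,
                 LearningParams(alpha_start=0.73, alpha_asymptote=0.73)),
            alpha_sd_log10=0.05),
        "nsft_trained": ObserverProfile(
            "nsft_trained", _sym(trained_contrast, trained_sf),
            alpha_sd_log10=0.05),
        "amblyopic": ObserverProfile(
            "amblyopic",
            {("left", "sf"): LearningParams(alpha_start=0.28,
                                            alpha_asymptote=0.47),
             ("right", "sf"): LearningParams(alpha_start=0.46,
                                             alpha_asymptote=0.48),
             ("left", "contrast"): naive_contrast,
             ("right", "contrast"): naive_contrast},
            alpha_sd_log10=0.05),
        # uncalibrated placeholder: no baseline VA is printed for old mice;
        # slowed learning is encoded as a larger tau.
        "old": ObserverProfile(
            "old",
            _sym(naive_contrast,
                 LearningParams(alpha_start=0.38, alpha_asymptote=0.60,
                                tau=3 * DEFAULT_TAU))),
    }
    return presets


_PRESETS = _make_presets()
PROFILE_NAMES = tuple(sorted(_PRESETS))

# amblyopic preset convention: the deprived eye is "left", the fellow "right"
DEPRIVED_EYE = "left"


def make_profile(name: str, **overrides) -> ObserverProfile:
    """Return a named preset profile, optionally with field overrides."""
    try:
        profile = _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown profile {name!r}; available: {', '.join(PROFILE_NAMES)}"
        ) from None
    return replace(profile, **overrides) if overrides else profile


@dataclass
class ObserverState:
    """One simulated animal: sampled thresholds plus learning state.

    ``log10_offset`` is the animal's draw from the between-animal spread; it
    shifts the start and asymptote of every pathway together so that the
    improvement ratio stays narrow across animals, as in the printed PPRs.
    """

    profile: ObserverProfile
    animal_id: int
    log10_offset: float = 0.0
    rng: np.random.Generator = field(
        default_factory=np.random.default_rng, repr=False)
    dose: float = 0.0
    trained_pathway: tuple[str, str, str] | None = None   # (eye, task_class, domain)
    reference_sf: float | None = None   # SF at which contrast trials run

    def _span(self, eye: str, domain: str) -> tuple[float, float, LearningParams]:
        lp = self.profile.pathway(eye, domain)
        g = 10.0 ** self.log10_offset
        start, asym = lp.alpha_start * g, lp.alpha_asymptote * g
        if domain == "contrast":
            sf = self.reference_sf
            if sf is not None and not math.isclose(
                    sf, self.profile.reference_sf):
                start = min(1.0, self.profile.contrast_alpha_at(sf, eye) * g)
                asym = min(1.0, self.profile.contrast_alpha_at(
                    sf, eye, asymptote=True) * g)
            start, asym = min(start, 1.0), min(asym, 1.0)
        return start, asym, lp

    def progress(self) -> float:
        """Fractional progress of the trained pathway toward its asymptote."""
        if self.trained_pathway is None:
            return 0.0
        eye, _, domain = self.trained_pathway
        eye = eye if eye in EYES else "left"
        lp = self.profile.pathway(eye, domain)
        return 1.0 - math.exp(-self.dose / lp.tau)

    def _transfer_fraction(self, eye: str, tclass: str, domain: str) -> float:
        if self.trained_pathway is None:
            return 0.0
        teye, tclass0, tdomain = self.trained_pathway
        lp = self.profile.pathway(teye if teye in EYES else "left", tdomain)
        f = 1.0
        if teye != "both" and eye != teye:
            f *= lp.interocular_transfer_fraction
        if tclass != tclass0:
            f *= lp.task_transfer_matrix.get((tclass0, tclass), 0.0)
        if domain != tdomain:
            f *= lp.cross_domain_fraction
        return f

    def current_alpha(self, eye: str = "both", task: str = "V_vs_H",
                      domain: str = "sf") -> float:
        """Current true threshold for a given eye, task and domain."""
        tclass = task_class(task)
        if eye == "both":
            vals = [self.current_alpha(e, task, domain) for e in EYES]
            return min(vals) if domain == "contrast" else max(vals)
        start, asym, _ = self._span(eye, domain)
        u = self.progress() * self._transfer_fraction(eye, tclass, domain)
        return start + u * (asym - start)

    def psychometric(self, eye: str = "both", task: str = "V_vs_H",
                     domain: str = "sf") -> PsychometricParams:
        return PsychometricParams(
            alpha=self.current_alpha(eye, task, domain),
            beta=self.profile.beta[domain], domain=domain,
            lapse_rate=self.profile.lapse_rate)

    def prob_correct(self, level, domain: str, eye: str = "both",
                     task: str = "V_vs_H"):
        return p_correct(self.psychometric(eye, task, domain), level)

    def begin_training(self, eye: str, task: str, domain: str) -> None:
        """Declare the trained pathway; learning dose accrues to it."""
        self.trained_pathway = (eye, task_class(task), domain)


def simulate_choice(state: ObserverState, stimulus: float, s_plus_side: str,
                    rng: np.random.Generator, *, domain: str = "sf",
                    eye: str = "both", task: str = "V_vs_H", day: int = 1,
                    session: int = 1, index: int = 0,
                    is_correction: bool = False) -> Trial:
    """Simulate one swim: a Bernoulli choice at the stimulus level."""
    if s_plus_side not in ("left", "right"):
        raise ValueError("s_plus_side must be 'left' or 'right'")
    p = state.prob_correct(stimulus, domain, eye, task)
    correct = bool(rng.random() < p)
    choice = s_plus_side if correct else (
        "right" if s_plus_side == "left" else "left")
    return Trial(day=day, session=session, index=index, task=task,
                 domain=domain, level=stimulus, s_plus_side=s_plus_side,
                 choice=choice, correct=correct, is_correction=is_correction,
                 animal_id=state.animal_id)


def update_learning(state: ObserverState, day_trials: Iterable[Trial]
                    ) -> ObserverState:
    """Accrue effective dose from near-threshold practice trials.

    A non-correction trial counts when its level is within the proximity
    bandwidth of the current trained threshold on the log10 axis; the
    trained threshold then relaxes exponentially in dose toward its
    asymptote.  Requires ``begin_training`` to have been called.
    """
    if state.trained_pathway is None:
        raise ValueError("call begin_training before update_learning")
    eye, tclass, domain = state.trained_pathway
    task = "V_vs_H" if tclass == "pattern" else "V_vs_G"
    bw = state.profile.pathway(
        eye if eye in EYES else "left", domain).proximity_bandwidth
    n = 0
    alpha = state.current_alpha(eye if eye != "both" else "both", task, domain)
    for t in day_trials:
        if t.is_correction:
            continue
        if abs(math.log10(t.level) - math.log10(alpha)) <= bw:
            n += 1
    state.dose += n
    return state


def make_cohort(profile: ObserverProfile | str, n: int, seed: int,
                reference_sf: float | None = None) -> list[ObserverState]:
    """Sample a cohort of observers with per-animal child RNG streams.

    Animal i (1-based) draws its threshold offset and its private stream
    from ``SeedSequence((seed, i))``, so cohorts are reproducible and
    individual animals can be regenerated in isolation.
    """
    if isinstance(profile, str):
        profile = make_profile(profile)
    cohort = []
    for i in range(1, n + 1):
        ss = np.random.SeedSequence((seed, i))
        rng = np.random.default_rng(ss)
        offset = profile.alpha_sd_log10 * rng.standard_normal()
        cohort.append(ObserverState(profile=profile, animal_id=i,
                                    log10_offset=offset, rng=rng,
                                    reference_sf=reference_sf))
    return cohort


def cohort_to_frame(cohort: Sequence[ObserverState]) -> pd.DataFrame:
    rows = []
    for obs in cohort:
        for eye in EYES:
            rows.append({
                "animal_id": obs.animal_id,
                "profile": obs.profile.name,
                "eye": eye,
                "alpha_contrast": obs.current_alpha(eye, "V_vs_H", "contrast"),
                "alpha_sf": obs.current_alpha(eye, "V_vs_H", "sf"),
                "log10_offset": obs.log10_offset,
            })
    return pd.DataFrame(rows)


def cohort_to_csv(cohort: Sequence[ObserverState], path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def cohort_from_config(path) -> list[ObserverState]:
    """Build a cohort from a YAML spec: {profile, n, seed[, reference_sf]}.

    The file may contain a single mapping or a list of them under
    ``cohorts:``; the result is the concatenation in file order.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    specs = cfg.get("cohorts", [cfg]) if isinstance(cfg, dict) else cfg
    out: list[ObserverState] = []
    for spec in specs:
        out.extend(make_cohort(spec["profile"], int(spec["n"]),
                               int(spec["seed"]),
                               spec.get("reference_sf")))
    return out
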
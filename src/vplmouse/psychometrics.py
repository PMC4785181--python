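"""Frequency-of-seeing curves, threshold read-out, and contrast sensitivity.

The visual water task yields a trial log per animal.  Accuracy is pooled per
stimulus level into a frequency-of-seeing (FOS) curve and the threshold is the
level at which the curve crosses the 70%-correct criterion, found by linear
interpolation between the two tested levels that bracket the crossing.  In the
contrast domain the threshold converts to contrast sensitivity (CS = 1 /
contrast threshold); thresholds at several spatial frequencies assemble into a
contrast-sensitivity function (CSF).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constants import ACCURACY_CRITERION

__all__ = [
    "FrequencyOfSeeing",
    "ThresholdEstimate",
    "CSFCurve",
    "michelson_contrast",
    "build_fos",
    "threshold_at_criterion",
    "contrast_sensitivity",
    "assemble_csf",
    "log_parabola_csf",
    "solve_log_parabola",
]


def michelson_contrast(l_max: float, l_min: float) -> float:
    """Michelson contrast (Lmax - Lmin) / (Lmax + Lmin) of a grating.

    Both luminances are in cd/m^2 and must be non-negative with
    ``l_max >= l_min`` and ``l_max > 0``.
    """
    if l_min < 0 or l_max < 0:
        raise ValueError("luminance must be non-negative")
    if l_max < l_min:
        raise ValueError("l_max must be >= l_min")
    if l_max == 0:
        raise ValueError("l_max must be positive")
    return (l_max - l_min) / (l_max + l_min)


@dataclass(frozen=True)
class FrequencyOfSeeing:
    """Per-level trial counts and accuracy, sorted by stimulus level."""

    levels: np.ndarray          # strictly increasing stimulus levels
    n_trials: np.ndarray        # non-correction trials per level
    n_correct: np.ndarray
    domain: str                 # "contrast" | "sf"

    def __post_init__(self):
        if not np.all(np.diff(self.levels) > 0):
            raise ValueError("levels must be strictly increasing")
        if np.any(self.n_trials <= 0) or np.any(self.n_correct > self.n_trials):
            raise ValueError("inconsistent trial counts")

    @property
    def accuracy(self) -> np.ndarray:
        return self.n_correct / self.n_trials

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level": self.levels,
                "n_trials": self.n_trials,
                "n_correct": self.n_correct,
                "accuracy": self.accuracy,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_fos(trials: Iterable, include_corrections: bool = False,
              domain: str | None = None) -> FrequencyOfSeeing:
    """Pool a trial log into a frequency-of-seeing curve.

    Correction trials (forced repeats after an error) are excluded by
    default; they follow an error at a known platform side and would bias
    accuracy upward.
    """
    levels: list[float] = []
    correct: list[bool] = []
    for t in trials:
        if t.is_correction and not include_corrections:
            continue
        levels.append(t.level)
        correct.append(t.correct)
        if domain is None:
            domain = t.domain
    if not levels:
        raise ValueError("no (non-correction) trials to pool")
    df = pd.DataFrame({"level": levels, "correct": correct})
    g = df.groupby("level", sort=True)["correct"].agg(["count", "sum"])
    return FrequencyOfSeeing(
        levels=g.index.to_numpy(dtype=float),
        n_trials=g["count"].to_numpy(dtype=int),
        n_correct=g["sum"].to_numpy(dtype=int),
        domain=domain or "contrast",
    )


@dataclass(frozen=True)
class ThresholdEstimate:
    """A stimulus level at the 70%-correct criterion.

    ``defined`` is False when the FOS curve never crosses the criterion
    (e.g. performance above criterion at every tested level).
    """

    threshold: float
    domain: str
    criterion: float = ACCURACY_CRITERION
    fos: FrequencyOfSeeing | None = field(default=None, repr=False)
    defined: bool = True
    reason: str | None = None


def _difficulty_order(fos: FrequencyOfSeeing) -> np.ndarray:
    """Indices of fos.levels from the easiest stimulus to the hardest."""
    if fos.domain == "contrast":
        return np.argsort(fos.levels)[::-1]   # high contrast is easy
    return np.argsort(fos.levels)             # low SF is easy


def threshold_at_criterion(fos: FrequencyOfSeeing,
                           criterion: float = ACCURACY_CRITERION,
                           isotonic: bool = False) -> ThresholdEstimate:
    """Read the threshold off the FOS curve at the accuracy criterion.

    The crossing is sought from the easy end of the level axis: the first
    adjacent pair of tested levels whose accuracy goes from >= criterion to
    < criterion brackets the threshold, which is linearly interpolated.  A
    level whose accuracy equals the criterion exactly is itself the
    threshold.  With ``isotonic=True`` the accuracies are first regularised
    to be non-increasing in difficulty (weighted isotonic regression),
    which removes spurious multiple crossings from sampling noise.
    """
    order = _difficulty_order(fos)
    levels = fos.levels[order]
    acc = fos.accuracy[order].astype(float)
    if isotonic:
        from sklearn.isotonic import IsotonicRegression
        ir = IsotonicRegression(increasing=False)
        acc = ir.fit_transform(np.arange(acc.size), acc,
                               sample_weight=fos.n_trials[order])

    exact = np.nonzero(np.isclose(acc, criterion, rtol=0, atol=1e-12))[0]
    cross = None
    for i in range(acc.size - 1):
        if acc[i] >= criterion > acc[i + 1]:
            cross = i
            break
    if exact.size and (cross is None or exact[0] <= cross):
        return ThresholdEstimate(float(levels[exact[0]]), fos.domain,
                                 criterion, fos)
    if cross is None:
        if np.all(acc >= criterion):
            reason = "floor not reached"
        elif np.all(acc < criterion):
            reason = "criterion not met at any level"
        else:
            reason = "no downward crossing"
        return ThresholdEstimate(math.nan, fos.domain, criterion, fos,
                                 defined=False, reason=reason)
    x0, x1 = levels[cross], levels[cross + 1]
    a0, a1 = acc[cross], acc[cross + 1]
    thr = x0 + (x1 - x0) * (a0 - criterion) / (a0 - a1)
    return ThresholdEstimate(float(thr), fos.domain, criterion, fos)


def contrast_sensitivity(threshold: float) -> float:
    """CS = 1 / contrast threshold; defined on (0, 1]."""
    if not 0 < threshold <= 1:
        raise ValueError("contrast threshold must lie in (0, 1]")
    return 1.0 / threshold


@dataclass(frozen=True)
class CSFCurve:
    """Contrast-sensitivity function: (spatial frequency, CS) points."""

    points: tuple[tuple[float, float], ...]

    def __post_init__(self):
        sfs = [p[0] for p in self.points]
        if sfs != sorted(sfs):
            raise ValueError("points must be sorted by spatial frequency")

    @property
    def sfs(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def cs(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sf_cpd": self.sfs, "cs": self.cs})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def assemble_csf(estimates: Sequence[tuple[float, ThresholdEstimate]]) -> CSFCurve:
    """Assemble contrast-threshold estimates at several SFs into a CSF.

    Undefined estimates are dropped with a warning.
    """
    if not estimates:
        raise ValueError("no estimates to assemble")
    pts = []
    for sf, est in estimates:
        if not est.defined:
            warnings.warn(f"dropping undefined threshold at {sf} cpd "
                          f"({est.reason})", stacklevel=2)
            continue
        pts.append((float(sf), contrast_sensitivity(est.threshold)))
    if not pts:
        raise ValueError("all estimates undefined")
    return CSFCurve(tuple(sorted(pts)))


def log_parabola_csf(sf, peak_cs: float, peak_sf: float, width: float):
    """Log-parabola CSF: log10 CS = log10 peak_cs - width * (log10 sf/peak_sf)^2."""
    sf = np.asarray(sf, dtype=float)
    if np.any(sf <= 0):
        raise ValueError("spatial frequency must be positive")
    return 10.0 ** (np.log10(peak_cs) - width * (np.log10(sf / peak_sf)) ** 2)


def solve_log_parabola(anchor_a: tuple[float, float],
                       anchor_b: tuple[float, float],
                       width: float = 1.5) -> tuple[float, float]:
    """Peak CS and peak SF of the log-parabola through two (sf, CS) anchors.

    Used by the synthetic-observer generator to place contrast thresholds at
    spatial frequencies where no group mean is printed; the width (in
    log10-CS per log10-cpd^2) sets how broad the inverted-U is.
    """
    (s1, c1), (s2, c2) = anchor_a, anchor_b
    l1, l2 = math.log10(s1), math.log10(s2)
    y1, y2 = math.log10(c1), math.log10(c2)
    if s1 == s2:
        raise ValueError("anchors must differ in spatial frequency")
    # y_i = c - width*(l_i - p)^2; subtracting the two equations is linear in p:
    # y2 - y1 = width*(l1 - l2)*(l1 + l2 - 2p)
    p = ((l1 + l2) - (y2 - y1) / ((l1 - l2) * width)) / 2
    c = y1 + width * (l1 - p) ** 2
    return 10.0 ** c, 10.0 ** p
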
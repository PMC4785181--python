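"""Derived learning statistics: improvement, PPR, retention, transfer, and
group summaries, plus the sucrose-preference and spine-density formulas.

All formulas operate on assessed values in their reporting units (CS as
1/contrast-threshold, VA in cpd).  Group statistics are means +/- SEM with
the sample (n-1) standard deviation; by convention an n=1 group reports
SEM 0.  Group-level improvement figures can be computed per animal and then
averaged (the default, matching how the printed group percentages behave)
or directly on group means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "PrePost",
    "GroupSummary",
    "percent_improvement",
    "post_pre_ratio",
    "retention_coefficient",
    "transfer_index",
    "sucrose_preference",
    "spine_density",
    "group_summary",
    "group_improvement",
]


@dataclass(frozen=True)
class PrePost:
    """Pre/post assessed values of one animal, with optional retest and
    naive-group reference (all in the same units)."""

    pre: float
    post: float
    retest: float | None = None
    naive: float | None = None

    def __post_init__(self):
        for v in (self.pre, self.post, self.retest, self.naive):
            if v is not None and v <= 0:
                raise ValueError("assessed values must be positive")


def percent_improvement(pre: float, post: float) -> float:
    """[(post - pre) / pre] x 100, signed."""
    if pre <= 0:
        raise ValueError("pre-training value must be positive")
    return (post - pre) / pre * 100.0


def post_pre_ratio(pre: float, post: float) -> float:
    """PPR = post / pre."""
    if pre <= 0:
        raise ValueError("pre-training value must be positive")
    return post / pre


def retention_coefficient(pre: float, post: float, retest: float) -> float:
    """(retest - pre) / (post - pre) x 100: 100% = fully retained."""
    if post == pre:
        raise ValueError("no learning to retain (post equals pre)")
    return (retest - pre) / (post - pre) * 100.0


def transfer_index(trained_pre: float, trained_post: float,
                   untrained_naive: float, untrained_post: float) -> float:
    """TI = (post - naive)_untrained / (post - pre)_trained.

    TI = 1 indicates complete transfer of the trained improvement to the
    untrained condition, TI = 0 none.
    """
    denom = trained_post - trained_pre
    if denom == 0:
        raise ValueError("zero trained improvement; TI undefined")
    return (untrained_post - untrained_naive) / denom


def sucrose_preference(sucrose_g: float, water_g: float) -> float:
    """Sucrose consumed / total consumed x 100, in percent."""
    if sucrose_g < 0 or water_g < 0:
        raise ValueError("consumptions must be non-negative")
    total = sucrose_g + water_g
    if total == 0:
        raise ValueError("no consumption recorded")
    return sucrose_g / total * 100.0


def spine_density(spine_count: int, segment_length_um: float) -> float:
    """Dendritic spines per 10 um on a segment of at least 25 um."""
    if segment_length_um < 25:
        raise ValueError("segment too short (< 25 um)")
    if spine_count < 0:
        raise ValueError("spine count must be non-negative")
    return spine_count / segment_length_um * 10.0


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sem: float
    degenerate: bool = False    # True for the n=1 SEM-0 convention


def group_summary(values: Sequence[float]) -> GroupSummary:
    """Mean +/- SEM of a group; SEM uses the n-1 sample SD; n=1 -> SEM 0."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("empty group")
    if vals.size == 1:
        return GroupSummary(1, float(vals[0]), 0.0, degenerate=True)
    sem = float(np.std(vals, ddof=1) / math.sqrt(vals.size))
    return GroupSummary(int(vals.size), float(vals.mean()), sem)


def group_improvement(pre: Sequence[float], post: Sequence[float],
                      per_animal: bool = True) -> dict:
    """Group percent improvement and PPR.

    With ``per_animal=True`` (default) each animal's improvement and ratio
    are computed first and then summarised; with False the formulas are
    applied to the group means directly.  The two differ slightly whenever
    animals vary, which is why printed group percentages need not equal
    arithmetic on the printed group means.
    """
    pre = np.asarray(list(pre), dtype=float)
    post = np.asarray(list(post), dtype=float)
    if pre.shape != post.shape or pre.size == 0:
        raise ValueError("pre and post must be equal-length, non-empty")
    if per_animal:
        imps = [percent_improvement(a, b) for a, b in zip(pre, post)]
        pprs = [post_pre_ratio(a, b) for a, b in zip(pre, post)]
        return {"percent_improvement": group_summary(imps),
                "ppr": group_summary(pprs)}
    return {"percent_improvement": percent_improvement(pre.mean(), post.mean()),
            "ppr": post_pre_ratio(pre.mean(), post.mean())}
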
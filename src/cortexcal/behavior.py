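"""Behavioral indices for the texture-discrimination and four-choice tasks.

DI = (approaches to novel - approaches to familiar) / total approaches,
so DI > 0 means novelty preference.  Encoding-phase animals are excluded for
insufficient interest (< 12 total approaches) or side bias (> 60% of
approach time on one column).  The four-choice session criterion is met at
the first trial ending a 10-trial window with >= 8 correct choices;
omissions count as non-correct by default (a flag skips them instead).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._validate import UndefinedResultError

__all__ = [
    "ApproachCounts",
    "discrimination_index",
    "encoding_exclusion",
    "session_criterion",
]

OUTCOMES = ("correct", "incorrect", "omission")


@dataclass(frozen=True)
class ApproachCounts:
    approaches_novel: int
    approaches_familiar: int
    time_on_novel_s: float = 0.0
    time_on_familiar_s: float = 0.0

    def __post_init__(self):
        if self.approaches_novel < 0 or self.approaches_familiar < 0:
            raise ValueError("approach counts must be >= 0")
        if self.time_on_novel_s < 0 or self.time_on_familiar_s < 0:
            raise ValueError("approach times must be >= 0")

    @property
    def total_approaches(self) -> int:
        return self.approaches_novel + self.approaches_familiar


def discrimination_index(counts: ApproachCounts) -> float:
    """(novel - familiar) / total approaches; in [-1, 1]."""
    total = counts.total_approaches
    if total == 0:
        raise UndefinedResultError("DI undefined with zero total approaches")
    return (counts.approaches_novel - counts.approaches_familiar) / total


def encoding_exclusion(
    counts: ApproachCounts, min_total: int = 12, max_bias: float = 0.60
) -> tuple[bool, str]:
    """(include, reason) for an encoding-phase animal.

    Excluded if total approaches < ``min_total`` or if more than
    ``max_bias`` of the approach time is spent on one column.
    """
    if counts.total_approaches < min_total:
        return False, f"insufficient interest ({counts.total_approaches} < {min_total} approaches)"
    total_time = counts.time_on_novel_s + counts.time_on_familiar_s
    if total_time > 0:
        share = max(counts.time_on_novel_s, counts.time_on_familiar_s) / total_time
        if share > max_bias:
            return False, f"side bias ({share:.0%} of approach time on one column)"
    return True, "included"


def session_criterion(
    outcomes, k: int = 8, window: int = 10, skip_omissions: bool = False
) -> int | None:
    """First trial index (1-based count of trials consumed) at which a
    window of ``window`` consecutive trials contains >= ``k`` correct
    choices, or None if never met.

    Omissions count as non-correct; with ``skip_omissions`` they are removed
    before windowing and the returned index still counts every trial
    consumed, omissions included.
    """
    if k > window:
        raise ValueError("k must be <= window")
    seq = list(outcomes)
    for o in seq:
        if o not in OUTCOMES:
            raise ValueError(f"unknown outcome {o!r}")
    if skip_omissions:
        kept = [(i, o) for i, o in enumerate(seq) if o != "omission"]
    else:
        kept = list(enumerate(seq))
    correct = np.array([o == "correct" for _, o in kept], dtype=int)
    if correct.size < window:
        return None
    csum = np.concatenate([[0], np.cumsum(correct)])
    wins = csum[window:] - csum[:-window]
    hits = np.flatnonzero(wins >= k)
    if hits.size == 0:
        return None
    end_kept = int(hits[0]) + window - 1  # index into kept
    return kept[end_kept][0] + 1
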
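"""Matching of detected trees to field/truth stems and accuracy scoring.

A detection can only be paired with a stem when their heights differ by less
than 30% of the stem height and the lean angle from the stem location up to
the crown apex is less than 15 degrees from nadir.  Among eligible pairs an
optimal one-to-one assignment maximizing the total pair score is selected
(Hungarian algorithm).  Unmatched stems are omission errors; unmatched
detections whose apex lies outside the plot buffer are commission errors.

The pair-score formula (equal-weight linear combination of the two
normalized residuals) is this package's own definition: the matching
constraints are standard but no canonical score function exists for them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .segmentation import DetectedTree

MAX_HEIGHT_DIFF_FRAC = 0.30
MAX_LEAN_DEG = 15.0


@dataclass
class MatchResult:
    pairs: List[Tuple[int, int]]  # (detection index, stem index)
    omissions: List[int]  # stem indices
    commissions: List[int]  # detection indices (apex not in buffer)
    total_score: float

    @property
    def mt(self) -> int:
        return len(self.pairs)

    @property
    def oe(self) -> int:
        return len(self.omissions)

    @property
    def ce(self) -> int:
        return len(self.commissions)


@dataclass
class AccuracyScores:
    recall: float
    precision: float
    f_score: float


def pair_score(
    apex_x: float,
    apex_y: float,
    apex_height: float,
    stem_x: float,
    stem_y: float,
    stem_height: float,
) -> Optional[float]:
    """Score in (0, 1] for an eligible detection/stem pair, else None.

    Eligibility: |height difference| < 30% of stem height (strict) and lean
    angle < 15 degrees from nadir (strict), with
    lean = arctan(horizontal distance / apex height).
    """
    if stem_height <= 0:
        raise ValueError("stem height must be positive")
    dh = abs(apex_height - stem_height)
    if dh >= MAX_HEIGHT_DIFF_FRAC * stem_height:
        return None
    horiz = math.hypot(apex_x - stem_x, apex_y - stem_y)
    lean = math.degrees(math.atan2(horiz, apex_height))
    if lean >= MAX_LEAN_DEG:
        return None
    return 0.5 * (1.0 - dh / (MAX_HEIGHT_DIFF_FRAC * stem_height)) + 0.5 * (
        1.0 - lean / MAX_LEAN_DEG
    )


def score_matrix(detected: Sequence[DetectedTree], stems: pd.DataFrame) -> np.ndarray:
    """(n_detections, n_stems) matrix of pair scores; NaN where ineligible."""
    m = np.full((len(detected), len(stems)), np.nan)
    sx = stems["x"].to_numpy(float)
    sy = stems["y"].to_numpy(float)
    sh = stems["height_m"].to_numpy(float)
    for i, t in enumerate(detected):
        for j in range(len(stems)):
            s = pair_score(t.apex_x, t.apex_y, t.apex_height, sx[j], sy[j], sh[j])
            if s is not None:
                m[i, j] = s
    return m


def match_trees(detected: Sequence[DetectedTree], stems: pd.DataFrame) -> MatchResult:
    """Optimal one-to-one matching maximizing total pair score.

    Ineligible pairs can never be matched.  Ties are broken deterministically
    by (stem index, detection index) via the assignment solver's stable
    ordering of an integer-scaled cost matrix.
    """
    nd, ns = len(detected), len(stems)
    if nd == 0 or ns == 0:
        commissions = [i for i, t in enumerate(detected) if not t.in_buffer]
        return MatchResult([], list(range(ns)), commissions, 0.0)
    scores = score_matrix(detected, stems)
    eligible = np.isfinite(scores)
    # maximize score: pad ineligible with 0 benefit but forbid them afterwards
    benefit = np.where(eligible, scores, 0.0)
    rows, cols = linear_sum_assignment(benefit, maximize=True)
    pairs = [(int(r), int(c)) for r, c in zip(rows, cols) if eligible[r, c]]
    pairs.sort(key=lambda rc: (rc[1], rc[0]))
    total = float(sum(scores[r, c] for r, c in pairs))
    matched_d = {r for r, _ in pairs}
    matched_s = {c for _, c in pairs}
    omissions = [j for j in range(ns) if j not in matched_s]
    commissions = [
        i for i, t in enumerate(detected) if i not in matched_d and not t.in_buffer
    ]
    return MatchResult(pairs, omissions, commissions, total)


class UndefinedScoreError(ArithmeticError):
    """Both numerator and denominator are empty: the score has no value."""


def accuracy_scores(m: MatchResult) -> AccuracyScores:
    """Recall = MT/(MT+OE), precision = MT/(MT+CE), F = harmonic mean.

    When MT = 0 with errors present, recall/precision are 0 and F is defined
    as 0 (harmonic-mean limit).  A zero denominator raises
    :class:`UndefinedScoreError`.
    """
    mt, oe, ce = m.mt, m.oe, m.ce
    if mt + oe == 0 or mt + ce == 0:
        raise UndefinedScoreError("no stems or no detections to score against")
    recall = mt / (mt + oe)
    precision = mt / (mt + ce)
    if recall + precision == 0:
        f = 0.0
    else:
        f = 2.0 * recall * precision / (recall + precision)
    return AccuracyScores(recall=recall, precision=precision, f_score=f)
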
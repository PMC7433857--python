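"""Normative cut-off derivation and eligibility screening.

Cut-offs follow the mean − k·SD convention (k = 2 by default) applied to a
control sample; the integer screening thresholds are configuration, with the
published values as defaults (naming abnormal below 60, CCT-Picture abnormal
below 54, exclusion when spontaneous naming exceeds 59).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .errors import InvariantViolationError

REASON_NAMING_NOT_ABNORMAL = "naming-not-abnormal"
REASON_NAMING_ABOVE_EXCLUSION = "naming-above-exclusion"
REASON_CCT_NOT_ABNORMAL = "cct-not-abnormal"
REASON_CCT_REQUIRED = "cct-required"


@dataclass(frozen=True)
class NormativeSample:
    """Control scores for one instrument, with sample mean and SD (n−1)."""

    instrument: str
    scores: tuple[float, ...]

    def __post_init__(self):
        if len(self.scores) < 2:
            raise InvariantViolationError(
                f"normative sample for {self.instrument!r} needs >= 2 scores"
            )

    @property
    def mean(self) -> float:
        return statistics.fmean(self.scores)

    @property
    def sd(self) -> float:
        return statistics.stdev(self.scores)


@dataclass(frozen=True)
class NormativeCutoffs:
    """Integer screening thresholds; defaults are the published values."""

    naming_abnormal_below: int = 60
    cct_abnormal_below: int = 54
    naming_exclude_above: int = 59

    def __post_init__(self):
        if not 0 < self.naming_abnormal_below <= 64:
            raise InvariantViolationError("naming_abnormal_below outside score range")
        if not 0 < self.cct_abnormal_below <= 64:
            raise InvariantViolationError("cct_abnormal_below outside score range")
        if not 0 <= self.naming_exclude_above <= 64:
            raise InvariantViolationError("naming_exclude_above outside score range")


@dataclass(frozen=True)
class ScreeningDecision:
    eligible: bool
    reasons: tuple[str, ...] = field(default_factory=tuple)


def derive_cutoff(sample: NormativeSample, k: float = 2.0) -> float:
    """Return mean − k·SD of the control sample (real-valued).

    The integer threshold actually applied in screening is configuration
    informed by this value; the published thresholds round it inconsistently
    (60 below 60.81 but 54 above 53.84), so no rounding rule is imposed here.
    """
    if not k > 0:
        raise ValueError("k must be positive")
    return sample.mean - k * sample.sd


def screen_participant(
    naming_correct: int,
    cct_picture: Optional[int],
    cutoffs: NormativeCutoffs = NormativeCutoffs(),
    require_cct: bool = True,
) -> ScreeningDecision:
    """Apply the eligibility rules; ineligibility carries every failed rule.

    Eligible iff naming is abnormal (below the naming cut-off), naming does
    not exceed the very-mild-anomia exclusion threshold, and CCT-Picture is
    abnormal (below its cut-off).  Set ``require_cct=False`` for naming-only
    screening when CCT-Picture was not administered.
    """
    if not 0 <= naming_correct <= 64:
        raise InvariantViolationError("naming_correct out of range [0, 64]")
    if cct_picture is not None and not 0 <= cct_picture <= 64:
        raise InvariantViolationError("cct_picture out of range [0, 64]")

    reasons: list[str] = []
    if naming_correct > cutoffs.naming_exclude_above:
        reasons.append(REASON_NAMING_ABOVE_EXCLUSION)
    if naming_correct >= cutoffs.naming_abnormal_below:
        reasons.append(REASON_NAMING_NOT_ABNORMAL)
    if cct_picture is None:
        if require_cct:
            reasons.append(REASON_CCT_REQUIRED)
    elif cct_picture >= cutoffs.cct_abnormal_below:
        reasons.append(REASON_CCT_NOT_ABNORMAL)

    return ScreeningDecision(eligible=not reasons, reasons=tuple(reasons))


def screen_cohort(
    rows: Sequence[tuple[str, int, Optional[int]]],
    cutoffs: NormativeCutoffs = NormativeCutoffs(),
    require_cct: bool = True,
):
    """Screen (participant_id, naming, cct) triples; yields (id, decision)."""
    for pid, naming, cct in rows:
        yield pid, screen_participant(naming, cct, cutoffs, require_cct=require_cct)
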
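"""Semantic storage loss (SSL) scoring.

The SSL score is the unweighted mean of three components, each in [0, 1]:

``c_cue``
    proportion of items missed in spontaneous naming that were retrieved
    with a phonemic cue;
``c_consistency``
    proportion of items missed in spontaneous naming that were recognized
    in the word-picture matching task (WPMT);
``c_ratio``
    naming proportion / (naming proportion + MMSE proportion).

Lower scores indicate a greater degree of semantic storage loss.  Scores
can be computed either from aggregate counts (one row per participant) or
from 64 per-item outcome triples; the item-level route is canonical when
item data exist, because the aggregate reconstruction of ``c_consistency``
assumes every spontaneously named item was also recognized in matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import (
    InvariantViolationError,
    NoMissedItemsError,
    UndefinedRatioError,
)

NAMING_MAX = 64
MMSE_MAX = 30

#: probability-one recognition is NOT assumed for item-level data; these flags
#: mark how a score was obtained and any adjustment applied.
FLAG_AGGREGATE = "aggregate-mode"
FLAG_ITEM_LEVEL = "item-level-mode"
FLAG_CLAMPED = "clamped"
FLAG_NO_MISS = "no-missed-items"


class ParticipantRecord(BaseModel):
    """One participant's aggregate task scores plus optional covariates."""

    model_config = ConfigDict(frozen=True)

    participant_id: str
    group_label: Optional[str] = None
    naming_correct: int = Field(ge=0, le=NAMING_MAX)
    cued_correct: int = Field(ge=0, le=NAMING_MAX)
    wpmt_correct: int = Field(ge=0, le=NAMING_MAX)
    mmse: int = Field(ge=0, le=MMSE_MAX)
    moca: Optional[int] = Field(default=None, ge=0, le=30)
    cct_picture: Optional[int] = Field(default=None, ge=0, le=64)
    roi_ratios: Optional[Mapping[str, float]] = None

    @model_validator(mode="after")
    def _check_invariants(self) -> "ParticipantRecord":
        if self.cued_correct < self.naming_correct:
            raise ValueError(
                f"cued_correct ({self.cued_correct}) < naming_correct "
                f"({self.naming_correct}): cued naming is cumulative"
            )
        if self.roi_ratios is not None:
            for name, value in self.roi_ratios.items():
                if not value > 0:
                    raise ValueError(f"roi_ratios[{name!r}] must be strictly positive")
        return self


class ItemOutcomes(BaseModel):
    """Per-item outcome triples for the 64-item naming battery.

    ``named_with_cue`` is meaningful only for items not named spontaneously;
    entries for spontaneously named items are ignored.
    """

    model_config = ConfigDict(frozen=True)

    participant_id: str
    group_label: Optional[str] = None
    named_spontaneously: tuple[bool, ...]
    named_with_cue: tuple[bool, ...]
    recognized_in_wpmt: tuple[bool, ...]
    mmse: int = Field(ge=0, le=MMSE_MAX)

    @model_validator(mode="after")
    def _check_length(self) -> "ItemOutcomes":
        for name in ("named_spontaneously", "named_with_cue", "recognized_in_wpmt"):
            if len(getattr(self, name)) != NAMING_MAX:
                raise ValueError(f"{name} must have exactly {NAMING_MAX} entries")
        return self

    @property
    def naming_correct(self) -> int:
        return sum(self.named_spontaneously)

    @property
    def cued_correct(self) -> int:
        return sum(
            s or c for s, c in zip(self.named_spontaneously, self.named_with_cue)
        )

    @property
    def wpmt_correct(self) -> int:
        return sum(self.recognized_in_wpmt)

    def to_record(self, **extra) -> ParticipantRecord:
        """Aggregate the item triples into a :class:`ParticipantRecord`."""
        return ParticipantRecord(
            participant_id=self.participant_id,
            group_label=self.group_label,
            naming_correct=self.naming_correct,
            cued_correct=self.cued_correct,
            wpmt_correct=self.wpmt_correct,
            mmse=self.mmse,
            **extra,
        )


@dataclass(frozen=True)
class SSLComponents:
    """The three sub-scores and their unweighted mean."""

    c_cue: float
    c_consistency: float
    c_ratio: float
    flags: frozenset[str] = field(default_factory=frozenset)

    @property
    def ssl(self) -> float:
        return (self.c_cue + self.c_consistency + self.c_ratio) / 3.0

    @property
    def ssl_display(self) -> float:
        return round_half_away(self.ssl, 2)


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (0.505 -> 0.51), unlike banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def cue_retrieval_score(
    naming_correct: int, cued_correct: int, total: int = NAMING_MAX
) -> float:
    """Proportion of items missed in spontaneous naming retrieved with a cue."""
    if not 0 <= naming_correct <= total:
        raise InvariantViolationError(f"naming_correct out of range [0, {total}]")
    if cued_correct < naming_correct:
        raise InvariantViolationError(
            f"cued_correct ({cued_correct}) < naming_correct ({naming_correct})"
        )
    if cued_correct > total:
        raise InvariantViolationError(f"cued_correct out of range [0, {total}]")
    if naming_correct == total:
        raise NoMissedItemsError("all items named spontaneously; score undefined")
    return (cued_correct - naming_correct) / (total - naming_correct)


def consistency_score_aggregate(
    naming_correct: int, wpmt_correct: int, total: int = NAMING_MAX
) -> tuple[float, bool]:
    """Reconstruct the naming->comprehension consistency proportion from counts.

    Assumes every spontaneously named item was also recognized in matching,
    giving (wpmt - naming)/(total - naming).  Values below 0 (WPMT below
    spontaneous naming) are clamped to 0.  Returns ``(score, clamped)``.
    """
    if not 0 <= naming_correct <= total or not 0 <= wpmt_correct <= total:
        raise InvariantViolationError("counts out of range")
    if naming_correct == total:
        raise NoMissedItemsError("all items named spontaneously; score undefined")
    raw = (wpmt_correct - naming_correct) / (total - naming_correct)
    if raw < 0.0:
        return 0.0, True
    return min(raw, 1.0), False


def consistency_score_items(items: ItemOutcomes, baseline: str = "spontaneous") -> float:
    """Item-level consistency: fraction of missed items recognized in matching.

    ``baseline="spontaneous"`` (canonical) conditions on items missed in
    spontaneous naming.  ``baseline="cued"`` is a non-canonical variant
    conditioning on items missed even with a cue; it does not reproduce the
    published scores and is provided for exploratory use only.
    """
    if baseline == "spontaneous":
        missed = [not s for s in items.named_spontaneously]
    elif baseline == "cued":
        missed = [
            not (s or c)
            for s, c in zip(items.named_spontaneously, items.named_with_cue)
        ]
    else:
        raise ValueError(f"unknown baseline {baseline!r}")
    n_missed = sum(missed)
    if n_missed == 0:
        raise NoMissedItemsError("no missed items at the requested baseline")
    hit = sum(r for r, m in zip(items.recognized_in_wpmt, missed) if m)
    return hit / n_missed


def naming_general_ratio(
    naming_correct: int,
    mmse: int,
    naming_max: int = NAMING_MAX,
    mmse_max: int = MMSE_MAX,
) -> float:
    """x/(x+y) with x the naming proportion and y the MMSE proportion.

    Approaches 0 when general cognition outstrips naming (storage-loss
    pattern) and 1 when naming outstrips general cognition; equals 0.5 when
    the two proportions are equal and non-zero.
    """
    if not 0 <= naming_correct <= naming_max:
        raise InvariantViolationError(f"naming_correct out of range [0, {naming_max}]")
    if not 0 <= mmse <= mmse_max:
        raise InvariantViolationError(f"mmse out of range [0, {mmse_max}]")
    if naming_correct == 0 and mmse == 0:
        raise UndefinedRatioError("naming and MMSE both zero; ratio undefined")
    x = naming_correct / naming_max
    y = mmse / mmse_max
    return x / (x + y)


def ssl_score(
    data: ParticipantRecord | ItemOutcomes, mode: str = "aggregate"
) -> SSLComponents:
    """Compute the three components and the omnibus SSL score.

    ``mode="aggregate"`` accepts either input type and scores from counts;
    ``mode="item_level"`` requires :class:`ItemOutcomes` and uses the literal
    item-level consistency definition.  Rounding is applied only at display
    time; the returned components are full precision.
    """
    if mode not in ("aggregate", "item_level"):
        raise ValueError(f"unknown mode {mode!r}")

    flags: set[str] = set()
    if mode == "item_level":
        if not isinstance(data, ItemOutcomes):
            raise TypeError("item_level mode requires ItemOutcomes")
        record = data.to_record()
        c_consistency = consistency_score_items(data)
        flags.add(FLAG_ITEM_LEVEL)
    else:
        record = data.to_record() if isinstance(data, ItemOutcomes) else data
        c_consistency, clamped = consistency_score_aggregate(
            record.naming_correct, record.wpmt_correct
        )
        flags.add(FLAG_AGGREGATE)
        if clamped:
            flags.add(FLAG_CLAMPED)

    c_cue = cue_retrieval_score(record.naming_correct, record.cued_correct)
    c_ratio = naming_general_ratio(record.naming_correct, record.mmse)
    return SSLComponents(
        c_cue=c_cue,
        c_consistency=c_consistency,
        c_ratio=c_ratio,
        flags=frozenset(flags),
    )


def score_cohort(records: Sequence[ParticipantRecord | ItemOutcomes]) -> pd.DataFrame:
    """Score every participant; unscorable rows are retained with a reason code.

    Returns one row per participant with columns ``group_label``, ``c_cue``,
    ``c_consistency``, ``c_ratio``, ``ssl`` (full precision), ``ssl_display``
    (2 dp, half away from zero), ``flags`` and ``unscorable_reason``.
    """
    seen: set[str] = set()
    rows = []
    for rec in records:
        pid = rec.participant_id
        if pid in seen:
            raise InvariantViolationError(f"duplicate participant_id {pid!r}")
        seen.add(pid)
        mode = "item_level" if isinstance(rec, ItemOutcomes) else "aggregate"
        base = {"participant_id": pid, "group_label": rec.group_label}
        try:
            comp = ssl_score(rec, mode=mode)
        except (NoMissedItemsError, UndefinedRatioError) as exc:
            rows.append(
                {
                    **base,
                    "c_cue": float("nan"),
                    "c_consistency": float("nan"),
                    "c_ratio": float("nan"),
                    "ssl": float("nan"),
                    "ssl_display": float("nan"),
                    "flags": exc.reason_code,
                    "unscorable_reason": exc.reason_code,
                }
            )
        else:
            rows.append(
                {
                    **base,
                    "c_cue": comp.c_cue,
                    "c_consistency": comp.c_consistency,
                    "c_ratio": comp.c_ratio,
                    "ssl": comp.ssl,
                    "ssl_display": comp.ssl_display,
                    "flags": ";".join(sorted(comp.flags)),
                    "unscorable_reason": "",
                }
            )
    columns = [
        "participant_id",
        "group_label",
        "c_cue",
        "c_consistency",
        "c_ratio",
        "ssl",
        "ssl_display",
        "flags",
        "unscorable_reason",
    ]
    return pd.DataFrame(rows, columns=columns)
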
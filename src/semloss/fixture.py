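"""Embedded 28-participant reference cohort.

Aggregate task scores, demographics and the published 2-dp SSL value for the
28 PPA participants (11 nfvPPA, 5 svPPA, 12 lvPPA).  Two rows (DL, WB) do not
reproduce their published SSL from the published task counts and carry
``reproducible=False``; they are retained verbatim but excluded from
reproduction checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .scoring import ParticipantRecord, round_half_away, ssl_score

# participant_id, group, pathology, sex, age, education, naming, cued, wpmt,
# mmse, published 2-dp SSL
_ROWS = [
    ("KD", "nfvPPA", "FTD", "F", 61, 8, 28, 51, 56, 18, 0.61),
    ("MR", "nfvPPA", "FTD", "M", 68, 12, 51, 61, 63, 19, 0.75),
    ("BJ", "nfvPPA", "FTD", "M", 72, 15, 57, 64, 64, 28, 0.83),
    ("LR", "nfvPPA", "FTD", "M", 73, 12, 40, 56, 62, 6, 0.78),
    ("MA", "nfvPPA", "FTD", "F", 63, 18, 56, 59, 64, 26, 0.63),
    ("RP", "nfvPPA", "FTD", "M", 59, 14, 26, 50, 52, 17, 0.58),
    ("PS", "nfvPPA", "FTD", "M", 73, 12, 57, 63, 62, 22, 0.71),
    ("DL", "nfvPPA", "FTD", "M", 68, 13, 15, 33, 38, 8, 0.53),
    ("AS", "nfvPPA", "FTD", "F", 71, 16, 46, 59, 64, 23, 0.74),
    ("DC", "nfvPPA", "FTD", "M", 75, 11, 58, 63, 64, 27, 0.78),
    ("LS", "nfvPPA", "FTD", "F", 67, 16, 53, 61, 60, 12, 0.68),
    ("MC", "svPPA", "FTD", "M", 73, 12, 12, 16, 24, 17, 0.19),
    ("WP", "svPPA", "FTD", "M", 82, 12, 7, 21, 38, 10, 0.35),
    ("BF", "svPPA", "FTD", "M", 54, 16, 8, 10, 32, 26, 0.20),
    ("ZD", "svPPA", "FTD", "M", 63, 11, 15, 23, 51, 18, 0.39),
    ("TL", "svPPA", "FTD", "F", 71, 18, 14, 17, 49, 26, 0.32),
    ("GD", "lvPPA", "AD", "M", 78, 7, 51, 59, 61, 19, 0.65),
    ("OL", "lvPPA", "AD", "M", 65, 11, 30, 40, 57, 23, 0.49),
    ("LA", "lvPPA", "AD", "F", 56, 18, 11, 11, 45, 7, 0.36),
    ("FA", "lvPPA", "AD", "F", 77, 16, 10, 15, 40, 8, 0.34),
    ("MG", "lvPPA", "AD", "M", 79, 10, 31, 49, 45, 23, 0.45),
    ("CG", "lvPPA", "AD", "M", 78, 9, 21, 34, 58, 12, 0.54),
    ("CC", "lvPPA", "AD", "F", 78, 12, 17, 36, 46, 12, 0.47),
    ("MD", "lvPPA", "AD", "M", 64, 11, 30, 50, 53, 14, 0.59),
    ("SC", "lvPPA", "AD", "M", 80, 14, 27, 51, 43, 17, 0.50),
    ("WB", "lvPPA", "AD", "F", 60, 18, 3, 20, 26, 2, 0.41),
    ("AM", "lvPPA", "AD", "M", 60, 18, 44, 59, 60, 13, 0.72),
    ("BM", "lvPPA", "AD", "F", 72, 18, 12, 36, 54, 10, 0.54),
]

_COLUMNS = [
    "participant_id",
    "group_label",
    "pathology",
    "sex",
    "age",
    "education_years",
    "naming_correct",
    "cued_correct",
    "wpmt_correct",
    "mmse",
    "ssl_printed",
]


@dataclass(frozen=True)
class Fixture28:
    """The embedded reference cohort as a frame plus validated records."""

    frame: pd.DataFrame

    @property
    def records(self) -> list[ParticipantRecord]:
        return [
            ParticipantRecord(
                participant_id=r.participant_id,
                group_label=r.group_label,
                naming_correct=r.naming_correct,
                cued_correct=r.cued_correct,
                wpmt_correct=r.wpmt_correct,
                mmse=r.mmse,
            )
            for r in self.frame.itertuples(index=False)
        ]

    @property
    def group_sizes(self) -> dict[str, int]:
        return self.frame["group_label"].value_counts().to_dict()


def load_fixture() -> Fixture28:
    """Return the embedded cohort with a per-row ``reproducible`` flag.

    ``reproducible`` is computed at load time: True iff re-scoring the row's
    task counts reproduces the published 2-dp SSL exactly.
    """
    frame = pd.DataFrame(_ROWS, columns=_COLUMNS)
    repro = []
    for r in frame.itertuples(index=False):
        comp = ssl_score(
            ParticipantRecord(
                participant_id=r.participant_id,
                naming_correct=r.naming_correct,
                cued_correct=r.cued_correct,
                wpmt_correct=r.wpmt_correct,
                mmse=r.mmse,
            )
        )
        repro.append(round_half_away(comp.ssl, 2) == round_half_away(r.ssl_printed, 2))
    frame["reproducible"] = repro
    return Fixture28(frame=frame)
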
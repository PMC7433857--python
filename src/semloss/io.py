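"""CSV input/output and configuration.

Two schemas are supported:

aggregate (one row per participant)
    ``participant_id, naming_correct, cued_correct, wpmt_correct, mmse`` with
    optional ``group_label, moca, cct_picture, atl_left, atl_right,
    dlpfc_left, dlpfc_right`` (the four ROI columns become ``roi_ratios``).

item_level (long format, 64 rows per participant)
    ``participant_id, item_index, category, named_spontaneously,
    named_with_cue, recognized_in_wpmt`` plus ``mmse`` (and optionally
    ``group_label``), constant within participant.
"""

from __future__ import annotations

import configparser
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .scoring import ItemOutcomes, ParticipantRecord
from .screening import NormativeCutoffs
from .simulate import ROI_NAMES, SimulatedCohort

logger = logging.getLogger("semloss")

AGGREGATE_REQUIRED = [
    "participant_id",
    "naming_correct",
    "cued_correct",
    "wpmt_correct",
    "mmse",
]
AGGREGATE_OPTIONAL = ["group_label", "moca", "cct_picture", *ROI_NAMES]

ITEM_REQUIRED = [
    "participant_id",
    "item_index",
    "named_spontaneously",
    "named_with_cue",
    "recognized_in_wpmt",
    "mmse",
]
ITEM_OPTIONAL = ["category", "group_label"]

_BOOL = {"true": True, "1": True, "false": False, "0": False}


@dataclass
class RowError:
    line: int
    participant_id: str
    message: str


@dataclass
class CohortReadResult:
    records: list = field(default_factory=list)
    errors: list[RowError] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def _check_header(columns, required, optional, path):
    missing = [c for c in required if c not in columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    unknown = [c for c in columns if c not in required + optional]
    if unknown:
        warnings.warn(f"{path}: ignoring unknown columns {unknown}", stacklevel=3)


def _parse_bool(value) -> bool:
    key = str(value).strip().lower()
    if key not in _BOOL:
        raise ValueError(f"not a boolean: {value!r}")
    return _BOOL[key]


def read_cohort_csv(path, schema: str = "aggregate") -> CohortReadResult:
    """Read and validate a cohort CSV; malformed rows go to an error report.

    Line numbers in the error report are 1-based file lines (header = 1).
    """
    path = Path(path)
    if schema == "aggregate":
        return _read_aggregate(path)
    if schema == "item_level":
        return _read_items(path)
    raise ValueError(f"unknown schema {schema!r}")


def _read_aggregate(path: Path) -> CohortReadResult:
    frame = pd.read_csv(path, dtype={"participant_id": str})
    _check_header(list(frame.columns), AGGREGATE_REQUIRED, AGGREGATE_OPTIONAL, path)
    result = CohortReadResult()
    for pos, row in enumerate(frame.to_dict("records")):
        line = pos + 2  # header is line 1
        pid = str(row.get("participant_id", ""))
        roi = {
            name: float(row[name])
            for name in ROI_NAMES
            if name in row and pd.notna(row[name])
        }
        try:
            record = ParticipantRecord(
                participant_id=pid,
                group_label=_opt_str(row.get("group_label")),
                naming_correct=_req_int(row, "naming_correct"),
                cued_correct=_req_int(row, "cued_correct"),
                wpmt_correct=_req_int(row, "wpmt_correct"),
                mmse=_req_int(row, "mmse"),
                moca=_opt_int(row.get("moca")),
                cct_picture=_opt_int(row.get("cct_picture")),
                roi_ratios=roi or None,
            )
        except (ValueError, TypeError) as exc:
            result.errors.append(RowError(line=line, participant_id=pid, message=str(exc)))
        else:
            result.records.append(record)
    return result


def _read_items(path: Path) -> CohortReadResult:
    frame = pd.read_csv(path, dtype={"participant_id": str})
    _check_header(list(frame.columns), ITEM_REQUIRED, ITEM_OPTIONAL, path)
    result = CohortReadResult()
    for pid, sub in frame.groupby("participant_id", sort=False):
        first_line = int(sub.index[0]) + 2
        try:
            sub = sub.sort_values("item_index")
            triples = {
                col: tuple(_parse_bool(v) for v in sub[col])
                for col in ("named_spontaneously", "named_with_cue", "recognized_in_wpmt")
            }
            mmse_vals = set(int(v) for v in sub["mmse"])
            if len(mmse_vals) != 1:
                raise ValueError(f"mmse not constant within participant {pid!r}")
            group = None
            if "group_label" in sub.columns:
                group = _opt_str(sub["group_label"].iloc[0])
            items = ItemOutcomes(
                participant_id=str(pid),
                group_label=group,
                named_spontaneously=triples["named_spontaneously"],
                named_with_cue=triples["named_with_cue"],
                recognized_in_wpmt=triples["recognized_in_wpmt"],
                mmse=mmse_vals.pop(),
            )
        except (ValueError, TypeError) as exc:
            result.errors.append(
                RowError(line=first_line, participant_id=str(pid), message=str(exc))
            )
        else:
            result.records.append(items)
    return result


def _req_int(row: dict, key: str) -> int:
    value = row.get(key)
    if value is None or (isinstance(value, float) and pd.isna(value)):
        raise ValueError(f"missing value for {key}")
    f = float(value)
    if f != int(f):
        raise ValueError(f"{key} must be an integer, got {value!r}")
    return int(f)


def _opt_int(value):
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    return _req_int({"x": value}, "x")


def _opt_str(value):
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    return str(value)


def records_to_frame(records) -> pd.DataFrame:
    """Aggregate records -> CSV-shaped frame (ROI map expanded to columns)."""
    rows = []
    for rec in records:
        row = {
            "participant_id": rec.participant_id,
            "group_label": rec.group_label,
            "naming_correct": rec.naming_correct,
            "cued_correct": rec.cued_correct,
            "wpmt_correct": rec.wpmt_correct,
            "mmse": rec.mmse,
            "moca": rec.moca,
            "cct_picture": rec.cct_picture,
        }
        for name in ROI_NAMES:
            row[name] = (rec.roi_ratios or {}).get(name)
        rows.append(row)
    return pd.DataFrame(rows)


def items_to_frame(items_list) -> pd.DataFrame:
    """Item outcomes -> long-format frame (8 categories x 8 items)."""
    rows = []
    for items in items_list:
        for i in range(64):
            rows.append(
                {
                    "participant_id": items.participant_id,
                    "group_label": items.group_label,
                    "item_index": i + 1,
                    "category": i // 8 + 1,
                    "named_spontaneously": items.named_spontaneously[i],
                    "named_with_cue": items.named_with_cue[i],
                    "recognized_in_wpmt": items.recognized_in_wpmt[i],
                    "mmse": items.mmse,
                }
            )
    return pd.DataFrame(rows)


def write_cohort(cohort: SimulatedCohort, out_dir) -> tuple[Path, Path]:
    """Write aggregate and item-level CSVs for a simulated cohort."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    agg_path = out_dir / "cohort_aggregate.csv"
    items_path = out_dir / "cohort_items.csv"
    records_to_frame(cohort.records).to_csv(agg_path, index=False)
    items_to_frame(cohort.items).to_csv(items_path, index=False)
    return agg_path, items_path


def read_config(path) -> NormativeCutoffs:
    """Read screening thresholds from an INI-style key/value config.

    Recognized keys (section ``[screening]`` or top level ``[DEFAULT]``):
    ``naming_abnormal_below``, ``cct_abnormal_below``, ``naming_exclude_above``.
    """
    parser = configparser.ConfigParser()
    with open(path) as fh:
        parser.read_file(fh)
    section = parser["screening"] if parser.has_section("screening") else parser["DEFAULT"]
    defaults = NormativeCutoffs()
    return NormativeCutoffs(
        naming_abnormal_below=section.getint(
            "naming_abnormal_below", defaults.naming_abnormal_below
        ),
        cct_abnormal_below=section.getint(
            "cct_abnormal_below", defaults.cct_abnormal_below
        ),
        naming_exclude_above=section.getint(
            "naming_exclude_above", defaults.naming_exclude_above
        ),
    )
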
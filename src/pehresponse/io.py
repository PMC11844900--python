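"""Reading and writing long-format trial datasets (CSV / XLSX).

Canonical storage is long format: one row per participant x condition x
timepoint, with the header
``participant_id, group, condition, timepoint, hr, bsbp, bdbp, csbp, cfpwv``.
Recognised optional columns carry duplicate tonometry replicates
(``csbp_rep1`` ...) and participant covariates (``age``, ``sex``, ``vo2peak``,
``hr_max``); anything else is ignored with a logged warning. Numeric minute
columns for the timepoint (0/5/15/30) are mapped onto PRE/P5/P15/P30 on read.

``read_dataset(write_dataset(d)) == d`` holds for every valid dataset.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Optional

import pandas as pd

from .errors import IntegrityError, ParseError, SchemaError
from .model import (
    MINUTE_TO_TIMEPOINT,
    Condition,
    Group,
    ParticipantRecord,
    SessionMeasurement,
    Sex,
    StudyDataset,
    Timepoint,
)

log = logging.getLogger(__name__)

MANDATORY_COLUMNS = ("participant_id", "group", "condition", "timepoint", "bsbp", "bdbp", "csbp")
MEASUREMENT_OPTIONAL = ("hr", "cfpwv", "csbp_rep1", "csbp_rep2", "bsbp_rep1", "bsbp_rep2")
PARTICIPANT_OPTIONAL = ("age", "sex", "vo2peak", "hr_max")
CANONICAL_ORDER = (
    "participant_id",
    "group",
    "condition",
    "timepoint",
    "hr",
    "bsbp",
    "bdbp",
    "csbp",
    "cfpwv",
    "csbp_rep1",
    "csbp_rep2",
    "bsbp_rep1",
    "bsbp_rep2",
    "age",
    "sex",
    "vo2peak",
    "hr_max",
)

_NUMERIC = ("hr", "bsbp", "bdbp", "csbp", "cfpwv", "csbp_rep1", "csbp_rep2",
            "bsbp_rep1", "bsbp_rep2", "age", "vo2peak", "hr_max")


def _parse_timepoint(raw: object, row: int) -> Timepoint:
    if isinstance(raw, Timepoint):
        return raw
    text = str(raw).strip()
    try:
        return Timepoint(text.upper())
    except ValueError:
        pass
    try:
        minutes = int(float(text))
    except (TypeError, ValueError):
        raise ParseError(f"row {row}: unrecognised timepoint {raw!r}") from None
    if minutes not in MINUTE_TO_TIMEPOINT:
        raise ParseError(f"row {row}: timepoint minutes {minutes} not in {sorted(MINUTE_TO_TIMEPOINT)}")
    return MINUTE_TO_TIMEPOINT[minutes]


def _num(raw: object, column: str, row: int) -> Optional[float]:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    if isinstance(raw, str) and raw.strip() == "":
        return None
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise ParseError(f"row {row}: non-numeric value {raw!r} in column {column!r}") from None


def read_dataset(
    path: str | Path,
    format: Optional[str] = None,
    column_map: Optional[dict[str, str]] = None,
) -> StudyDataset:
    """Load and validate a long-format dataset from CSV or XLSX.

    Parameters
    ----------
    path
        File to read. ``format`` ("csv" or "xlsx") is inferred from the
        suffix when not given.
    column_map
        Optional mapping from the file's column names onto the canonical
        ones, for spreadsheets laid out with other headers.

    Raises
    ------
    SchemaError
        A mandatory column is absent.
    ParseError
        A cell cannot be converted (the message names the 1-based data row).
    IntegrityError
        Duplicate (participant, condition, timepoint) rows, inconsistent
        group labels, or physically impossible pressures.
    """
    path = Path(path)
    fmt = format or ("xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv")
    if fmt == "xlsx":
        frame = pd.read_excel(path, sheet_name=0)
    else:
        frame = pd.read_csv(path, float_precision="round_trip")
    if column_map:
        frame = frame.rename(columns=column_map)
    frame.columns = [str(c).strip() for c in frame.columns]

    known = set(MANDATORY_COLUMNS) | set(MEASUREMENT_OPTIONAL) | set(PARTICIPANT_OPTIONAL)
    unknown = [c for c in frame.columns if c not in known]
    if unknown:
        log.warning("ignoring unknown columns: %s", unknown)
    missing = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")

    participants: dict[str, ParticipantRecord] = {}
    measurements: list[SessionMeasurement] = []
    for idx, rec in enumerate(frame.to_dict("records"), start=1):
        pid = str(rec["participant_id"]).strip()
        try:
            group = Group(str(rec["group"]).strip().upper())
        except ValueError:
            raise ParseError(f"row {idx}: unknown group {rec['group']!r}") from None
        try:
            condition = Condition(str(rec["condition"]).strip().upper())
        except ValueError:
            raise ParseError(f"row {idx}: unknown condition {rec['condition']!r}") from None
        timepoint = _parse_timepoint(rec["timepoint"], idx)

        if pid not in participants:
            sex_raw = rec.get("sex")
            sex = None
            if sex_raw is not None and not (isinstance(sex_raw, float) and math.isnan(sex_raw)):
                text = str(sex_raw).strip().upper()
                if text:
                    try:
                        sex = Sex(text)
                    except ValueError:
                        raise ParseError(f"row {idx}: unknown sex {sex_raw!r}") from None
            participants[pid] = ParticipantRecord(
                id=pid,
                group=group,
                age=_num(rec.get("age"), "age", idx),
                sex=sex,
                vo2peak=_num(rec.get("vo2peak"), "vo2peak", idx),
                hr_max=_num(rec.get("hr_max"), "hr_max", idx),
            )
        elif participants[pid].group != group:
            raise IntegrityError(f"row {idx}: participant {pid!r} listed under two groups")

        try:
            measurements.append(
                SessionMeasurement(
                    participant_id=pid,
                    condition=condition,
                    timepoint=timepoint,
                    hr=_num(rec.get("hr"), "hr", idx),
                    bsbp=_num(rec["bsbp"], "bsbp", idx),
                    bdbp=_num(rec["bdbp"], "bdbp", idx),
                    csbp=_num(rec["csbp"], "csbp", idx),
                    cfpwv=_num(rec.get("cfpwv"), "cfpwv", idx),
                    csbp_rep1=_num(rec.get("csbp_rep1"), "csbp_rep1", idx),
                    csbp_rep2=_num(rec.get("csbp_rep2"), "csbp_rep2", idx),
                    bsbp_rep1=_num(rec.get("bsbp_rep1"), "bsbp_rep1", idx),
                    bsbp_rep2=_num(rec.get("bsbp_rep2"), "bsbp_rep2", idx),
                )
            )
        except IntegrityError as exc:
            raise IntegrityError(f"row {idx}: {exc}") from None

    return StudyDataset(
        participants=list(participants.values()),
        measurements=measurements,
        provenance=str(path),
    )


def to_frame(data: StudyDataset) -> pd.DataFrame:
    """Flatten a dataset into the canonical long-format table."""
    groups = {p.id: p for p in data.participants}
    rows = []
    for m in data.measurements:
        p = groups[m.participant_id]
        rows.append(
            {
                "participant_id": m.participant_id,
                "group": p.group.value,
                "condition": m.condition.value,
                "timepoint": m.timepoint.value,
                "hr": m.hr,
                "bsbp": m.bsbp,
                "bdbp": m.bdbp,
                "csbp": m.csbp,
                "cfpwv": m.cfpwv,
                "csbp_rep1": m.csbp_rep1,
                "csbp_rep2": m.csbp_rep2,
                "bsbp_rep1": m.bsbp_rep1,
                "bsbp_rep2": m.bsbp_rep2,
                "age": p.age,
                "sex": p.sex.value if p.sex is not None else None,
                "vo2peak": p.vo2peak,
                "hr_max": p.hr_max,
            }
        )
    frame = pd.DataFrame(rows, columns=list(CANONICAL_ORDER))
    # drop all-empty optional columns so hand-written files round-trip cleanly
    base = {*MANDATORY_COLUMNS, "hr", "cfpwv"}
    keep = [c for c in CANONICAL_ORDER if c in base or (len(frame) and frame[c].notna().any())]
    return frame[keep]


def write_dataset(data: StudyDataset, path: str | Path) -> None:
    """Write the canonical long-format CSV; inverse of :func:`read_dataset`."""
    frame = to_frame(data)
    frame.to_csv(path, index=False)
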
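"""Study data model for a two-group, two-condition, four-timepoint crossover trial.

The trial structure: participants with coronary artery disease (CAD) and
age-matched controls (CON) each complete a moderate (MOD) and a high-intensity
(HIGH) combined exercise session, with supine hemodynamic measurements taken
pre-exercise and 5, 15 and 30 minutes into recovery.

Units are fixed throughout the package: pressures in mmHg, pulse wave velocity
in m/s, heart rate in beats/min. No unit inference is performed.
"""

from __future__ import annotations

import enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import IntegrityError


class Group(str, enum.Enum):
    CAD = "CAD"
    CON = "CON"


class Condition(str, enum.Enum):
    MOD = "MOD"
    HIGH = "HIGH"


class Timepoint(str, enum.Enum):
    PRE = "PRE"
    P5 = "P5"
    P15 = "P15"
    P30 = "P30"


#: Minute offsets accepted on read and mapped onto the fixed labels.
MINUTE_TO_TIMEPOINT = {0: Timepoint.PRE, 5: Timepoint.P5, 15: Timepoint.P15, 30: Timepoint.P30}


class Sex(str, enum.Enum):
    M = "M"
    F = "F"


class Outcome(str, enum.Enum):
    """Measured hemodynamic outcomes addressable by downstream analyses."""

    CSBP = "csbp"
    BSBP = "bsbp"
    BDBP = "bdbp"
    HR = "hr"
    CFPWV = "cfpwv"


class ParticipantRecord(BaseModel):
    """One enrolled subject with group assignment and optional covariates."""

    model_config = ConfigDict(frozen=True)

    id: str
    group: Group
    age: Optional[float] = Field(default=None, gt=0)
    sex: Optional[Sex] = None
    vo2peak: Optional[float] = Field(default=None, gt=0)
    hr_max: Optional[float] = Field(default=None, gt=0)
    hypertensive: Optional[bool] = None
    ace_inhibitor: Optional[bool] = None
    beta_blocker: Optional[bool] = None
    ca_blocker: Optional[bool] = None
    anticoagulant: Optional[bool] = None
    statin: Optional[bool] = None


class SessionMeasurement(BaseModel):
    """One (participant, condition, timepoint) hemodynamic observation.

    ``csbp``/``bsbp`` hold the values used for analysis (the average of the
    two tonometry/oscillometry replicates when duplicates were recorded); the
    raw replicates, when available, travel in the optional ``*_rep`` fields so
    that individual coefficients of variation remain estimable.
    """

    model_config = ConfigDict(frozen=True)

    participant_id: str
    condition: Condition
    timepoint: Timepoint
    hr: Optional[float] = Field(default=None, gt=0)
    bsbp: float = Field(gt=0)
    bdbp: float = Field(gt=0)
    csbp: float = Field(gt=0)
    cfpwv: Optional[float] = Field(default=None, gt=0)
    csbp_rep1: Optional[float] = Field(default=None, gt=0)
    csbp_rep2: Optional[float] = Field(default=None, gt=0)
    bsbp_rep1: Optional[float] = Field(default=None, gt=0)
    bsbp_rep2: Optional[float] = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _pressures_ordered(self) -> "SessionMeasurement":
        if not self.bsbp > self.bdbp:
            raise IntegrityError(
                f"participant {self.participant_id!r} {self.condition.value}/"
                f"{self.timepoint.value}: bsbp ({self.bsbp}) must exceed bdbp ({self.bdbp})"
            )
        return self

    def value(self, outcome: Outcome | str) -> Optional[float]:
        return getattr(self, Outcome(outcome).value)


class StudyDataset(BaseModel):
    """Validated container of participants and their session measurements.

    Invariants enforced at construction: participant ids unique, every
    measurement references an enrolled participant, and at most one
    measurement per (participant, condition, timepoint).
    """

    participants: list[ParticipantRecord]
    measurements: list[SessionMeasurement]
    provenance: str = ""

    @model_validator(mode="after")
    def _check_integrity(self) -> "StudyDataset":
        ids = [p.id for p in self.participants]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise IntegrityError(f"duplicate participant ids: {dupes}")
        known = set(ids)
        seen: set[tuple[str, Condition, Timepoint]] = set()
        for m in self.measurements:
            if m.participant_id not in known:
                raise IntegrityError(f"measurement references unknown participant {m.participant_id!r}")
            key = (m.participant_id, m.condition, m.timepoint)
            if key in seen:
                raise IntegrityError(
                    f"duplicate measurement for participant {key[0]!r} "
                    f"{key[1].value}/{key[2].value}"
                )
            seen.add(key)
        return self

    # -- convenience accessors -------------------------------------------------

    def participant(self, pid: str) -> ParticipantRecord:
        for p in self.participants:
            if p.id == pid:
                return p
        raise KeyError(pid)

    def measurement(
        self, pid: str, condition: Condition | str, timepoint: Timepoint | str
    ) -> Optional[SessionMeasurement]:
        condition = Condition(condition)
        timepoint = Timepoint(timepoint)
        for m in self.measurements:
            if (
                m.participant_id == pid
                and m.condition == condition
                and m.timepoint == timepoint
            ):
                return m
        return None

    def measurements_for(self, pid: str) -> list[SessionMeasurement]:
        return [m for m in self.measurements if m.participant_id == pid]

    def is_complete(
        self, pid: str, outcome: Outcome | str, condition: Condition | str
    ) -> bool:
        """A participant is complete for an outcome x condition iff PRE and at
        least one of {P15, P30} carry a value for that outcome."""
        outcome = Outcome(outcome)

        def has(tp: Timepoint) -> bool:
            m = self.measurement(pid, condition, tp)
            return m is not None and m.value(outcome) is not None

        return has(Timepoint.PRE) and (has(Timepoint.P15) or has(Timepoint.P30))

    def complete_participants(
        self, outcome: Outcome | str, condition: Condition | str
    ) -> list[ParticipantRecord]:
        return [p for p in self.participants if self.is_complete(p.id, outcome, condition)]
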
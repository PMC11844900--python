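"""Derived hemodynamic quantities.

Central pressures are obtained by carotid tonometry calibrated from brachial
diastolic and mean arterial pressure, both assumed constant along the arterial
tree; that calibration fixes the conventions used here:

* mean arterial pressure  MAP = 2/3 bDBP + 1/3 bSBP
* amplification           AP  = bSBP - cSBP (may be negative in stiff arteries)
* pulse pressures         bPP = bSBP - bDBP,  cPP = cSBP - bDBP
* carotid-femoral PWV     cfPWV = 0.8 x taped distance / transit time
* heart-rate recovery     HRR1 = HR_peak - HR_1min (positive-recovery sign)
* technical error         TE  = CV x baseline mean

Session load is scored with the training-impulse (TRIMP) method: zone-weighted
aerobic minutes (below-VT1 = 1, at-VT1 = 2, at-VT2 = 3, main aerobic segment
only) plus resistance volume (sets x reps x effective load in kg).
"""

from __future__ import annotations

import enum
import logging
import math
import warnings
from typing import Optional, Sequence

from pydantic import BaseModel, ConfigDict, Field

from .errors import DomainError
from .model import Outcome, SessionMeasurement, StudyDataset, Timepoint

log = logging.getLogger(__name__)

SQRT2 = math.sqrt(2.0)


# --------------------------------------------------------------------------
# pointwise derived pressures


def mean_arterial_pressure(bsbp: float, bdbp: float) -> float:
    """MAP = 2/3 diastolic + 1/3 systolic; strictly between the two inputs."""
    if not (bsbp > bdbp > 0):
        raise DomainError(f"require bsbp > bdbp > 0, got ({bsbp}, {bdbp})")
    return (2.0 * bdbp + bsbp) / 3.0


def amplification(bsbp: float, csbp: float) -> float:
    """Amplification pressure: brachial minus central systolic, sign kept."""
    if bsbp <= 0 or csbp <= 0:
        raise DomainError(f"pressures must be positive, got ({bsbp}, {csbp})")
    return bsbp - csbp


def pulse_pressures(bsbp: float, bdbp: float, csbp: float) -> tuple[float, float]:
    """(brachial, central) pulse pressure; central diastolic is taken equal to
    brachial diastolic under the tonometry calibration."""
    if not (bsbp > bdbp > 0):
        raise DomainError(f"require bsbp > bdbp > 0, got ({bsbp}, {bdbp})")
    if csbp <= 0:
        raise DomainError(f"csbp must be positive, got {csbp}")
    return bsbp - bdbp, csbp - bdbp


def cfpwv(taped_distance: float, ptt: float, correction: float = 0.8) -> float:
    """Carotid-femoral pulse wave velocity in m/s.

    ``taped_distance`` is the over-body tape distance between recording sites
    in metres, scaled by ``correction`` (0.8 by convention) to approximate the
    true arterial path; ``ptt`` is the foot-to-foot pulse transit time in s.
    """
    if taped_distance <= 0 or ptt <= 0 or correction <= 0:
        raise DomainError(
            f"distance, transit time and correction must be positive, "
            f"got ({taped_distance}, {ptt}, {correction})"
        )
    return correction * taped_distance / ptt


def hrr1(hr_peak: float, hr_1min: float) -> float:
    """Heart-rate recovery at 1 min, reported as peak minus 1-min HR so that
    a faster recovery gives a larger positive number."""
    if hr_peak <= 0 or hr_1min <= 0:
        raise DomainError(f"heart rates must be positive, got ({hr_peak}, {hr_1min})")
    return hr_peak - hr_1min


def technical_error(cv: float, baseline_mean: float) -> float:
    """Technical error of measurement: CV (as a fraction) times baseline mean."""
    if cv < 0:
        raise DomainError(f"cv must be non-negative, got {cv}")
    if baseline_mean <= 0:
        raise DomainError(f"baseline mean must be positive, got {baseline_mean}")
    if cv > 1:
        warnings.warn(f"cv {cv} > 1 is implausible for blood pressure", stacklevel=2)
    return cv * baseline_mean


def coefficient_of_variation(rep1: float, rep2: float) -> float:
    """Within-pair CV of duplicate readings: SD of the pair over the pair mean.

    The SD of two values is |rep1 - rep2| / sqrt(2).
    """
    if rep1 <= 0 or rep2 <= 0:
        raise DomainError(f"replicates must be positive, got ({rep1}, {rep2})")
    return abs(rep1 - rep2) / SQRT2 / ((rep1 + rep2) / 2.0)


def delta_from_baseline(pre: Optional[float], post: Optional[float]) -> Optional[float]:
    """Post-exercise change; ``None``/NaN in either argument propagates."""
    if pre is None or post is None:
        return None
    if math.isnan(pre) or math.isnan(post):
        return math.nan
    return post - pre


# --------------------------------------------------------------------------
# per-session derived panel


class HemoPanel(BaseModel):
    """Derived pressures for one session measurement."""

    model_config = ConfigDict(frozen=True)

    map: float
    bpp: float
    cpp: float
    amplification: float
    source: SessionMeasurement


def derive_panel(m: SessionMeasurement) -> HemoPanel:
    bpp, cpp = pulse_pressures(m.bsbp, m.bdbp, m.csbp)
    return HemoPanel(
        map=mean_arterial_pressure(m.bsbp, m.bdbp),
        bpp=bpp,
        cpp=cpp,
        amplification=amplification(m.bsbp, m.csbp),
        source=m,
    )


def derived_table(data: StudyDataset):
    """One row of derived quantities per session measurement (DataFrame)."""
    import pandas as pd

    rows = []
    for m in data.measurements:
        panel = derive_panel(m)
        rows.append(
            {
                "participant_id": m.participant_id,
                "condition": m.condition.value,
                "timepoint": m.timepoint.value,
                "map": panel.map,
                "bpp": panel.bpp,
                "cpp": panel.cpp,
                "amplification": panel.amplification,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["participant_id", "condition", "timepoint", "map", "bpp", "cpp", "amplification"],
    )


# --------------------------------------------------------------------------
# session load (TRIMP)


class Zone(str, enum.Enum):
    BELOW_VT1 = "BELOW_VT1"
    AT_VT1 = "AT_VT1"
    AT_VT2 = "AT_VT2"


DEFAULT_ZONE_WEIGHTS: dict[Zone, float] = {Zone.BELOW_VT1: 1.0, Zone.AT_VT1: 2.0, Zone.AT_VT2: 3.0}


class SessionPlan(BaseModel):
    """Structure of one combined-exercise session.

    ``segments`` lists only the main aerobic block (warm-up and cool-down are
    excluded from the load score); ``loads_1rm_fraction`` gives, per resistance
    exercise, the one-repetition maximum in kg and the prescribed fraction.
    """

    model_config = ConfigDict(frozen=True)

    segments: tuple[tuple[float, Zone], ...] = ()
    resistance_sets: int = Field(default=0, ge=0)
    resistance_reps: int = Field(default=0, ge=0)
    loads_1rm_fraction: tuple[tuple[float, float], ...] = ()

    @property
    def valid(self) -> bool:
        return all(d > 0 for d, _ in self.segments) and all(
            rm > 0 and 0 < f <= 1 for rm, f in self.loads_1rm_fraction
        )


class TrimpScore(BaseModel):
    model_config = ConfigDict(frozen=True)

    aerobic: float = Field(ge=0)
    resistance: float = Field(ge=0)

    @property
    def total(self) -> float:
        return self.aerobic + self.resistance


def trimp(plan: SessionPlan, zone_weights: Optional[dict[Zone, float]] = None) -> TrimpScore:
    """Training impulse of a combined session.

    aerobic = sum of segment minutes weighted by heart-rate zone;
    resistance = sum over exercises of sets x reps x (1RM x fraction).
    """
    if any(d <= 0 for d, _ in plan.segments):
        raise DomainError("segment durations must be positive")
    if any(rm <= 0 or not 0 < f <= 1 for rm, f in plan.loads_1rm_fraction):
        raise DomainError("1RM loads must be positive with fractions in (0, 1]")
    if not plan.segments and not plan.loads_1rm_fraction:
        log.warning("empty session plan: TRIMP is zero")
    weights = dict(DEFAULT_ZONE_WEIGHTS)
    if zone_weights:
        weights.update(zone_weights)
    aerobic = sum(duration * weights[Zone(zone)] for duration, zone in plan.segments)
    resistance = sum(
        plan.resistance_sets * plan.resistance_reps * rm * frac
        for rm, frac in plan.loads_1rm_fraction
    )
    return TrimpScore(aerobic=aerobic, resistance=resistance)


def moderate_session_plan(
    one_rms: Sequence[float] = (), fraction: float = 0.6
) -> SessionPlan:
    """The moderate-intensity bout: 18 min continuous cycling at VT1 followed
    by 2 min unloaded cycling, then 2 x 12 resistance reps at 60% 1RM."""
    return SessionPlan(
        segments=((18.0, Zone.AT_VT1), (2.0, Zone.BELOW_VT1)),
        resistance_sets=2,
        resistance_reps=12,
        loads_1rm_fraction=tuple((rm, fraction) for rm in one_rms),
    )


def high_session_plan(one_rms: Sequence[float] = (), fraction: float = 0.8) -> SessionPlan:
    """The high-intensity bout: 5 x 2 min at VT2 interspersed with 4 x 2 min
    at VT1, then 2 min de-loading, then 2 x 12 resistance reps at 80% 1RM."""
    segments: list[tuple[float, Zone]] = []
    for _ in range(4):
        segments.append((2.0, Zone.AT_VT2))
        segments.append((2.0, Zone.AT_VT1))
    segments.append((2.0, Zone.AT_VT2))
    segments.append((2.0, Zone.BELOW_VT1))
    return SessionPlan(
        segments=tuple(segments),
        resistance_sets=2,
        resistance_reps=12,
        loads_1rm_fraction=tuple((rm, fraction) for rm in one_rms),
    )


# --------------------------------------------------------------------------
# dataset helpers used by the responder stage


def baseline_value(
    data: StudyDataset, pid: str, outcome: Outcome | str, condition
) -> Optional[float]:
    m = data.measurement(pid, condition, Timepoint.PRE)
    return None if m is None else m.value(outcome)


def individual_cv(data: StudyDataset, pid: str, outcome: Outcome | str) -> Optional[float]:
    """Participant-level CV over all sessions carrying duplicate replicates of
    the outcome; ``None`` when no pair is available.

    Pairs are pooled as the root mean square of the per-pair CVs: the SD of a
    single pair underestimates sigma by sqrt(2/pi), whereas pooling variances
    keeps the estimator centred on the generating CV.
    """
    outcome = Outcome(outcome)
    if outcome not in (Outcome.CSBP, Outcome.BSBP):
        return None
    pairs = []
    for m in data.measurements_for(pid):
        r1 = getattr(m, f"{outcome.value}_rep1")
        r2 = getattr(m, f"{outcome.value}_rep2")
        if r1 is not None and r2 is not None:
            pairs.append(coefficient_of_variation(r1, r2))
    if not pairs:
        return None
    return float(math.sqrt(sum(cv**2 for cv in pairs) / len(pairs)))
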
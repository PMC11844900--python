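"""Synthetic crossover cohorts with known ground truth.

The generator emulates the study conditions: per-group baseline distributions
(CAD cSBP 101 (18), bSBP 112 (8), bDBP 70 (6) mmHg; CON cSBP 122 (18),
bSBP 122 (9), bDBP 77 (7) mmHg), multiplicative measurement noise at the
stated coefficients of variation (CAD 5%, CON 4%), and a mixture of true
response profiles per outcome: sustained post-exercise elevation, hypotension,
or a null response. A responder's true trajectory is a step function — zero at
baseline, a transient bump at 5 min, the full effect (default 10 mmHg, the
headline CAD cSBP 30-min contrast) at 15 and 30 min; null profiles carry only
the 5-min bump. Duplicate tonometry replicates are emitted per session so
individual CVs are estimable. MOD and HIGH sessions are generated
independently (no within-participant session correlation is imposed).
"""

from __future__ import annotations

import enum
import math
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .config import AnalysisConfig
from .errors import DomainError
from .model import (
    Condition,
    Group,
    Outcome,
    ParticipantRecord,
    SessionMeasurement,
    Sex,
    StudyDataset,
    Timepoint,
)
from .responder import ResponderLabel, classify_cohort


class TrueProfile(str, enum.Enum):
    SUSTAINED_ELEVATION = "SUSTAINED_ELEVATION"
    HYPOTENSIVE = "HYPOTENSIVE"
    NULL = "NULL"


#: Which responder label each true profile should elicit.
PROFILE_TO_LABEL = {
    TrueProfile.SUSTAINED_ELEVATION: ResponderLabel.HYPERTENSIVE_RESPONDER,
    TrueProfile.HYPOTENSIVE: ResponderLabel.HYPOTENSIVE_RESPONDER,
    TrueProfile.NULL: ResponderLabel.NON_RESPONDER,
}


class GroupParams(BaseModel):
    """Generator settings for one group."""

    model_config = ConfigDict(frozen=True)

    label: Group
    n: int = Field(ge=2)
    baseline_mean_csbp: float = Field(gt=0)
    baseline_sd_csbp: float = Field(gt=0)
    baseline_mean_bsbp: float = Field(gt=0)
    baseline_sd_bsbp: float = Field(gt=0)
    baseline_mean_bdbp: float = Field(gt=0)
    baseline_sd_bdbp: float = Field(gt=0)
    cv: float = Field(ge=0)
    responder_mix: dict[TrueProfile, float]
    #: mean absolute true change at 15/30 min for responder profiles, mmHg
    effect_magnitude: float = Field(default=10.0, ge=0)
    #: transient change at 5 min applied to every profile, mmHg
    transient_5min_bump: float = 0.0
    hr_mean: float = Field(default=63.0, gt=0)
    hr_sd: float = Field(default=10.0, gt=0)
    cfpwv_mean: float = Field(default=8.3, gt=0)
    cfpwv_sd: float = Field(default=1.7, gt=0)

    @model_validator(mode="after")
    def _mix_sums_to_one(self) -> "GroupParams":
        total = sum(self.responder_mix.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise DomainError(f"responder mix must sum to 1, got {total}")
        if any(v < 0 for v in self.responder_mix.values()):
            raise DomainError("responder mix proportions must be non-negative")
        return self


def default_group_params() -> dict[Group, GroupParams]:
    """Study-condition defaults: baseline distributions, CVs, sample sizes,
    and response mixtures at the reported per-group proportions (CAD: mostly
    sustained central elevations; CON: mostly central hypotensive)."""
    return {
        Group.CAD: GroupParams(
            label=Group.CAD,
            n=17,
            baseline_mean_csbp=101.0,
            baseline_sd_csbp=18.0,
            baseline_mean_bsbp=112.0,
            baseline_sd_bsbp=8.0,
            baseline_mean_bdbp=70.0,
            baseline_sd_bdbp=6.0,
            cv=0.05,
            responder_mix={
                TrueProfile.SUSTAINED_ELEVATION: 0.59,
                TrueProfile.HYPOTENSIVE: 0.12,
                TrueProfile.NULL: 0.29,
            },
            effect_magnitude=10.0,
            transient_5min_bump=16.0,
            hr_mean=62.0,
            hr_sd=11.0,
        ),
        Group.CON: GroupParams(
            label=Group.CON,
            n=18,
            baseline_mean_csbp=122.0,
            baseline_sd_csbp=18.0,
            baseline_mean_bsbp=122.0,
            baseline_sd_bsbp=9.0,
            baseline_mean_bdbp=77.0,
            baseline_sd_bdbp=7.0,
            cv=0.04,
            responder_mix={
                TrueProfile.SUSTAINED_ELEVATION: 0.14,
                TrueProfile.HYPOTENSIVE: 0.61,
                TrueProfile.NULL: 0.25,
            },
            effect_magnitude=10.0,
            transient_5min_bump=7.0,
            hr_mean=63.0,
            hr_sd=11.0,
        ),
    }


class SyntheticTruth(BaseModel):
    """Ground truth for one generated participant."""

    model_config = ConfigDict(frozen=True)

    participant_id: str
    true_label: dict[Outcome, TrueProfile]
    true_effect: dict[Outcome, float]


def _trajectory(profile: TrueProfile, effect: float, bump: float) -> dict[Timepoint, float]:
    late = effect if profile is not TrueProfile.NULL else 0.0
    return {Timepoint.PRE: 0.0, Timepoint.P5: bump, Timepoint.P15: late, Timepoint.P30: late}


def _noisy(rng: np.random.Generator, latent: float, cv: float, lower: float = 0.0) -> float:
    """One observation with SD = cv x latent, truncated below at ``lower``."""
    if cv == 0:
        return latent
    for _ in range(100):
        value = rng.normal(latent, cv * latent)
        if value > lower:
            return value
    return max(latent, lower + 1e-6)  # pathological parameters only


def generate_cohort(
    params: Optional[dict[Group, GroupParams]] = None, seed: int = 0
) -> tuple[StudyDataset, list[SyntheticTruth]]:
    """Generate one crossover dataset plus its ground-truth table.

    For every participant a latent baseline per outcome is drawn from the
    group distribution; each observed session value is
    latent + true trajectory + measurement noise (SD = cv x latent). cSBP and
    bSBP are recorded as the average of two noisy replicates, which are also
    stored so individual CVs can be estimated downstream.
    """
    params = params or default_group_params()
    rng = np.random.default_rng(seed)
    participants: list[ParticipantRecord] = []
    measurements: list[SessionMeasurement] = []
    truths: list[SyntheticTruth] = []

    for group in sorted(params, key=lambda g: g.value):
        gp = params[group]
        profiles = list(gp.responder_mix)
        probs = np.array([gp.responder_mix[p] for p in profiles])
        for i in range(gp.n):
            pid = f"{gp.label.value}{i + 1:03d}"
            participants.append(
                ParticipantRecord(
                    id=pid,
                    group=gp.label,
                    age=float(np.clip(round(rng.normal(63, 8)), 40, 90)),
                    sex=Sex.M if rng.random() < 0.78 else Sex.F,
                )
            )

            # latent baselines; redraw until physically ordered
            for _ in range(100):
                bdbp0 = rng.normal(gp.baseline_mean_bdbp, gp.baseline_sd_bdbp)
                bsbp0 = rng.normal(gp.baseline_mean_bsbp, gp.baseline_sd_bsbp)
                csbp0 = rng.normal(gp.baseline_mean_csbp, gp.baseline_sd_csbp)
                if bsbp0 > bdbp0 > 0 and csbp0 > 0:
                    break
            hr0 = max(rng.normal(gp.hr_mean, gp.hr_sd), 35.0)
            pwv0 = max(rng.normal(gp.cfpwv_mean, gp.cfpwv_sd), 3.0)

            labels: dict[Outcome, TrueProfile] = {}
            effects: dict[Outcome, float] = {}
            traj: dict[Outcome, dict[Timepoint, float]] = {}
            for outcome in (Outcome.CSBP, Outcome.BSBP):
                profile = profiles[rng.choice(len(profiles), p=probs)]
                sign = -1.0 if profile is TrueProfile.HYPOTENSIVE else 1.0
                effect = sign * gp.effect_magnitude if profile is not TrueProfile.NULL else 0.0
                labels[outcome] = profile
                effects[outcome] = effect
                traj[outcome] = _trajectory(profile, effect, gp.transient_5min_bump)
            truths.append(SyntheticTruth(participant_id=pid, true_label=labels, true_effect=effects))

            hr_traj = {Timepoint.PRE: 0.0, Timepoint.P5: 9.0, Timepoint.P15: 5.0, Timepoint.P30: 4.0}
            pwv_traj = {Timepoint.PRE: 0.0, Timepoint.P5: 0.46, Timepoint.P15: 0.1, Timepoint.P30: 0.1}

            for condition in (Condition.MOD, Condition.HIGH):
                for tp in Timepoint:
                    bdbp = _noisy(rng, bdbp0, gp.cv)
                    c1 = _noisy(rng, csbp0 + traj[Outcome.CSBP][tp], gp.cv)
                    c2 = _noisy(rng, csbp0 + traj[Outcome.CSBP][tp], gp.cv)
                    b1 = _noisy(rng, bsbp0 + traj[Outcome.BSBP][tp], gp.cv, lower=bdbp)
                    b2 = _noisy(rng, bsbp0 + traj[Outcome.BSBP][tp], gp.cv, lower=bdbp)
                    hr = _noisy(rng, hr0 + hr_traj[tp], 0.03 if gp.cv > 0 else 0.0)
                    pwv = _noisy(rng, pwv0 + pwv_traj[tp], 0.05 if gp.cv > 0 else 0.0)
                    measurements.append(
                        SessionMeasurement(
                            participant_id=pid,
                            condition=condition,
                            timepoint=tp,
                            hr=hr,
                            bsbp=(b1 + b2) / 2.0,
                            bdbp=bdbp,
                            csbp=(c1 + c2) / 2.0,
                            cfpwv=pwv,
                            csbp_rep1=c1,
                            csbp_rep2=c2,
                            bsbp_rep1=b1,
                            bsbp_rep2=b2,
                        )
                    )

    dataset = StudyDataset(
        participants=participants, measurements=measurements, provenance=f"synthetic(seed={seed})"
    )
    return dataset, truths


def truth_to_frame(truths: list[SyntheticTruth]) -> pd.DataFrame:
    rows = []
    for t in truths:
        for outcome, profile in t.true_label.items():
            rows.append(
                {
                    "participant_id": t.participant_id,
                    "outcome": outcome.value,
                    "true_label": profile.value,
                    "true_effect": t.true_effect[outcome],
                }
            )
    return pd.DataFrame(rows, columns=["participant_id", "outcome", "true_label", "true_effect"])


def recovery_experiment(
    params: Optional[dict[Group, GroupParams]] = None,
    n_reps: int = 50,
    master_seed: int = 0,
    outcome: Outcome | str = Outcome.CSBP,
    condition: Condition | str = Condition.HIGH,
    config: Optional[AnalysisConfig] = None,
) -> pd.DataFrame:
    """Generate-and-classify ``n_reps`` cohorts; tally true profile vs call.

    Returns a confusion table (rows: true profiles, columns: responder labels)
    aggregated over replicates. An empty frame for ``n_reps == 0``.
    """
    outcome = Outcome(outcome)
    condition = Condition(condition)
    profiles = [p.value for p in TrueProfile]
    labels = [l.value for l in ResponderLabel]
    table = pd.DataFrame(0, index=pd.Index(profiles, name="true"), columns=labels)
    if n_reps == 0:
        return table.iloc[0:0]
    seeds = np.random.SeedSequence(master_seed).generate_state(n_reps) % (2**31)
    for rep in range(n_reps):
        data, truths = generate_cohort(params, seed=int(seeds[rep]))
        calls = classify_cohort(data, outcome, condition, config, master_seed=int(seeds[rep]))
        truth_by_id = {t.participant_id: t.true_label[outcome] for t in truths}
        for call in calls:
            table.loc[truth_by_id[call.participant_id].value, call.label.value] += 1
    return table


def agreement_rate(table: pd.DataFrame) -> float:
    """Fraction of calls matching the label implied by the true profile."""
    total = int(table.to_numpy().sum())
    if total == 0:
        return float("nan")
    hit = sum(
        int(table.loc[profile.value, PROFILE_TO_LABEL[profile].value])
        for profile in TrueProfile
        if profile.value in table.index
    )
    return hit / total
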
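"""ROPE + HDI individual responder classification.

Each participant's post-exercise blood-pressure change (delta) is wrapped in a
measurement-error "posterior": a normal distribution centred on the observed
delta with scale TE * sqrt(2), where TE is the technical error of the
measurement (CV x individual baseline mean). From a Monte-Carlo sample of that
distribution the highest density interval (HDI, default 89%) is located as the
narrowest contiguous window of sorted draws, and the percentage of HDI draws
falling inside the region of practical equivalence (ROPE, a null band of
+/- 20% of the group baseline SD) drives the decision rule:

* > 99% of the HDI inside the ROPE   -> non-responder (change negligible)
* < 1% inside the ROPE               -> responder, hypotensive when delta < 0
                                        and hypertensive when delta > 0
* anything in between                -> undecided

This is deliberately not a full Bayesian update: the posterior is the
measurement-error distribution around the observed delta, nothing more.
"""

from __future__ import annotations

import enum
import hashlib
import logging
import math
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import stats

from .config import AnalysisConfig
from .errors import DomainError, IntegrityError
from .hemodynamics import SQRT2, individual_cv, technical_error
from .model import Condition, Outcome, StudyDataset, Timepoint

log = logging.getLogger(__name__)


class ResponderLabel(str, enum.Enum):
    HYPOTENSIVE_RESPONDER = "HYPOTENSIVE_RESPONDER"
    HYPERTENSIVE_RESPONDER = "HYPERTENSIVE_RESPONDER"
    NON_RESPONDER = "NON_RESPONDER"
    UNDECIDED = "UNDECIDED"


class RopeInterval(BaseModel):
    """Symmetric null band: +/- fraction x baseline SD."""

    model_config = ConfigDict(frozen=True)

    lower: float
    upper: float
    fraction: float
    source_sd: float

    @model_validator(mode="after")
    def _symmetric_positive(self) -> "RopeInterval":
        if not self.upper > 0 or abs(self.lower + self.upper) > 1e-9:
            raise DomainError(f"ROPE must be symmetric with positive half-width, got ({self.lower}, {self.upper})")
        return self

    def contains(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        return (x >= self.lower) & (x <= self.upper)


def rope_from_sd(baseline_sd: float, fraction: float = 0.2) -> RopeInterval:
    """Build the ROPE as +/- ``fraction`` x ``baseline_sd`` mmHg."""
    if baseline_sd <= 0:
        raise DomainError(f"baseline SD must be positive, got {baseline_sd}")
    if fraction <= 0:
        raise DomainError(f"ROPE fraction must be positive, got {fraction}")
    half = fraction * baseline_sd
    return RopeInterval(lower=-half, upper=half, fraction=fraction, source_sd=baseline_sd)


class PosteriorSpec(BaseModel):
    """Parameters of one participant's measurement-error distribution."""

    model_config = ConfigDict(frozen=True)

    location: float
    scale: float = Field(gt=0)
    n_draws: int = Field(default=1000, ge=100)
    hdi_mass: float = Field(default=0.89, gt=0, lt=1)
    seed: int = 0


class HdiInterval(BaseModel):
    model_config = ConfigDict(frozen=True)

    lower: float
    upper: float
    mass: float

    @model_validator(mode="after")
    def _ordered(self) -> "HdiInterval":
        if self.lower > self.upper:
            raise DomainError("HDI lower bound exceeds upper bound")
        return self

    @property
    def width(self) -> float:
        return self.upper - self.lower


def draw_posterior(spec: PosteriorSpec) -> np.ndarray:
    """Sorted Monte-Carlo sample from Normal(location, scale); reproducible
    for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    return np.sort(rng.normal(spec.location, spec.scale, spec.n_draws))


def hdi(sample: np.ndarray, mass: float) -> HdiInterval:
    """Highest density interval of an empirical sample.

    Among all contiguous windows of ceil(mass * n) sorted draws, the one with
    minimal width; ties resolved in favour of the lowest start index.
    """
    if not 0 < mass < 1:
        raise DomainError(f"mass must lie in (0, 1), got {mass}")
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n < 10:
        raise DomainError(f"need at least 10 draws for an HDI, got {n}")
    m = math.ceil(mass * n)
    widths = x[m - 1 :] - x[: n - m + 1]
    start = int(np.argmin(widths))  # argmin returns the first minimum
    return HdiInterval(lower=float(x[start]), upper=float(x[start + m - 1]), mass=mass)


def pct_hdi_in_rope(sample: np.ndarray, hdi_interval: HdiInterval, rope: RopeInterval) -> float:
    """Fraction of draws inside the HDI that also fall inside the ROPE."""
    x = np.asarray(sample, dtype=float)
    in_hdi = (x >= hdi_interval.lower) & (x <= hdi_interval.upper)
    n_hdi = int(in_hdi.sum())
    if n_hdi == 0:
        return 0.0
    return float((in_hdi & rope.contains(x)).sum() / n_hdi)


def pct_in_rope(sample: np.ndarray, rope: RopeInterval) -> float:
    """Fraction of all draws inside the ROPE (full-posterior sensitivity variant)."""
    x = np.asarray(sample, dtype=float)
    return float(rope.contains(x).mean())


def classify(
    pct: float,
    delta: float,
    upper_thr: float = 0.99,
    lower_thr: float = 0.01,
) -> ResponderLabel:
    """Apply the decision thresholds to the %-in-ROPE statistic.

    The undecided band is inclusive: [lower_thr, upper_thr].
    """
    if not 0 <= pct <= 1:
        raise DomainError(f"pct must lie in [0, 1], got {pct}")
    if pct > upper_thr:
        return ResponderLabel.NON_RESPONDER
    if pct < lower_thr:
        if delta == 0:
            raise IntegrityError("directionless responder: delta is exactly 0 with pct below threshold")
        return (
            ResponderLabel.HYPOTENSIVE_RESPONDER
            if delta < 0
            else ResponderLabel.HYPERTENSIVE_RESPONDER
        )
    return ResponderLabel.UNDECIDED


class ResponderCall(BaseModel):
    """Per-participant classification with its posterior summaries."""

    model_config = ConfigDict(frozen=True)

    participant_id: str
    outcome: Outcome
    condition: Condition
    delta: float
    posterior: PosteriorSpec
    hdi: HdiInterval
    pct_in_rope: float = Field(ge=0, le=1)
    label: ResponderLabel


def _participant_seed(master_seed: int, pid: str, outcome: Outcome, condition: Condition) -> int:
    """Stable per-participant seed so cohort results are order-independent."""
    digest = hashlib.sha256(
        f"{master_seed}:{pid}:{outcome.value}:{condition.value}".encode()
    ).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def group_baseline_sd(data: StudyDataset, outcome: Outcome | str, group) -> float:
    """SD (n-1) across a group's participants of each participant's PRE value
    averaged over conditions."""
    outcome = Outcome(outcome)
    values = []
    for p in data.participants:
        if p.group != group:
            continue
        pres = [
            m.value(outcome)
            for m in data.measurements_for(p.id)
            if m.timepoint == Timepoint.PRE and m.value(outcome) is not None
        ]
        if pres:
            values.append(float(np.mean(pres)))
    if len(values) < 2:
        raise DomainError(
            f"group {getattr(group, 'value', group)} has {len(values)} baseline observation(s) "
            f"for {outcome.value}; cannot form a ROPE"
        )
    return float(np.std(values, ddof=1))


def group_rope(
    data: StudyDataset, outcome: Outcome | str, group, config: Optional[AnalysisConfig] = None
) -> RopeInterval:
    """The group's ROPE for an outcome: config override if set, otherwise
    ``rope_fraction`` x the group baseline SD."""
    config = config or AnalysisConfig()
    outcome = Outcome(outcome)
    key = f"{outcome.value}:{getattr(group, 'value', group)}"
    if key in config.rope_overrides:
        half = config.rope_overrides[key]
        return RopeInterval(lower=-half, upper=half, fraction=config.rope_fraction, source_sd=half / config.rope_fraction)
    return rope_from_sd(group_baseline_sd(data, outcome, group), config.rope_fraction)


def classify_participant(
    delta: float,
    te: float,
    rope: RopeInterval,
    *,
    participant_id: str = "",
    outcome: Outcome = Outcome.CSBP,
    condition: Condition = Condition.HIGH,
    config: Optional[AnalysisConfig] = None,
    seed: int = 0,
) -> ResponderCall:
    """Run the full rule for one observed delta and technical error."""
    config = config or AnalysisConfig()
    scale = te * SQRT2
    if scale <= 0:
        raise DomainError(f"posterior scale must be positive (TE={te})")
    spec = PosteriorSpec(
        location=delta,
        scale=scale,
        n_draws=config.n_draws,
        hdi_mass=config.hdi_mass,
        seed=seed,
    )
    sample = draw_posterior(spec)
    interval = hdi(sample, config.hdi_mass)
    pct = (
        pct_hdi_in_rope(sample, interval, rope)
        if config.pct_scope == "hdi"
        else pct_in_rope(sample, rope)
    )
    label = classify(pct, delta, config.upper_threshold, config.lower_threshold)
    return ResponderCall(
        participant_id=participant_id,
        outcome=outcome,
        condition=condition,
        delta=delta,
        posterior=spec,
        hdi=interval,
        pct_in_rope=pct,
        label=label,
    )


def classify_cohort(
    data: StudyDataset,
    outcome: Outcome | str,
    condition: Condition | str,
    config: Optional[AnalysisConfig] = None,
    master_seed: int = 0,
) -> list[ResponderCall]:
    """Classify every complete participant for one outcome x condition.

    delta is the mean of the configured post-exercise changes from baseline
    (default: mean of the 15- and 30-min deltas). The technical error uses the
    group CV by default, or per-participant duplicate-measurement CVs when
    ``config.cv_source == "individual"``. The ROPE is the participant group's.

    Incomplete participants are skipped with a logged reason; a group whose
    baseline cannot support a ROPE raises :class:`DomainError`.
    """
    config = config or AnalysisConfig()
    outcome = Outcome(outcome)
    condition = Condition(condition)
    delta_tps = [Timepoint(tp) for tp in config.delta_timepoints]

    complete = data.complete_participants(outcome, condition)
    skipped = [p.id for p in data.participants if p not in complete]
    for pid in skipped:
        log.info("skipping %s: incomplete for %s/%s", pid, outcome.value, condition.value)

    ropes: dict = {}
    warned: set = set()
    z_hdi = float(stats.norm.ppf(0.5 + config.hdi_mass / 2.0))

    calls: list[ResponderCall] = []
    for p in complete:
        if p.group not in ropes:
            ropes[p.group] = group_rope(data, outcome, p.group, config)
        rope = ropes[p.group]

        pre = data.measurement(p.id, condition, Timepoint.PRE).value(outcome)
        deltas = []
        for tp in delta_tps:
            m = data.measurement(p.id, condition, tp)
            if m is not None and m.value(outcome) is not None:
                deltas.append(m.value(outcome) - pre)
        delta = float(np.mean(deltas))

        if config.cv_source == "individual":
            cv = individual_cv(data, p.id, outcome)
            if cv is None:
                log.info("skipping %s: no duplicate replicates to estimate an individual CV", p.id)
                continue
        else:
            cv = config.group_cvs[p.group.value]
        te = technical_error(cv, pre)

        # With group-level CVs the posterior half-HDI (~1.6 x TE x sqrt(2)) can
        # exceed the ROPE half-width, making >99%-in-ROPE calls unattainable.
        if p.group not in warned and te * SQRT2 * z_hdi > rope.upper:
            log.warning(
                "group %s: posterior half-HDI (~%.2f mmHg) exceeds ROPE half-width "
                "(%.2f mmHg); non-responder calls are unattainable at these CVs",
                p.group.value,
                te * SQRT2 * z_hdi,
                rope.upper,
            )
            warned.add(p.group)

        calls.append(
            classify_participant(
                delta,
                te,
                rope,
                participant_id=p.id,
                outcome=outcome,
                condition=condition,
                config=config,
                seed=_participant_seed(master_seed, p.id, outcome, condition),
            )
        )
    return calls


def calls_to_frame(calls: list[ResponderCall]):
    """Responder table: one row per call (DataFrame)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "participant_id": c.participant_id,
                "outcome": c.outcome.value,
                "condition": c.condition.value,
                "delta": c.delta,
                "hdi_lower": c.hdi.lower,
                "hdi_upper": c.hdi.upper,
                "pct_in_rope": c.pct_in_rope,
                "label": c.label.value,
            }
            for c in calls
        ],
        columns=[
            "participant_id",
            "outcome",
            "condition",
            "delta",
            "hdi_lower",
            "hdi_upper",
            "pct_in_rope",
            "label",
        ],
    )


def label_counts(calls: list[ResponderCall], data: Optional[StudyDataset] = None):
    """Per-group tallies of responder labels (DataFrame), mirroring the
    figure-style summaries."""
    import pandas as pd

    groups = {p.id: p.group.value for p in data.participants} if data is not None else {}
    rows = [
        {
            "group": groups.get(c.participant_id, ""),
            "outcome": c.outcome.value,
            "condition": c.condition.value,
            "label": c.label.value,
        }
        for c in calls
    ]
    frame = pd.DataFrame(rows, columns=["group", "outcome", "condition", "label"])
    if frame.empty:
        return pd.DataFrame(columns=["group", "outcome", "condition", "label", "n"])
    return (
        frame.groupby(["group", "outcome", "condition", "label"], sort=True)
        .size()
        .reset_index(name="n")
    )
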
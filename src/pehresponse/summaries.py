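"""Group-level descriptive and inferential summaries.

Cell means/SDs per group x condition x timepoint, marginal-mean contrasts
between timepoints (averaging each participant's change over their available
conditions, then over participants — equal to the mixed-model marginal-mean
contrast for balanced complete crossover data), Welch two-sample comparisons,
and Hedges' g (mean contrast over the pooled SD with the small-sample
correction J = 1 - 3 / (4(n1+n2) - 9)).
"""

from __future__ import annotations

import math
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict
from scipy import stats

from .errors import DomainError
from .model import Condition, Group, Outcome, StudyDataset, Timepoint


class CellSummary(BaseModel):
    model_config = ConfigDict(frozen=True)

    group: Group
    condition: Condition
    timepoint: Timepoint
    outcome: Outcome
    n: int
    mean: float
    sd: Optional[float]  # undefined (None) when n == 1


class ContrastResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    group: Group
    outcome: Outcome
    label: str
    estimate: float
    ci_lower: float
    ci_upper: float
    hedges_g: Optional[float]
    n_pairs: int


def cell_summaries(data: StudyDataset, outcome: Outcome | str) -> list[CellSummary]:
    """Mean (SD) per populated group x condition x timepoint cell."""
    outcome = Outcome(outcome)
    groups = {p.id: p.group for p in data.participants}
    rows = []
    for m in data.measurements:
        v = m.value(outcome)
        if v is not None and not math.isnan(v):
            rows.append((groups[m.participant_id], m.condition, m.timepoint, v))
    out: list[CellSummary] = []
    frame = pd.DataFrame(rows, columns=["group", "condition", "timepoint", "value"])
    if frame.empty:
        return out
    for (g, c, t), cell in frame.groupby(["group", "condition", "timepoint"], sort=True):
        values = cell["value"].to_numpy()
        out.append(
            CellSummary(
                group=g,
                condition=c,
                timepoint=t,
                outcome=outcome,
                n=len(values),
                mean=float(np.mean(values)),
                sd=float(np.std(values, ddof=1)) if len(values) > 1 else None,
            )
        )
    return out


def cells_to_frame(cells: list[CellSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": c.group.value,
                "condition": c.condition.value,
                "timepoint": c.timepoint.value,
                "outcome": c.outcome.value,
                "n": c.n,
                "mean": c.mean,
                "sd": c.sd,
            }
            for c in cells
        ],
        columns=["group", "condition", "timepoint", "outcome", "n", "mean", "sd"],
    )


def hedges_g(contrast: float, pooled_sd: float, n1: int, n2: int) -> float:
    """Standardised mean difference with the small-sample bias correction."""
    if pooled_sd <= 0:
        raise DomainError(f"pooled SD must be positive, got {pooled_sd}")
    j = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    return contrast / pooled_sd * j


def pooled_sd(sd1: float, n1: int, sd2: float, n2: int) -> float:
    """n-1 weighted pooled SD of two cells."""
    if n1 < 2 or n2 < 2:
        raise DomainError("pooled SD needs at least two observations per cell")
    return math.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))


def marginal_contrast(
    data: StudyDataset,
    outcome: Outcome | str,
    group: Group | str,
    timepoint_a: Timepoint | str,
    timepoint_b: Timepoint | str,
    label: Optional[str] = None,
) -> ContrastResult:
    """Marginal-mean contrast b - a within a group.

    Each participant's change is averaged over the conditions in which both
    timepoints are present, then averaged over participants. The 95% CI is
    t-based on those per-participant paired differences. For balanced complete
    data this equals the mixed model's marginal-mean contrast; with missing
    sessions it is a documented approximation.
    """
    outcome = Outcome(outcome)
    group = Group(group)
    tp_a = Timepoint(timepoint_a)
    tp_b = Timepoint(timepoint_b)

    diffs: list[float] = []
    vals_a: list[float] = []
    vals_b: list[float] = []
    for p in data.participants:
        if p.group != group:
            continue
        per_condition = []
        pa, pb = [], []
        for cond in Condition:
            ma = data.measurement(p.id, cond, tp_a)
            mb = data.measurement(p.id, cond, tp_b)
            va = ma.value(outcome) if ma is not None else None
            vb = mb.value(outcome) if mb is not None else None
            if va is not None and vb is not None:
                per_condition.append(vb - va)
                pa.append(va)
                pb.append(vb)
        if per_condition:
            diffs.append(float(np.mean(per_condition)))
            vals_a.append(float(np.mean(pa)))
            vals_b.append(float(np.mean(pb)))

    n = len(diffs)
    if n < 2:
        raise DomainError(f"need at least 2 complete pairs, got {n}")
    arr = np.asarray(diffs)
    estimate = float(arr.mean())
    sd = float(arr.std(ddof=1))
    halfwidth = float(stats.t.ppf(0.975, n - 1)) * sd / math.sqrt(n) if sd > 0 else 0.0

    sd_a = float(np.std(vals_a, ddof=1))
    sd_b = float(np.std(vals_b, ddof=1))
    g_val: Optional[float] = None
    if sd_a > 0 or sd_b > 0:
        sp = pooled_sd(sd_a, n, sd_b, n)
        if sp > 0:
            g_val = hedges_g(estimate, sp, n, n)

    return ContrastResult(
        group=group,
        outcome=outcome,
        label=label or f"d_{tp_b.value.lower()}-{tp_a.value.lower()}",
        estimate=estimate,
        ci_lower=estimate - halfwidth,
        ci_upper=estimate + halfwidth,
        hedges_g=g_val,
        n_pairs=n,
    )


def contrasts_to_frame(contrasts: list[ContrastResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": c.group.value,
                "outcome": c.outcome.value,
                "contrast": c.label,
                "estimate": c.estimate,
                "ci_lower": c.ci_lower,
                "ci_upper": c.ci_upper,
                "hedges_g": c.hedges_g,
                "n_pairs": c.n_pairs,
            }
            for c in contrasts
        ],
        columns=["group", "outcome", "contrast", "estimate", "ci_lower", "ci_upper", "hedges_g", "n_pairs"],
    )


class WelchResult(NamedTuple):
    difference: float
    ci_lower: float
    ci_upper: float
    t: float
    df: float
    p: float


def welch_test(sample_a, sample_b) -> WelchResult:
    """Welch's unequal-variance two-sample t-test (two-sided) with a 95% CI
    on the mean difference a - b, using the Satterthwaite-Welch df."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DomainError("each sample needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise DomainError("both samples are degenerate (zero variance)")
    se2 = va / a.size + vb / b.size
    se = math.sqrt(se2)
    df = se2**2 / (
        (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
    )
    diff = float(a.mean() - b.mean())
    t_stat = diff / se
    p = 2.0 * float(stats.t.sf(abs(t_stat), df))
    half = float(stats.t.ppf(0.975, df)) * se
    return WelchResult(diff, diff - half, diff + half, t_stat, df, p)
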
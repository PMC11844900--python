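# Methods

## Setting and data model

The pipeline targets randomized crossover trials of acute exercise with two
groups (CAD patients, controls), two session intensities (MOD, HIGH) and four
timepoints (PRE and 5/15/30 min post-exercise). Canonical storage is a long
table — one row per participant × condition × timepoint — because the
responder stage consumes per-timepoint deltas; a column-mapping entry in the
YAML config adapts spreadsheets with other headers, and numeric minute
columns (0/5/15/30) are mapped onto the fixed labels PRE/P5/P15/P30 on read.
Units are fixed (mmHg, m/s, beats/min); missing optional values are explicit
nulls, never sentinels. Validation is total: any malformed input raises a
typed error (`SchemaError`, `ParseError`, `IntegrityError`) and never yields
a partially loaded dataset.

Duplicate tonometry/oscillometry readings are averaged at ingest — the stored
`csbp`/`bsbp` are the analysis values — while the raw replicates travel in
optional `*_rep1/2` columns so that per-participant coefficients of variation
remain estimable.

## Derived hemodynamics

Carotid waveforms are calibrated from brachial diastolic and mean arterial
pressure, both taken as constant along the arterial tree. That single
assumption fixes every derived quantity: MAP = ⅔·bDBP + ⅓·bSBP;
amplification = bSBP − cSBP (sign preserved; negative amplification is
physiological in stiff arteries); bPP = bSBP − bDBP; cPP = cSBP − bDBP
(no separate central diastolic exists under the calibration);
cfPWV = k·taped distance / transit time with k = 0.8 by convention
(overridable). Heart-rate recovery is reported as HRR1 = HR_peak − HR_1min:
the positive-recovery convention, chosen so that faster recovery yields a
larger positive number, matching how group means are conventionally tabled.

TRIMP scores a combined session as zone-weighted aerobic minutes plus
resistance volume (sets × reps × 1RM × fraction, in kg·repetitions). The
zone weights (below-VT1 = 1, at-VT1 = 2, at-VT2 = 3) and the restriction to
the main aerobic segment (warm-up and cool-down excluded) were chosen so the
scoring reproduces both published session totals (38 and 48) from the
published session structures; both the weights and segment inclusion are
config-overridable, since other TRIMP variants exist.

## The ROPE + HDI responder rule

This is deliberately **not** a full Bayesian update. The "posterior" for a
participant is the measurement-error distribution around the observed change:
N(δ, TE·√2), with δ the mean of the 15- and 30-min changes from the session
baseline (per-timepoint classification is available via
`delta_timepoints`), and TE = CV × the participant's baseline mean. The √2
reflects that a delta is a difference of two error-bearing measurements.

From `n_draws` (default 1000) Monte-Carlo draws, the HDI of mass `hdi_mass`
(default 0.89) is the narrowest contiguous window of ⌈mass·n⌉ sorted draws;
ties resolve to the lowest start index, so a constant sample yields a
zero-width interval. The decision statistic is the fraction of draws *inside
the HDI* that also fall inside the ROPE (a `pct_scope="full"` switch uses
all draws instead, for sensitivity analysis). Labels: >99% in ROPE →
non-responder; <1% → responder, hypotensive or hypertensive by the sign of
δ (δ exactly 0 with pct below threshold is rejected as contradictory); the
undecided band is inclusive, [1%, 99%].

The ROPE is ±`rope_fraction` (default 0.2) × the group's baseline SD, where
the baseline SD is computed across participants from each participant's PRE
values averaged over conditions; bounds are directly overridable per
outcome × group because pooling conventions for the baseline SD differ
between reports.

**CV source.** `cv_source="group"` (default) uses fixed per-group CVs
(defaults 5% CAD, 4% CON); `"individual"` estimates each participant's CV
from duplicate replicates, pooling pairs by root mean square — the SD of a
single pair underestimates σ by √(2/π), so variances, not SDs, are averaged.
The two choices are not interchangeable: with group CVs of 4–5% on baselines
above 100 mmHg the posterior half-HDI (≈1.6·TE·√2 ≈ 11 mmHg) exceeds any
±3–4 mmHg ROPE, making non-responder calls unattainable; the classifier
logs a loud warning whenever this happens, and the synthetic harness
demonstrates it quantitatively. Individual duplicate-measurement CVs are
typically far smaller and make the full label set reachable.

Determinism: each participant's draw seed derives from a SHA-256 hash of
(master seed, participant id, outcome, condition), so cohort tables are
bit-identical across runs and independent of row order.

## Group summaries

Cell summaries are mean (SD, n−1 denominator; undefined at n = 1) per
group × condition × timepoint. The timepoint contrast within a group is a
balanced marginal mean: each participant's change is averaged over the
conditions in which both timepoints are present, then over participants,
with a t-based 95% CI on those per-participant differences. For complete
balanced crossover data this equals the REML mixed model's marginal-mean
contrast; with missing sessions it is an approximation, documented as such —
the mixed model itself (Satterthwaite df, ω², Bonferroni machinery) is out
of scope. Hedges' g divides the contrast by the n−1-weighted pooled SD of
the two cells and applies J = 1 − 3/(4(n₁+n₂)−9); Welch's test uses the
Satterthwaite–Welch df (quantiles and p-values via scipy). No multiplicity
adjustment is applied by default.

## Synthetic cohorts

The generator draws, per participant, latent baselines from the group's
normal distributions (defaults: the study conditions — CAD n = 17, cSBP
101 (18), bSBP 112 (8), bDBP 70 (6), CV 5%; CON n = 18, cSBP 122 (18),
bSBP 122 (9), bDBP 77 (7), CV 4%). True response profiles per outcome are
drawn from a configurable mixture (defaults reflect the reported pattern:
CAD mostly sustained central elevations, 0.59/0.12/0.29; CON mostly central
hypotension, 0.14/0.61/0.25). Trajectories are step functions — 0 at PRE, a
transient bump at 5 min (defaults 16 mmHg CAD, 7 mmHg CON, the reported
5-min group rises), the full effect at 15 and 30 min — because
classification pools the 15/30-min deltas; no autocorrelation model is
imposed. The default effect magnitude is 10 mmHg (the headline 30-min CAD
cSBP contrast); 5 mmHg is the smallest effect worth simulating. Measurement
noise is multiplicative-in-mean (SD = CV × latent value, truncated at zero)
to match the CV definition; two replicates per systolic measurement are
emitted and averaged. MOD and HIGH sessions are generated independently —
no within-participant session correlation is imposed, as none is reported.

What the generator does **not** emulate: physiological coupling between
cSBP and bSBP trajectories (profiles are drawn independently per outcome),
medication effects, within-participant correlation across sessions,
non-normal baseline tails, and drift in the measurement error. Passing
recovery tests therefore shows the decision rule recovers step-like truth
under Gaussian measurement error at the stated CVs — not that it is robust
to every feature of real recovery data.

## Numerical choices and problem sizes

* HDI window: ⌈mass·n⌉ draws; first-minimum tie-break; ≥10 draws required.
  The min-width estimator's edges converge slowly (≈n^(−1/3)); estimator
  tests use 4×10⁶ draws to pin the 89% normal HDI to ±1.598 within 0.02.
* Recovery experiments in the tests use small groups (5–10 participants)
  over 50–200 seeded replicates — enough for the ≥0.99/≥0.95 recovery
  margins at the configured separations while keeping the suite fast.
* Degenerate inputs: zero posterior scale, non-positive pressures,
  bSBP ≤ bDBP, single-observation ROPEs and <2 contrast pairs all raise
  `DomainError`/`IntegrityError` rather than returning NaNs.
* CSV floats are parsed with pandas' round-trip parser so write→read is
  bit-exact.

## Limitations

* The balanced marginal-mean contrast is not a mixed model; with
  substantial missingness the two diverge.
* Waveform-level processing (foot detection, intersecting tangents) is out
  of scope — transit times and calibrated pressures arrive as numbers.
* The published bSBP ROPE half-widths (±3.71, ±3.24 mmHg) are not 0.2× the
  printed baseline bSBP SDs; since the SD actually pooled is unknowable
  from the report, ROPE bounds are overridable rather than guessed.
* Group-level CVs make decisive non-responder calls impossible (see above);
  analyses of real data should prefer individual CVs when replicates exist.
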
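# Methods

`phase1pk` re-creates, as tested code, the quantitative analyses of a
first-in-human dose-escalation study of an anti-PD-1 monoclonal antibody
(mAb): noncompartmental pharmacokinetics (NCA), dose-proportionality
assessment, a preliminary population PK model with a body-weight
covariate, virtual-population exposure simulation with receptor-occupancy
(RO) margins, and the trial's operational tabulations. Because individual
patient data for such trials are not deposited, every analysis runs on a
seeded synthetic trial whose statistical structure matches what the
analyses assume; this note records the models, the defaults, and what the
synthetic results do and do not demonstrate.

## Structural PK model

Disposition is a linear two-compartment model with constant-rate IV
infusion input: central volume `V1` (L), peripheral volume `V2` (L),
inter-compartmental clearance `Q` (L/h), elimination clearance `CL`
(L/h). The central concentration is a sum of two exponentials with hybrid
rate constants `alpha > beta > 0`; derived quantities follow the standard
conventions `Vss = V1 + V2`, `Vz = CL/beta`, `t1/2 = ln 2 / beta`.

Implementation: each infusion is a step input switched on at its start
and off at its end, so a single cumulative-response function `I(t)`
(the integral of the unit-bolus response) yields both the during- and
post-infusion branches as `rate * (I(t-s) - I(t-s-T))`. A second
integral `K(t)` gives exact areas under multi-dose curves, used for
steady-state AUC windows without quadrature. When `alpha` and `beta`
approach each other (relative separation below 1e-8) evaluation switches
to the repeated-root analytic limit to avoid catastrophic cancellation;
with strictly positive parameters the discriminant is strictly positive,
so this is a numerical guard, not a reachable model state.

Internal units are hours, litres, mg (hence mg/L = ug/mL); reporting
layers convert half-life to days and clearance to L/day, matching the
mixed units of printed PK tables. Weight-based dose amounts are rounded
to 0.1 mg for reproducibility.

Steady state is detected numerically — the pre-dose trough of successive
cycles must change by less than a relative tolerance (default 1e-6,
parameterised; any value below the 0.1% detection criterion behaves
identically for reporting purposes) — rather than assumed at a fixed
cycle, which is robust when the terminal half-life is long relative to
the dosing interval. For simple tau-periodic schedules a geometric-series
closed form provides an independent cross-check and is used in tests.

## Noncompartmental analysis

AUC uses the linear-up/log-down trapezoid: linear on rising or
zero-bounded intervals, logarithmic (`dt*(C1-C2)/ln(C1/C2)`) on strictly
declining positive intervals; a partial final interval is interpolated
with its parent interval's rule. AUMC uses the matching closed forms.

The terminal slope `lambda_z` is chosen by exhaustive search over all
contiguous terminal subsets of at least three points strictly after Tmax,
maximising adjusted R^2, with ties within 1e-4 resolved toward more
points — the common industry heuristic. Fewer than three eligible points
yields a not-estimable result and all dependent parameters (AUC(0-inf),
t1/2, CL, Vz, Vss) are reported missing.

BLQ policy: pre-dose BLQ samples are set to zero, embedded BLQ samples
are excluded, trailing BLQ samples truncate the profile. Ctrough is the
sample closest to the nominal end-of-interval time within 10% of the
dosing interval. Vss uses the infusion-corrected mean residence time
(`MRT = AUMC/AUC - T_inf/2`), required for a 0.5-h infusion. An
extrapolated-AUC fraction above 20% triggers a warning but the value is
still reported. Geometric summaries report GM and GCV%
(`100*sqrt(exp(s^2)-1)`); for n <= 2 only the min–max range is shown.

## Dose proportionality

`ln(parameter)` is regressed on `ln(dose in mg/kg)` by OLS; the 90% CI
uses the t distribution with n-2 degrees of freedom; kinetics are judged
dose proportional when the CI encompasses 1. Only cycle-1 single-dose
parameters (Cmax, AUC(0-tau), AUC(0-inf)) enter, so accumulation cannot
confound the slope; subjects with a missing value drop out of that
parameter's row only.

## Population model and estimator

The population model is the two-compartment structure with log-normal
between-subject variability on all four parameters, an allometric power
of body weight on clearance (`CL_i = theta_CL (WT/70)^theta_WT exp(eta)`,
reference weight 70 kg by convention), and combined residual error
(proportional CV, default 15%, plus an additive floor of 0.05 ug/mL).

Estimation is deliberately two-stage rather than nonlinear mixed-effects:
stage 1 fits each subject by weighted nonlinear least squares on the log
scale (positivity by construction; residuals scaled by the combined error
model; besides the supplied start, five log-perturbed restarts within
+-50% with fixed sub-seeds, best objective kept); stage 2 summarises the
individual estimates — the weight exponent and typical clearance from the
regression of `ln(CL_i)` on `ln(WT_i/70)`, remaining typical values as
geometric means, `omega^2` as log-scale sample variances (clearance
residual to the weight regression), and the proportional residual
re-estimated from pooled relative residuals. With rich per-subject
sampling the two-stage estimator is consistent, and the `PopPKModel`
contract is estimator-agnostic, so an NLME backend could be swapped in
without interface changes. Initial values are self-primed from each
profile's own NCA.

Identifiability gate: a stage-1 fit whose implied terminal phase was
essentially unobserved (`beta * t_last` below one time constant) is
flagged and excluded from stage 2. On noisy profiles a few percent of
subjects otherwise collapse into a `CL -> 0`, `V2 -> infinity` optimum
that genuinely fits a flat-tailed noise realisation better than the truth
does; such estimates carry no information about elimination and would
distort the log-scale summaries. The CLI's `popfit` command relaxes the
gate (0.25) because default-trial cycle-1 data span less than one
terminal time constant — the resulting model is preliminary by
construction, and is labelled as such.

The clearance-versus-weight trend test is a two-sided t-test of the
`ln(CL)` on `ln(WT)` slope at the 0.05 level.

## Exposure simulation and RO margins

`simulate_population` draws `n` virtual subjects (weight from a truncated
log-normal, then random effects), propagates each to the steady-state
trough, and is seed-reproducible with a draw order independent of the
regimen, so matched seeds share subjects across regimens. The summary
reports the arithmetic mean trough; a t-based CI of the mean computed on
the log scale and back-transformed (exposures are log-normal); an
empirical prediction interval at the same coverage (5th–95th percentiles
at 90%); the fold-margin of the CI lower bound over the full-RO
concentration (one decimal, half-up); and a tissue-adjusted margin
dividing by a dilution factor of 3, the typical serum-to-tissue ratio for
mAbs. CI versus PI conventions are a documented package choice — the
analysis this mirrors does not define its intervals.

## Receptor occupancy

Two assay streams (CD3+ binding ratio, IL-2 stimulation ratio) are
processed identically; both are normalised so 1 is saturation. "Full RO"
means a ratio of at least 0.9 (the tolerance of 0.10 around saturation is
configurable; "full" is never quantified in such reports). Per subject
the minimum paired serum concentration among full-RO measurements is
taken; the cohort value is the arithmetic mean of per-subject minima
(matching "mean minimum concentration" wording — an alternative pooled
reading exists and is noted as ambiguous). Subjects with no full-RO
measurement are listed separately, not averaged. Anomalous-flagged
measurements are excluded; flagging is an input, not detected.

The generator's forward relation is sigmoid Emax,
`RO = C^h / (EC50^h + C^h)`, with defaults EC50 = 2.44/3 ug/mL and
h = 2 chosen so the relation reaches 0.90 exactly at 2.44 ug/mL — the
full-RO concentration scale reported for this drug class.

## Trial operations

Escalation: a dose level is safe when fewer than a third of evaluable
patients had a DLT. The 3+3 arm: 0/3 safe, 1/3 expand to 6, two DLTs
anywhere exceeded, at most 1/6 safe. The modified 6+6 arm is
under-specified in public sources; it is implemented as the <33% rule on
cohorts of at least 6 with the borderline 1/6 cohort expanded to 12 —
an interpretation, documented as such.

TEAE tables count subjects once per category (any/related/grade >= 3/
serious/withdrawal/interruption/immune-related and their related
variants) with half-up percentages to one decimal; per-term related-AE
rows are filtered at >= 10% incidence within each study part.

Responses follow immune-related RECIST confirmation: irCR/irPR (and
irPD) require a second qualifying assessment at least 28 days later
("at least 4 weeks" operationalised); irSD needs no confirmation and no
minimum duration. ORR counts confirmed irCR+irPR; DCR adds irSD. Time to
response is the first assessment of the confirmed category; duration runs
to the first subsequent irPD, else censored at the last assessment.

## Synthetic trial generator

The generator emulates the study conditions the analyses assume: five
regimens (1/3/10 mg/kg Q2W on days 1 and 15 of 28-day cycles, including
PK/PDy variants that skip the cycle-1 day-15 dose; 500 mg Q3W; 1000 mg
Q6W), 30-minute infusions, cohort sizes 3/3/3/6/6 in the escalation part
and 6/7 in the fixed-dose part (34 subjects), body weights log-normal
(median 75 kg, sigma_log 0.2) truncated to the observed 45.6–145.6 kg
span, and one ADA-positive subject (94 kg, 1 mg/kg PK/PDy cohort) whose
clearance is scaled (default 2.5x, escalated automatically until the
day-22-style concentration falls clearly below the full-RO level) and
whose occupancy EC50 is right-shifted, anchored to the subject's own
Cmax, emulating neutralising anti-drug antibodies — without the EC50
shift even a fast-clearing subject saturates the receptor at the end of
infusion, contradicting the no-full-RO phenotype being emulated.

Typical values (CL 0.2 L/day, V1 3.5 L, Q 0.03 L/h, V2 1.5 L, hence
Vss 5 L and t1/2 about 17.7 days) land in the magnitude range printed for
this mAb class; they are generator inputs, not claims about any real fit.
Between-subject variances are 0.09 on CL/Q/V2 and 0.0625 on V1 (25–30%
CV, consistent with printed GCV% ranges); the weight exponent defaults to
0.5 — a positive trend that is typically non-significant at n = 17,
matching the qualitative finding it emulates. Residual error is 15%
proportional plus a 0.05 ug/mL floor; LLOQ is 0.1 ug/mL with BLQ rows
flagged and the value withheld. Actual sample times jitter uniformly by
up to 10% of the preceding inter-sample gap, never crossing a dose time.
The default cycle-1 schedule is pre-dose, 0.5, 1, 2, 4, 8, 24, 72, 168 h
plus the cohort trough (336 h Q2W DLT-evaluable; 504 h PK/PDy and Q3W;
1008 h Q6W); the true trial's schedule is unpublished, so this is an
explicitly synthetic stand-in. AE streams draw per-term Bernoulli events
from a probability table approximating a PD-1-inhibitor safety profile
(related fatigue about a third of subjects); response streams draw
outcome categories per part (9.5% irPR / 23.8% irSD in the escalation
part) and realise them as visit sequences with confirmation gaps.

Parameter-recovery and calibration studies use a separate
estimation-grade design: single dose with washout sampling to 2352 h
(about 5.5 terminal half-lives). A 336-h cycle-1 window cannot identify
the terminal slope (alpha-phase contamination inflates it by tens of
percent), so recovery claims are made only where the design supports
them — the same reason the analysis this mirrors calls its own model
preliminary.

What passing tests show: the estimators are consistent and calibrated
*under the generator's assumptions* (linear kinetics, log-normal BSV,
the stated residual model, no dropout, no time-varying clearance, no
target-mediated disposition). They do not show that real data satisfy
those assumptions; the observed intra-individual clearance decrease over
cycles, for example, is deliberately not modelled.

## Study sizes and runtimes

Simulation studies use 200 replicates for coverage/calibration rates and
20 replicates for recovery medians (n = 17 trial-scale and n = 100
cohorts), 1000 virtual subjects for exposure simulation — sizes chosen so
Monte-Carlo error is small relative to the bands being checked while the
whole suite completes in minutes on one CPU.

## Known limitations

- Two-stage estimation understates uncertainty relative to NLME and needs
  rich per-subject data; sparse designs get a "preliminary" model only.
- The modified 6+6 expansion boundaries are an interpretation.
- The 2.44 ug/mL threshold enters the generator as a saturation scale;
  the package recomputes margins and cohort minima from data, but cannot
  re-derive the empirical threshold itself without the real assays.
- Printed fitted quantities that depend on unpublished raw data (cohort
  geometric means, slope point estimates, 51.1/29.2 ug/mL predicted
  troughs) serve as magnitude anchors only and are not reproduction
  targets of any test.
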
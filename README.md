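# phase1pk

Analysis pipeline for phase-1 dose-escalation PK/PDy studies of
monoclonal antibodies, built around the kind of first-in-human trial
that combines weight-based 3+3 escalation with fixed-dose cohorts:
noncompartmental pharmacokinetics, dose-proportionality assessment, a
preliminary population PK model with a body-weight covariate,
virtual-population exposure simulation with receptor-occupancy margins,
and the trial's clinical tabulations (DLT escalation decisions,
treatment-emergent adverse events, immune-related RECIST responses).

It is written for pharmacometricians and trial statisticians who want
these analyses as tested, reusable functions rather than one-off
scripts. Individual patient data from such trials are rarely deposited,
so the package ships a seeded synthetic-trial generator
(`phase1pk.synthetic_trial`) that emulates all four record streams — PK
profiles, RO assays, AEs, responses — with the statistical structure the
analyses assume, making every downstream stage testable end to end.

## Models and statistics

* **Kinetics** — two-compartment IV-infusion disposition with parameters
  (CL, V1, Q, V2), hybrid rates α > β > 0, Vss = V1 + V2, Vz = CL/β,
  t½ = ln2/β; closed-form superposition over arbitrary dosing schedules
  (`phase1pk.core_pk`).
* **NCA** — linear-up/log-down trapezoidal AUC and AUMC; λz by
  exhaustive adjusted-R² subset search; CL = Dose/AUC(0-∞);
  Vss = CL·(AUMC/AUC − T_inf/2); geometric mean / GCV% summaries
  (`phase1pk.nca`).
* **Dose proportionality** — power model ln(PK parameter) ~ ln(dose),
  90% t-interval on the slope, "dose proportional" iff the CI
  encompasses 1 (`phase1pk.dose_proportionality`).
* **Population PK** — CL_i = θ_CL·(WT_i/70)^θ_WT·exp(η_i), log-normal
  between-subject variability, combined residual error; two-stage
  estimation (per-subject weighted NLS, log-scale summary) and the
  0.05-level ln CL ~ ln WT trend test (`phase1pk.poppk_fit`).
* **Exposure simulation** — n virtual subjects propagated to the
  steady-state trough; log-scale t CI of the mean, empirical 90%
  prediction interval, and fold-margins of the CI lower bound over the
  serum concentration required for full PD-1 receptor occupancy,
  optionally divided by the typical threefold mAb tissue dilution
  (`phase1pk.exposure_sim`).
* **Receptor occupancy** — CD3+ binding and IL-2 stimulation ratios
  normalised to 1 at saturation; full-RO criterion (≥ 0.9), per-subject
  minimum full-RO concentration, sigmoid-Emax forward relation
  (`phase1pk.pdy_ro`).
* **Trial operations** — 3+3 and modified 6+6 escalation under the
  "< 33% DLT" rule; subject-level TEAE category tables with a ≥10%
  per-term incidence filter; irRECIST best overall response with ≥4-week
  confirmation, ORR and DCR (`phase1pk.clinical_ops`).

## Worked example

```python
from phase1pk.synthetic_trial import GeneratorConfig, generate_trial
from phase1pk.cli_io import profiles_from_dataset
from phase1pk.nca import nca_single_dose
from phase1pk.exposure_sim import fold_margin, simulate_population, summarize_exposure
from phase1pk.core_pk import q3w_fixed

trial = generate_trial(GeneratorConfig(seed=1))        # 34 subjects, 5 regimens
profile = profiles_from_dataset(trial.pk)[0]           # one cycle-1 profile
res = nca_single_dose(profile, tau=profile.nominal_trough_time)
print(f"{res.subject_id}: Cmax {res.cmax:.1f} ug/mL, "
      f"CL {res.cl_l_per_day:.3f} L/day, t1/2 {res.t_half_days:.1f} d")

model = trial.config.population_model()
troughs = simulate_population(model, q3w_fixed(500.0), n=1000, seed=1)
summary = summarize_exposure(troughs, ro_threshold=2.44)
print(f"mean steady-state Ctrough {summary.mean_ctrough:.1f} ug/mL, "
      f"fold-margin over full RO {summary.fold_margin}")
print("margin from a reported CI bound:", fold_margin(13.4, 2.44))
```

prints

```
1000mg-q6w-01: Cmax 389.3 ug/mL, CL 0.181 L/day, t1/2 12.6 d
mean steady-state Ctrough 76.5 ug/mL, fold-margin over full RO 27.4
margin from a reported CI bound: 5.5
```

The first line is one subject's noncompartmental summary (a 1000 mg Q6W
subject reaching ~389 µg/mL at end of infusion, clearing at 0.18 L/day
with a 13-day terminal half-life — mAb-typical magnitudes). The second
line is the simulated 500 mg Q3W steady-state trough distribution under
the generator's own population model: the mean trough sits far above the
2.44 µg/mL full-occupancy level. The last line applies the margin
arithmetic to a reported confidence bound: a 13.4 µg/mL lower bound is
5.5-fold the full-RO concentration.

A command-line interface mirrors the library
(`phase1pk simulate|nca|doseprop|popfit|expose|ro|clinical|report`);
`phase1pk report --seed 7 --out out/` runs the whole pipeline on one
synthetic dataset and writes CSV/YAML outputs, figures and JSON run
logs.

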
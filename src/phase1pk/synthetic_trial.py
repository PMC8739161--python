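"""Seeded generator of a phase-1-like mAb trial dataset.

Emulates the four linked record streams a dose-escalation PK/PDy
analysis consumes — concentration-time profiles, receptor-occupancy
assays, adverse events and irRECIST response assessments — for five
regimens (1/3/10 mg/kg Q2W with 28-day cycles, including a PK/PDy
variant that skips the cycle-1 day-15 dose; 500 mg Q3W; 1000 mg Q6W),
30-minute infusions, body weights spanning the observed 45.6-145.6 kg
range, log-normal between-subject variability, combined residual error,
an Emax concentration-occupancy relation, and one anti-drug-antibody
(ADA) subject with accelerated clearance.

Identical configuration and seed reproduce the dataset exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_pk import (
    DoseEvent,
    PKParameters,
    Regimen,
    conc_2cmt_infusion,
    q2w,
    q3w_fixed,
    q6w_fixed,
    single_dose,
)
from .exposure_sim import WeightDistribution
from .pdy_ro import ASSAYS, emax_ro, full_ro_concentration
from .poppk_fit import PopPKModel, ResidualErrorModel, individual_parameters

PART1 = "part1"
PART2A = "part2a"


class ConfigError(ValueError):
    """The generator configuration is internally inconsistent."""


@dataclass(frozen=True)
class CohortSpec:
    """One dose cohort: regimen, size, and its sampling skeleton.

    ``trough_time`` is the nominal end-of-interval PK sample relative to
    the first dose of the observed cycle (336 h for Q2W DLT-evaluable,
    504 h for PK/PDy and Q3W, 1008 h for Q6W); ``tau`` is the nominal
    interval used for AUC(0-tau).  ``sample_times``/``ro_times`` override
    the config-level defaults when set.
    """

    label: str
    part: str
    n: int
    regimen: Regimen
    trough_time: float
    tau: float
    sample_times: tuple[float, ...] | None = None
    ro_times: tuple[float, ...] | None = None
    observe_cycles: tuple[int, ...] = (1,)


@dataclass(frozen=True)
class SubjectSpec:
    subject_id: str
    body_weight: float
    cohort: str
    part: str
    params: PKParameters
    ro_ec50: float
    ro_hill: float
    ada_positive: bool = False


@dataclass(frozen=True)
class AETermSpec:
    term: str
    p_event: float
    p_related: float = 0.5
    p_grade3: float = 0.05
    p_serious: float = 0.05
    p_withdrawal: float = 0.01
    p_interruption: float = 0.10
    p_immune: float = 0.0


def default_cohorts() -> tuple[CohortSpec, ...]:
    """Cohort structure of the emulated study: 6/3/12 in the escalation
    part (including 3 + 6 PK/PDy subjects) and 6/7 in the fixed-dose
    part."""
    return (
        CohortSpec("1mgkg-dlt", PART1, 3, q2w(1.0), 336.0, 336.0),
        CohortSpec("1mgkg-pkpdy", PART1, 3, q2w(1.0, pk_pdy=True), 504.0, 672.0),
        CohortSpec("3mgkg-dlt", PART1, 3, q2w(3.0), 336.0, 336.0),
        CohortSpec("10mgkg-dlt", PART1, 6, q2w(10.0), 336.0, 336.0),
        CohortSpec("10mgkg-pkpdy", PART1, 6, q2w(10.0, pk_pdy=True), 504.0, 672.0),
        CohortSpec("500mg-q3w", PART2A, 6, q3w_fixed(500.0), 504.0, 504.0),
        CohortSpec("1000mg-q6w", PART2A, 7, q6w_fixed(1000.0), 1008.0, 1008.0),
    )


def default_ae_terms() -> tuple[AETermSpec, ...]:
    """Per-term event probabilities approximating the frequencies of a
    PD-1-inhibitor safety table (e.g. related fatigue in about a third
    of subjects); resemblance is statistical, not exact."""
    return (
        AETermSpec("fatigue", 0.45, p_related=0.75, p_grade3=0.05),
        AETermSpec("nausea", 0.35, p_related=0.65, p_grade3=0.02),
        AETermSpec("pruritus", 0.20, p_related=0.85),
        AETermSpec("arthralgia", 0.20, p_related=0.65),
        AETermSpec("decreased appetite", 0.20, p_related=0.65, p_grade3=0.02),
        AETermSpec("maculopapular rash", 0.15, p_related=0.85),
        AETermSpec("vomiting", 0.15, p_related=0.55, p_grade3=0.02),
        AETermSpec("anaemia", 0.20, p_related=0.30, p_grade3=0.10),
        AETermSpec("amylase increased", 0.10, p_related=0.70, p_grade3=0.10),
        AETermSpec("hypokalaemia", 0.15, p_related=0.50, p_grade3=0.05),
        AETermSpec("lipase increased", 0.08, p_related=0.70, p_grade3=0.30),
        AETermSpec("aspartate aminotransferase increased", 0.10, p_related=0.55,
                   p_grade3=0.20, p_withdrawal=0.3),
        AETermSpec("pneumonitis", 0.05, p_related=0.85, p_grade3=0.45,
                   p_serious=0.5, p_immune=0.85),
        AETermSpec("arthritis", 0.05, p_related=0.60, p_immune=0.60),
        AETermSpec("headache", 0.30, p_related=0.30),
        AETermSpec("dyspnoea", 0.25, p_related=0.20, p_grade3=0.10, p_serious=0.2),
        AETermSpec("constipation", 0.30, p_related=0.20),
        AETermSpec("pyrexia", 0.20, p_related=0.30),
        AETermSpec("abdominal pain", 0.25, p_related=0.20, p_serious=0.1),
    )


def default_response_probs() -> dict[str, dict[str, float]]:
    # remainder of the probability mass is progressive disease
    return {
        PART1: {"irPR": 0.095, "irSD": 0.238},
        PART2A: {"irPR": 0.0, "irSD": 0.154},
    }


def default_visit_days() -> dict[str, tuple[float, ...]]:
    # escalation part scans every 10 weeks; fixed-dose part first scan at
    # 12 weeks then every 6 weeks
    return {
        PART1: (70.0, 140.0, 210.0, 280.0),
        PART2A: (84.0, 126.0, 168.0, 210.0),
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic trial, with study-condition defaults.

    Typical values are chosen to land in the magnitude range of a mAb
    with linear kinetics (CL about 0.2 L/day, Vss about 5 L, terminal
    half-life two to three weeks); they are generator inputs, not claims
    about any fitted model.
    """

    seed: int = 0
    cohorts: tuple[CohortSpec, ...] = field(default_factory=default_cohorts)
    typical: PKParameters = field(
        default_factory=lambda: PKParameters(cl=0.2 / 24.0, v1=3.5, q=0.03, v2=1.5)
    )
    theta_wt: float = 0.5
    ref_weight: float = 70.0
    omega2: Mapping[str, float] = field(
        default_factory=lambda: {"cl": 0.09, "v1": 0.0625, "q": 0.09, "v2": 0.09}
    )
    residual_prop_cv: float = 0.15
    residual_add_sd: float = 0.05
    lloq: float = 0.1
    sample_times: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 24.0, 72.0, 168.0)
    time_jitter_frac: float = 0.10
    weight_distribution: WeightDistribution = field(default_factory=WeightDistribution)
    # receptor occupancy
    ro_times: tuple[float, ...] = (0.5, 24.0, 168.0)
    ro_washout_times: tuple[float, ...] = ()
    ro_ec50: float = 2.44 / 3.0
    ro_hill: float = 2.0
    ro_ec50_sd_log: float = 0.10
    ro_assay_sd: float = 0.02
    ro_anomalous_prob: float = 0.02
    # anti-drug-antibody subject
    ada_cohort: str | None = "1mgkg-pkpdy"
    ada_subject_index: int = 0
    ada_weight: float = 94.0
    ada_clearance_multiplier: float = 2.5
    ada_ec50_multiplier: float = 12.0
    # clinical streams
    ae_terms: tuple[AETermSpec, ...] = field(default_factory=default_ae_terms)
    response_probs: Mapping[str, Mapping[str, float]] = field(
        default_factory=default_response_probs
    )
    visit_days: Mapping[str, tuple[float, ...]] = field(default_factory=default_visit_days)

    def __post_init__(self) -> None:
        for k, v in self.omega2.items():
            if v < 0:
                raise ConfigError(f"omega2[{k}] must be >= 0")
        for p in (self.ro_anomalous_prob,):
            if not 0 <= p <= 1:
                raise ConfigError("probabilities must be in [0, 1]")
        if self.residual_prop_cv < 0 or self.residual_add_sd < 0:
            raise ConfigError("residual error terms must be >= 0")
        for cohort in self.cohorts:
            times = cohort.sample_times or self.sample_times
            if min(times) < 0:
                raise ConfigError(
                    f"cohort {cohort.label!r} schedules a sample before the first dose"
                )

    @property
    def full_ro_conc(self) -> float:
        """Concentration at which the generator's Emax relation reaches
        full occupancy (value 0.90 for the default tolerance)."""
        return full_ro_concentration(self.ro_ec50, self.ro_hill, tolerance=0.10)

    def population_model(self) -> PopPKModel:
        return PopPKModel(
            theta=self.typical,
            theta_wt=self.theta_wt,
            ref_weight=self.ref_weight,
            omega2=dict(self.omega2),
            residual=ResidualErrorModel(self.residual_prop_cv, self.residual_add_sd),
        )


@dataclass
class TrialRecordSet:
    """The joined synthetic streams, keyed by subject id."""

    subjects: list[SubjectSpec]
    pk: pd.DataFrame
    ro: pd.DataFrame
    ae: pd.DataFrame
    response: pd.DataFrame
    config: GeneratorConfig

    def rosters(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s in self.subjects:
            out.setdefault(s.cohort, []).append(s.subject_id)
        return out

    def parts(self) -> dict[str, str]:
        return {c.label: c.part for c in self.config.cohorts}


def make_ada_subject(
    spec: SubjectSpec,
    multiplier: float,
    ec50_multiplier: float = 1.0,
) -> SubjectSpec:
    """Accelerate a subject's clearance by ``multiplier`` (>= 1), marking
    them ADA-positive.

    ``ec50_multiplier`` additionally right-shifts the subject's
    occupancy EC50, emulating neutralising anti-drug antibodies so that
    no sampled concentration reaches full RO.
    """
    if multiplier < 1:
        raise ConfigError("ADA clearance multiplier must be >= 1")
    if multiplier == 1 and ec50_multiplier == 1:
        return spec
    return replace(
        spec,
        params=replace(spec.params, cl=spec.params.cl * multiplier),
        ro_ec50=spec.ro_ec50 * ec50_multiplier,
        ada_positive=True,
    )


def _choose_ada_multiplier(
    config: GeneratorConfig, spec: SubjectSpec, regimen: Regimen, check_time: float
) -> float:
    """Smallest multiplier from the configured start (escalated by 1.3x)
    whose day-22-style concentration falls clearly below the full-RO
    threshold, mirroring the observed ADA subject."""
    target = 0.65 * config.full_ro_conc
    mult = config.ada_clearance_multiplier
    amount = regimen.dose_amount(spec.body_weight)
    for _ in range(20):
        params = replace(spec.params, cl=spec.params.cl * mult)
        conc = conc_2cmt_infusion(
            params, [DoseEvent(0.0, amount, regimen.infusion_duration)], check_time
        )
        if conc < target:
            return mult
        mult *= 1.3
    return mult


def _draw_subjects(config: GeneratorConfig, rng: np.random.Generator) -> list[SubjectSpec]:
    model = config.population_model()
    subjects: list[SubjectSpec] = []
    for cohort in config.cohorts:
        weights = config.weight_distribution.sample(rng, cohort.n)
        for i in range(cohort.n):
            etas = {
                k: float(rng.normal(0.0, math.sqrt(config.omega2.get(k, 0.0))))
                for k in ("cl", "v1", "q", "v2")
            }
            weight = float(weights[i])
            is_ada = (
                config.ada_cohort == cohort.label and i == config.ada_subject_index
            )
            if is_ada:
                weight = config.ada_weight
            params = individual_parameters(model, weight, etas)
            ec50 = config.ro_ec50 * float(
                np.exp(rng.normal(0.0, config.ro_ec50_sd_log))
            )
            spec = SubjectSpec(
                subject_id=f"{cohort.label}-{i + 1:02d}",
                body_weight=weight,
                cohort=cohort.label,
                part=cohort.part,
                params=params,
                ro_ec50=ec50,
                ro_hill=config.ro_hill,
            )
            if is_ada:
                mult = _choose_ada_multiplier(
                    config, spec, cohort.regimen, cohort.trough_time
                )
                # neutralising antibodies right-shift the occupancy EC50;
                # the shift is anchored to the subject's own peak so that
                # even the end-of-infusion sample stays short of full RO
                params_ada = replace(spec.params, cl=spec.params.cl * mult)
                amount = cohort.regimen.dose_amount(weight)
                cmax = conc_2cmt_infusion(
                    params_ada,
                    [DoseEvent(0.0, amount, cohort.regimen.infusion_duration)],
                    cohort.regimen.infusion_duration,
                )
                needed = 1.5 * cmax / full_ro_concentration(ec50, config.ro_hill)
                spec = make_ada_subject(
                    spec, mult,
                    ec50_multiplier=max(config.ada_ec50_multiplier, needed),
                )
            subjects.append(spec)
    return subjects


def _jitter_times(
    nominal: np.ndarray,
    dose_times: np.ndarray,
    frac: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Actual sample times: nominal plus up to +-frac of the preceding
    gap, never reordered and never crossing a dose time."""
    actual = nominal.astype(float).copy()
    for i in range(1, nominal.size):
        gap = nominal[i] - nominal[i - 1]
        jit = rng.uniform(-frac, frac) * gap
        t = nominal[i] + jit
        # a sample scheduled at a dose time stays on its pre-dose side
        if np.any(np.isclose(nominal[i], dose_times)):
            t = nominal[i] - abs(jit)
        lo = actual[i - 1] + 1e-6
        hi = nominal[i] + frac * gap
        nxt = dose_times[dose_times > nominal[i] + 1e-9]
        if nxt.size:
            hi = min(hi, float(nxt.min()) - 1e-6)
        actual[i] = float(np.clip(t, lo, max(hi, lo)))
    return actual


def _pk_and_ro_rows(
    config: GeneratorConfig,
    cohort: CohortSpec,
    subject: SubjectSpec,
    rng: np.random.Generator,
) -> tuple[list[dict], list[dict]]:
    regimen = cohort.regimen
    sample_times = np.asarray(cohort.sample_times or config.sample_times, float)
    pk_rows: list[dict] = []
    ro_rows: list[dict] = []
    amount = regimen.dose_amount(subject.body_weight)
    emitted_dose_times: set[float] = set()

    for cyc in cohort.observe_cycles:
        start = (cyc - 1) * regimen.cycle_length
        nominal = np.unique(
            np.concatenate([start + sample_times, [start + cohort.trough_time]])
        )
        # administered doses: everything scheduled before the last sample
        schedule = regimen.dose_events(cyc + 1, weight=subject.body_weight)
        doses = [d for d in schedule if d.start_time < nominal[-1] - 1e-9]
        # jitter constraints use the full schedule so a trough that sits
        # at the next dose time can only move to its pre-dose side
        schedule_times = np.array([d.start_time for d in schedule])
        actual = _jitter_times(nominal, schedule_times, config.time_jitter_frac, rng)
        true_conc = np.asarray(
            conc_2cmt_infusion(subject.params, doses, actual), dtype=float
        )
        eps_p = rng.normal(0.0, 1.0, size=actual.size)
        eps_a = rng.normal(0.0, 1.0, size=actual.size)
        obs = np.clip(
            true_conc * (1.0 + config.residual_prop_cv * eps_p)
            + config.residual_add_sd * eps_a,
            0.0,
            None,
        )
        blq = obs < config.lloq
        for d in doses:
            if d.start_time not in emitted_dose_times:
                emitted_dose_times.add(d.start_time)
                pk_rows.append(
                    {
                        "ID": subject.subject_id,
                        "TIME": d.start_time,
                        "NTIME": d.start_time,
                        "AMT": amount,
                        "RATE": d.rate,
                        "DV": np.nan,
                        "EVID": 1,
                        "BLQ": 0,
                        "WT": subject.body_weight,
                        "COHORT": subject.cohort,
                        "PART": subject.part,
                    }
                )
        for i in range(actual.size):
            pk_rows.append(
                {
                    "ID": subject.subject_id,
                    "TIME": float(actual[i]),
                    "NTIME": float(nominal[i]),
                    "AMT": np.nan,
                    "RATE": np.nan,
                    "DV": np.nan if blq[i] else float(obs[i]),
                    "EVID": 0,
                    "BLQ": int(blq[i]),
                    "WT": subject.body_weight,
                    "COHORT": subject.cohort,
                    "PART": subject.part,
                }
            )

        ro_nominal = np.unique(
            np.concatenate(
                [
                    start + np.asarray(cohort.ro_times or config.ro_times, float),
                    [start + cohort.trough_time],
                    start + np.asarray(config.ro_washout_times, float),
                ]
            )
        )
        ro_conc_true = np.asarray(
            conc_2cmt_infusion(subject.params, doses, ro_nominal), dtype=float
        )
        paired = np.clip(
            ro_conc_true * (1.0 + config.residual_prop_cv * rng.normal(size=ro_nominal.size))
            + config.residual_add_sd * rng.normal(size=ro_nominal.size),
            0.0,
            None,
        )
        for i, t_ro in enumerate(ro_nominal):
            for assay in ASSAYS:
                value = float(
                    emax_ro(ro_conc_true[i], subject.ro_ec50, subject.ro_hill)
                    + rng.normal(0.0, config.ro_assay_sd)
                )
                anomalous = bool(rng.random() < config.ro_anomalous_prob)
                if anomalous:
                    value *= float(rng.uniform(0.2, 0.6))
                ro_rows.append(
                    {
                        "ID": subject.subject_id,
                        "TIME": float(t_ro),
                        "ASSAY": assay,
                        "VALUE": max(value, 0.0),
                        "CONC": float(paired[i]),
                        "ANOMALOUS": int(anomalous),
                        "COHORT": subject.cohort,
                        "PART": subject.part,
                    }
                )
    return pk_rows, ro_rows


def _ae_rows(
    config: GeneratorConfig, subject: SubjectSpec, rng: np.random.Generator
) -> list[dict]:
    rows = []
    for term in config.ae_terms:
        if rng.random() >= term.p_event:
            continue
        grade = 3 if rng.random() < term.p_grade3 else int(rng.integers(1, 3))
        rows.append(
            {
                "ID": subject.subject_id,
                "TERM": term.term,
                "GRADE": grade,
                "RELATED": int(rng.random() < term.p_related),
                "SERIOUS": int(grade >= 3 and rng.random() < term.p_serious * 4),
                "WITHDRAWAL": int(grade >= 3 and rng.random() < term.p_withdrawal * 4),
                "INTERRUPTION": int(rng.random() < term.p_interruption),
                "IMMUNE": int(rng.random() < term.p_immune),
                "COHORT": subject.cohort,
                "PART": subject.part,
            }
        )
    return rows


def _response_rows(
    config: GeneratorConfig, subject: SubjectSpec, rng: np.random.Generator
) -> list[dict]:
    probs = config.response_probs.get(subject.part, {})
    u = rng.random()
    p_pr = probs.get("irPR", 0.0)
    p_sd = probs.get("irSD", 0.0)
    visits = config.visit_days.get(subject.part, (70.0, 140.0, 210.0, 280.0))
    if u < p_pr:
        cats = ["irSD", "irPR", "irPR", "irPD"]
    elif u < p_pr + p_sd:
        cats = ["irSD", "irSD", "irPD"]
    else:
        cats = ["irPD", "irPD"]
    rows = []
    for day, cat in zip(visits, cats):
        rows.append(
            {
                "ID": subject.subject_id,
                "DAY": float(day),
                "CATEGORY": cat,
                "COHORT": subject.cohort,
                "PART": subject.part,
            }
        )
    return rows


#: single-dose schedule extending past three terminal half-lives, for
#: estimation-grade profiles (reliable lambda_z and individual fits)
RICH_WASHOUT_TIMES = (
    0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 24.0, 72.0, 168.0,
    336.0, 504.0, 672.0, 1008.0, 1344.0, 1680.0, 2016.0, 2352.0,
)


def estimation_study_config(
    n_subjects: int,
    seed: int = 0,
    doses_mg_per_kg: Sequence[float] = (1.0, 3.0, 10.0),
    theta_wt: float = 0.5,
    residual_prop_cv: float = 0.15,
    omega2: Mapping[str, float] | None = None,
    sample_times: tuple[float, ...] = RICH_WASHOUT_TIMES,
) -> GeneratorConfig:
    """A single-dose, washout-extended study for parameter recovery.

    ``n_subjects`` are spread as evenly as possible over the dose
    levels; every profile follows the rich washout schedule so both NCA
    and individual two-compartment fits are well determined.  No ADA
    subject is inserted.
    """
    base = n_subjects // len(doses_mg_per_kg)
    extra = n_subjects % len(doses_mg_per_kg)
    cohorts = []
    for i, dose in enumerate(doses_mg_per_kg):
        n = base + (1 if i < extra else 0)
        if n == 0:
            continue
        cohorts.append(
            CohortSpec(
                label=f"{dose:g}mgkg-rich",
                part=PART1,
                n=n,
                regimen=single_dose(dose, per_kg=True),
                trough_time=336.0,
                tau=336.0,
                sample_times=sample_times,
            )
        )
    kwargs = dict(
        seed=seed,
        cohorts=tuple(cohorts),
        theta_wt=theta_wt,
        residual_prop_cv=residual_prop_cv,
        ada_cohort=None,
    )
    if omega2 is not None:
        kwargs["omega2"] = dict(omega2)
    return GeneratorConfig(**kwargs)


PK_COLUMNS = ["ID", "TIME", "NTIME", "AMT", "RATE", "DV", "EVID", "BLQ", "WT", "COHORT", "PART"]
RO_COLUMNS = ["ID", "TIME", "ASSAY", "VALUE", "CONC", "ANOMALOUS", "COHORT", "PART"]
AE_COLUMNS = ["ID", "TERM", "GRADE", "RELATED", "SERIOUS", "WITHDRAWAL", "INTERRUPTION", "IMMUNE", "COHORT", "PART"]
RESPONSE_COLUMNS = ["ID", "DAY", "CATEGORY", "COHORT", "PART"]


def generate_trial(config: GeneratorConfig) -> TrialRecordSet:
    """Generate the four linked record streams for the configured trial.

    Randomness is split into independent sub-streams (subjects, PK/RO,
    AEs, responses) spawned from the configured seed, so the streams are
    individually reproducible.
    """
    root = np.random.default_rng(config.seed)
    rng_subj, rng_pk, rng_ae, rng_resp = root.spawn(4)
    subjects = _draw_subjects(config, rng_subj)
    cohort_by_label = {c.label: c for c in config.cohorts}

    pk_rows: list[dict] = []
    ro_rows: list[dict] = []
    ae_rows: list[dict] = []
    resp_rows: list[dict] = []
    for subject in subjects:
        cohort = cohort_by_label[subject.cohort]
        pk, ro = _pk_and_ro_rows(config, cohort, subject, rng_pk)
        pk_rows.extend(pk)
        ro_rows.extend(ro)
        ae_rows.extend(_ae_rows(config, subject, rng_ae))
        resp_rows.extend(_response_rows(config, subject, rng_resp))

    pk = pd.DataFrame(pk_rows, columns=PK_COLUMNS).sort_values(
        ["ID", "TIME", "EVID"], kind="stable", ignore_index=True
    )
    return TrialRecordSet(
        subjects=subjects,
        pk=pk,
        ro=pd.DataFrame(ro_rows, columns=RO_COLUMNS),
        ae=pd.DataFrame(ae_rows, columns=AE_COLUMNS),
        response=pd.DataFrame(resp_rows, columns=RESPONSE_COLUMNS),
        config=config,
    )
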
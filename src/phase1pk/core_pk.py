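"""Closed-form two-compartment IV-infusion kinetics with dose superposition.

This is the shared forward model of the package.  Drug is infused at a
constant rate into a central compartment (volume ``V1``) that exchanges
with a peripheral compartment (``V2``) via inter-compartmental clearance
``Q`` and is eliminated from the central compartment with clearance
``CL``.  The disposition is a sum of two exponentials with hybrid rate
constants ``alpha > beta > 0``; the terminal half-life is ``ln 2 / beta``.

All internal times are hours, volumes litres, clearances L/h and amounts
mg, so concentrations come out in mg/L == ug/mL.  Reporting layers
convert half-life to days and clearance to L/day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

LN2 = math.log(2.0)

#: relative alpha/beta separation below which the repeated-root limit is used
DEGENERATE_RTOL = 1e-8


class InvalidParameterError(ValueError):
    """A pharmacokinetic parameter violates its positivity constraint."""


@dataclass(frozen=True)
class PKParameters:
    """Micro-constant parameterisation of the two-compartment model.

    Parameters
    ----------
    cl : float
        Elimination clearance from the central compartment, L/h.
    v1 : float
        Central volume of distribution, L.
    q : float
        Inter-compartmental clearance, L/h.
    v2 : float
        Peripheral volume of distribution, L.
    """

    cl: float
    v1: float
    q: float
    v2: float

    def __post_init__(self) -> None:
        for name in ("cl", "v1", "q", "v2"):
            value = getattr(self, name)
            if not (np.isfinite(value) and value > 0):
                raise InvalidParameterError(
                    f"{name} must be strictly positive and finite, got {value!r}"
                )

    @property
    def vss(self) -> float:
        """Volume of distribution at steady state, ``V1 + V2`` (L)."""
        return self.v1 + self.v2

    def as_array(self) -> np.ndarray:
        return np.array([self.cl, self.v1, self.q, self.v2], dtype=float)

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "PKParameters":
        cl, v1, q, v2 = (float(v) for v in x)
        return cls(cl, v1, q, v2)


@dataclass(frozen=True)
class DoseEvent:
    """A single constant-rate IV infusion.

    ``start_time`` in hours, ``amount`` in mg, ``infusion_duration`` in
    hours (default 0.5 h, i.e. a 30-minute infusion).
    """

    start_time: float
    amount: float
    infusion_duration: float = 0.5

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise InvalidParameterError(f"dose amount must be > 0, got {self.amount}")
        if self.infusion_duration <= 0:
            raise InvalidParameterError(
                f"infusion duration must be > 0, got {self.infusion_duration}"
            )

    @property
    def rate(self) -> float:
        return self.amount / self.infusion_duration


def _hybrid_rates(params: PKParameters) -> tuple[float, float, float]:
    """Return ``(alpha, beta, k21)`` for the two-compartment model."""
    k10 = params.cl / params.v1
    k12 = params.q / params.v1
    k21 = params.q / params.v2
    s = k10 + k12 + k21
    disc = s * s - 4.0 * k10 * k21
    root = math.sqrt(max(disc, 0.0))
    alpha = 0.5 * (s + root)
    # product identity alpha*beta = k10*k21 is numerically stabler than
    # the subtractive root when the discriminant is small
    beta = k10 * k21 / alpha
    return alpha, beta, k21


def macro_constants(params: PKParameters) -> tuple[float, float, float, float]:
    """Convert micro constants to the macro form ``(alpha, beta, A, B)``.

    ``A`` and ``B`` are the unit-dose bolus intercepts (ug/mL per mg):
    after an instantaneous 1-mg dose the central concentration is
    ``A exp(-alpha t) + B exp(-beta t)``.  Identities
    ``alpha*beta = (CL/V1)(Q/V2)`` and
    ``alpha+beta = CL/V1 + Q/V1 + Q/V2`` hold by construction.
    """
    alpha, beta, k21 = _hybrid_rates(params)
    denom = params.v1 * (alpha - beta)
    if alpha - beta <= DEGENERATE_RTOL * alpha:
        # repeated root: macro intercepts are not individually defined;
        # evaluation routines switch to the analytic limit instead
        lam = 0.5 * (alpha + beta)
        return lam, lam, math.inf, math.inf
    a = (alpha - k21) / denom
    b = (k21 - beta) / denom
    return alpha, beta, a, b


def _is_degenerate(alpha: float, beta: float) -> bool:
    return (alpha - beta) <= DEGENERATE_RTOL * alpha


def _unit_cumulative(params: PKParameters, t: np.ndarray) -> np.ndarray:
    """``I(t) = int_0^t c_bolus(u) du`` for a unit (1 mg) bolus; I(t<=0)=0."""
    alpha, beta, k21 = _hybrid_rates(params)
    tc = np.clip(t, 0.0, None)
    if _is_degenerate(alpha, beta):
        lam = 0.5 * (alpha + beta)
        e = np.exp(-lam * tc)
        j1 = (1.0 - e * (1.0 + lam * tc)) / lam**2
        return ((1.0 - e) / lam - (lam - k21) * j1) / params.v1
    denom = params.v1 * (alpha - beta)
    a = (alpha - k21) / denom
    b = (k21 - beta) / denom
    return a / alpha * (1.0 - np.exp(-alpha * tc)) + b / beta * (
        1.0 - np.exp(-beta * tc)
    )


def _unit_double_cumulative(params: PKParameters, t: np.ndarray) -> np.ndarray:
    """``K(t) = int_0^t I(u) du`` for a unit bolus; K(t<=0)=0."""
    alpha, beta, k21 = _hybrid_rates(params)
    tc = np.clip(t, 0.0, None)
    if _is_degenerate(alpha, beta):
        lam = 0.5 * (alpha + beta)
        e = np.exp(-lam * tc)
        j1 = (1.0 - e * (1.0 + lam * tc)) / lam**2
        j2 = tc / lam**2 - (1.0 - e) / lam**3 - j1 / lam
        return (tc / lam - (1.0 - e) / lam**2 - (lam - k21) * j2) / params.v1
    denom = params.v1 * (alpha - beta)
    a = (alpha - k21) / denom
    b = (k21 - beta) / denom
    return a / alpha * (tc - (1.0 - np.exp(-alpha * tc)) / alpha) + b / beta * (
        tc - (1.0 - np.exp(-beta * tc)) / beta
    )


def conc_2cmt_infusion(
    params: PKParameters, doses: Iterable[DoseEvent], t: float | np.ndarray
):
    """Central-compartment concentration (ug/mL) at time(s) ``t``.

    Each infusion is represented as a step input switched on at its start
    and off at its end, so during- and post-infusion branches come from a
    single expression ``rate * (I(t - s) - I(t - s - T))`` and the curve
    is continuous everywhere, including at infusion ends.  Contributions
    of multiple doses superpose linearly.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    out = np.zeros_like(t_arr)
    for dose in doses:
        rel = t_arr - dose.start_time
        out = out + dose.rate * (
            _unit_cumulative(params, rel)
            - _unit_cumulative(params, rel - dose.infusion_duration)
        )
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(out)
    return out


def auc_2cmt_infusion(
    params: PKParameters, doses: Iterable[DoseEvent], t_start: float, t_end: float
) -> float:
    """Exact area under the model curve between ``t_start`` and ``t_end``."""
    if t_end < t_start or t_start < 0:
        raise ValueError("require 0 <= t_start <= t_end")
    total = 0.0
    for dose in doses:
        r1 = t_start - dose.start_time
        r2 = t_end - dose.start_time
        total += dose.rate * (
            _unit_double_cumulative(params, np.asarray(r2))
            - _unit_double_cumulative(params, np.asarray(r1))
            - _unit_double_cumulative(params, np.asarray(r2 - dose.infusion_duration))
            + _unit_double_cumulative(params, np.asarray(r1 - dose.infusion_duration))
        )
    return float(total)


@dataclass(frozen=True)
class Regimen:
    """A cyclic dosing schedule.

    ``dose`` is mg when ``per_kg`` is False, otherwise mg/kg (the amount
    administered is rounded to 0.1 mg).  ``dose_offsets`` are the dosing
    times (h) within each cycle of length ``cycle_length`` (h).  A
    distinct first cycle (e.g. the PK/PDy variant that skips the day-15
    dose of cycle 1) is expressed through ``first_cycle_offsets``.
    """

    label: str
    dose: float
    per_kg: bool
    cycle_length: float
    dose_offsets: tuple[float, ...]
    first_cycle_offsets: tuple[float, ...] | None = None
    infusion_duration: float = 0.5

    def __post_init__(self) -> None:
        if self.cycle_length <= 0:
            raise InvalidParameterError("cycle_length must be > 0")
        if not self.dose_offsets:
            raise InvalidParameterError("regimen needs at least one dose per cycle")
        if any(o < 0 or o >= self.cycle_length for o in self.dose_offsets):
            raise InvalidParameterError("dose offsets must lie within the cycle")

    @property
    def tau(self) -> float:
        """Mean dosing interval (h) of the repeating cycle."""
        return self.cycle_length / len(self.dose_offsets)

    def dose_amount(self, weight: float | None = None) -> float:
        if not self.per_kg:
            return self.dose
        if weight is None:
            raise ValueError(f"regimen {self.label!r} is weight-based; weight required")
        return round(self.dose * weight, 1)

    def offsets_for_cycle(self, cycle: int) -> tuple[float, ...]:
        if cycle == 1 and self.first_cycle_offsets is not None:
            return self.first_cycle_offsets
        return self.dose_offsets

    def dose_events(
        self, n_cycles: int, weight: float | None = None
    ) -> list[DoseEvent]:
        amount = self.dose_amount(weight)
        events = []
        for cycle in range(1, n_cycles + 1):
            start = (cycle - 1) * self.cycle_length
            for off in self.offsets_for_cycle(cycle):
                events.append(DoseEvent(start + off, amount, self.infusion_duration))
        return events


def q2w(dose_mg_per_kg: float, pk_pdy: bool = False) -> Regimen:
    """Weight-based Q2W dosing on days 1 and 15 of a 28-day cycle.

    The PK/PDy variant omits the day-15 dose of cycle 1 only.
    """
    suffix = " PK/PDy" if pk_pdy else ""
    return Regimen(
        label=f"{dose_mg_per_kg:g} mg/kg Q2W{suffix}",
        dose=dose_mg_per_kg,
        per_kg=True,
        cycle_length=672.0,
        dose_offsets=(0.0, 336.0),
        first_cycle_offsets=(0.0,) if pk_pdy else None,
    )


def q3w_fixed(amount_mg: float = 500.0) -> Regimen:
    return Regimen(
        label=f"{amount_mg:g} mg Q3W",
        dose=amount_mg,
        per_kg=False,
        cycle_length=504.0,
        dose_offsets=(0.0,),
    )


def q6w_fixed(amount_mg: float = 1000.0) -> Regimen:
    return Regimen(
        label=f"{amount_mg:g} mg Q6W",
        dose=amount_mg,
        per_kg=False,
        cycle_length=1008.0,
        dose_offsets=(0.0,),
    )


def single_dose(dose: float, per_kg: bool = True, label: str | None = None) -> Regimen:
    """A one-off administration (washout follows), encoded as a very long cycle."""
    return Regimen(
        label=label or ("single %g %s" % (dose, "mg/kg" if per_kg else "mg")),
        dose=dose,
        per_kg=per_kg,
        cycle_length=1e6,
        dose_offsets=(0.0,),
    )


class ConvergenceError(RuntimeError):
    """The multiple-dose profile failed to approach steady state."""


def steady_state_ctrough(
    params: PKParameters,
    regimen: Regimen,
    weight: float | None = None,
    rel_tol: float = 1e-6,
    max_cycles: int = 5000,
) -> float:
    """Pre-dose trough concentration at steady state (ug/mL).

    Cycles are appended one at a time; the trough is evaluated
    immediately before the first dose of each new cycle (the incoming
    dose contributes nothing at its own start time) and iteration stops
    once the successive-cycle relative change falls below ``rel_tol``.
    """
    alpha, beta, _ = _hybrid_rates(params)
    if beta <= 0:
        raise ConvergenceError("non-positive terminal rate constant")
    doses: list[DoseEvent] = []
    prev = None
    for cycle in range(1, max_cycles + 1):
        doses.extend(
            DoseEvent(
                (cycle - 1) * regimen.cycle_length + off,
                regimen.dose_amount(weight),
                regimen.infusion_duration,
            )
            for off in regimen.offsets_for_cycle(cycle)
        )
        t_next = cycle * regimen.cycle_length + regimen.dose_offsets[0]
        trough = conc_2cmt_infusion(params, doses, t_next)
        if prev is not None and abs(trough - prev) <= rel_tol * max(trough, 1e-300):
            return trough
        prev = trough
    raise ConvergenceError(
        f"trough did not converge within {max_cycles} cycles of {regimen.label!r}"
    )


def steady_state_ctrough_closed_form(
    params: PKParameters,
    amount: float,
    tau: float,
    infusion_duration: float = 0.5,
) -> float:
    """Geometric-series accumulation trough for simple tau-periodic dosing.

    For a post-infusion observer, each past dose aged ``k*tau`` contributes
    ``G_a exp(-alpha k tau) + G_b exp(-beta k tau)``; summing the geometric
    series over all past doses gives the steady-state pre-dose trough.
    """
    alpha, beta, k21 = _hybrid_rates(params)
    if _is_degenerate(alpha, beta):
        # fall back to numeric accumulation for the measure-zero repeated root
        reg = Regimen("tmp", amount, False, tau, (0.0,), infusion_duration=infusion_duration)
        return steady_state_ctrough(params, reg, rel_tol=1e-10)
    denom = params.v1 * (alpha - beta)
    a = (alpha - k21) / denom
    b = (k21 - beta) / denom
    rate = amount / infusion_duration
    g_a = rate * a / alpha * (math.exp(alpha * infusion_duration) - 1.0)
    g_b = rate * b / beta * (math.exp(beta * infusion_duration) - 1.0)
    ea = math.exp(-alpha * tau)
    eb = math.exp(-beta * tau)
    return g_a * ea / (1.0 - ea) + g_b * eb / (1.0 - eb)


def steady_state_auc(
    params: PKParameters,
    regimen: Regimen,
    window: float,
    weight: float | None = None,
    rel_tol: float = 1e-6,
    max_cycles: int = 5000,
) -> float:
    """AUC (ug.h/mL) over a ``window``-hour span starting at a steady-state
    cycle boundary.

    Steady state is detected by the successive-trough criterion; the area
    is then evaluated analytically over ``[t0, t0 + window]`` where ``t0``
    is the start of the first converged cycle, with enough further cycles
    appended to cover the window.
    """
    doses: list[DoseEvent] = []
    prev = None
    converged_cycle = None
    for cycle in range(1, max_cycles + 1):
        doses.extend(
            DoseEvent(
                (cycle - 1) * regimen.cycle_length + off,
                regimen.dose_amount(weight),
                regimen.infusion_duration,
            )
            for off in regimen.offsets_for_cycle(cycle)
        )
        t_next = cycle * regimen.cycle_length
        trough = conc_2cmt_infusion(params, doses, t_next)
        if prev is not None and abs(trough - prev) <= rel_tol * max(trough, 1e-300):
            converged_cycle = cycle
            break
        prev = trough
    if converged_cycle is None:
        raise ConvergenceError("no steady state within max_cycles")
    t0 = converged_cycle * regimen.cycle_length
    n_extra = int(math.ceil(window / regimen.cycle_length)) + 1
    for cycle in range(converged_cycle + 1, converged_cycle + 1 + n_extra):
        doses.extend(
            DoseEvent(
                (cycle - 1) * regimen.cycle_length + off,
                regimen.dose_amount(weight),
                regimen.infusion_duration,
            )
            for off in regimen.offsets_for_cycle(cycle)
        )
    return auc_2cmt_infusion(params, doses, t0, t0 + window)
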
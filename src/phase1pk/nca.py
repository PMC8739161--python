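"""Noncompartmental analysis of single-dose concentration-time profiles.

Implements the standard parameter set for an IV-infusion mAb study:
observed Cmax/Tmax/Ctrough, linear-up/log-down trapezoidal AUC and AUMC,
terminal-slope (lambda_z) estimation by exhaustive adjusted-R^2 subset
search, clearance and volume terms, plus geometric cohort summaries and
multiple-dose accumulation ratios.

BLQ policy: pre-dose BLQ observations are set to zero, BLQ samples
embedded between quantifiable ones are excluded, and trailing BLQ
samples truncate the profile at the last quantifiable point.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_pk import LN2


class NCAError(ValueError):
    """Profile cannot support the requested noncompartmental computation."""


@dataclass(frozen=True)
class ConcentrationProfile:
    """One subject's single-dose segment.

    ``times`` are hours after the dose start; ``concentrations`` are
    ug/mL with ``blq`` marking below-limit-of-quantification samples
    (whose concentration value is ignored).  ``nominal_trough_time`` is
    the scheduled end-of-interval sample (e.g. 336 h for Q2W
    DLT-evaluable subjects, 504 h for PK/PDy and Q3W, 1008 h for Q6W).
    """

    subject_id: str
    dose: float
    times: tuple[float, ...]
    concentrations: tuple[float, ...]
    blq: tuple[bool, ...]
    infusion_duration: float = 0.5
    nominal_trough_time: float | None = None
    body_weight: float | None = None
    cohort: str | None = None

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.concentrations) == len(self.blq) == n):
            raise NCAError("times, concentrations and blq must have equal length")
        t = np.asarray(self.times, dtype=float)
        if n >= 2 and np.any(np.diff(t) <= 0):
            raise NCAError(f"times must be strictly increasing for {self.subject_id}")
        if self.dose <= 0:
            raise NCAError("dose must be positive")
        if not any(ti > 0 for ti in self.times):
            raise NCAError("profile needs at least one post-dose sample")

    def quantifiable(self) -> tuple[np.ndarray, np.ndarray]:
        """Times and concentrations after applying the BLQ policy."""
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        b = np.asarray(self.blq, dtype=bool)
        c = np.where(b & (t <= 0), 0.0, c)
        keep = ~b | (t <= 0)
        t, c, b = t[keep], c[keep], b[keep]
        quant = np.flatnonzero(c > 0)
        if quant.size == 0:
            raise NCAError(f"no quantifiable post-dose samples for {self.subject_id}")
        last = quant[-1]
        return t[: last + 1], c[: last + 1]


@dataclass(frozen=True)
class LambdaZFit:
    lambda_z: float
    points_used: int
    adj_r_squared: float
    t_first: float


@dataclass(frozen=True)
class NCAResult:
    subject_id: str
    dose: float
    cmax: float
    tmax: float
    ctrough: float | None
    auc_0_last: float
    auc_0_tau: float | None
    auc_0_inf: float | None
    aumc_0_inf: float | None
    lambda_z: float | None
    lambda_z_points: int | None
    lambda_z_adj_r2: float | None
    t_half_days: float | None
    cl_l_per_day: float | None
    vz_l: float | None
    vss_l: float | None
    extrapolated_fraction: float | None
    body_weight: float | None = None
    cohort: str | None = None


@dataclass(frozen=True)
class GeoSummary:
    """Geometric mean / GCV% summary; for n <= 2 only min-max are shown."""

    n: int
    geometric_mean: float | None
    gcv_pct: float | None
    minimum: float
    maximum: float


def _interval_is_log(c1: float, c2: float) -> bool:
    return c1 > c2 > 0


def _segment_areas(t1: float, c1: float, t2: float, c2: float) -> tuple[float, float]:
    """(AUC, AUMC) over one interval with the linear-up/log-down rule."""
    dt = t2 - t1
    if _interval_is_log(c1, c2):
        k = math.log(c1 / c2) / dt
        auc = (c1 - c2) / k
        aumc = (t1 * c1 - t2 * c2) / k + (c1 - c2) / k**2
    else:
        auc = dt * (c1 + c2) / 2.0
        aumc = dt * (t1 * c1 + t2 * c2) / 2.0
    return auc, aumc


def _interp_conc(t1: float, c1: float, t2: float, c2: float, t: float) -> float:
    """Interpolate consistently with the interval's trapezoid rule."""
    f = (t - t1) / (t2 - t1)
    if _interval_is_log(c1, c2):
        return c1 * (c2 / c1) ** f
    return c1 + f * (c2 - c1)


def auc_lin_up_log_down(
    times: Sequence[float],
    concs: Sequence[float],
    t_end: float | None = None,
    moment: int = 0,
) -> float:
    """Trapezoidal AUC (``moment=0``) or AUMC (``moment=1``) to ``t_end``.

    Linear trapezoid on rising or zero-bounded intervals, logarithmic
    trapezoid on strictly declining positive intervals.  ``t_end`` may cut
    the final interval; the partial segment is interpolated with the same
    rule as its parent interval.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    if t.size < 2:
        raise NCAError("need at least two points for a trapezoidal area")
    if np.any(np.diff(t) <= 0):
        raise NCAError("times must be strictly increasing")
    if t_end is None:
        t_end = float(t[-1])
    if t_end > t[-1] + 1e-12:
        raise NCAError("t_end beyond last sample; use the infinity extrapolation")
    if t_end <= t[0]:
        return 0.0
    total = 0.0
    for i in range(t.size - 1):
        t1, t2 = float(t[i]), float(t[i + 1])
        c1, c2 = float(c[i]), float(c[i + 1])
        if t_end >= t2:
            seg = _segment_areas(t1, c1, t2, c2)
            total += seg[moment]
        else:
            if t_end > t1:
                cm = _interp_conc(t1, c1, t2, c2, t_end)
                seg = _segment_areas(t1, c1, t_end, cm)
                total += seg[moment]
            break
    return total


def _adj_r2(t: np.ndarray, logc: np.ndarray) -> tuple[float, float]:
    """Slope and adjusted R^2 of the log-linear least-squares fit."""
    n = t.size
    slope, intercept = np.polyfit(t, logc, 1)
    resid = logc - (slope * t + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((logc - logc.mean()) ** 2).sum())
    if ss_tot <= 0:
        r2 = 1.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return float(slope), float(adj)


def lambda_z_fit(
    profile: ConcentrationProfile, tie_tol: float = 1e-4
) -> LambdaZFit | None:
    """Terminal-slope estimate by exhaustive contiguous-subset search.

    All contiguous terminal subsets of >= 3 points strictly after Tmax
    (Tmax itself excluded) are fit by log-linear least squares; the subset
    with maximal adjusted R^2 wins, with ties within ``tie_tol`` resolved
    in favour of more points.  Returns ``None`` when no subset yields a
    positive terminal rate constant (the not-estimable case).
    """
    t, c = profile.quantifiable()
    imax = int(np.argmax(c))
    cand_idx = np.flatnonzero((np.arange(t.size) > imax) & (c > 0))
    if cand_idx.size < 3:
        return None
    best: tuple[float, int, float, float] | None = None  # adj, n, lz, tfirst
    for start in range(cand_idx.size - 2):
        idx = cand_idx[start:]
        slope, adj = _adj_r2(t[idx], np.log(c[idx]))
        lz = -slope
        if lz <= 0:
            continue
        if best is None or adj > best[0] + tie_tol:
            best = (adj, idx.size, lz, float(t[idx[0]]))
        elif abs(adj - best[0]) <= tie_tol and idx.size > best[1]:
            best = (adj, idx.size, lz, float(t[idx[0]]))
    if best is None:
        return None
    adj, n_pts, lz, t_first = best
    return LambdaZFit(lambda_z=lz, points_used=n_pts, adj_r_squared=adj, t_first=t_first)


def find_ctrough(
    profile: ConcentrationProfile, tau: float, window_frac: float = 0.10
) -> float | None:
    """Observed concentration at the nominal trough time.

    The actual sample closest to ``nominal_trough_time`` and within
    ``window_frac`` of the dosing interval is reported; otherwise the
    trough is missing.
    """
    if profile.nominal_trough_time is None:
        return None
    t, c = profile.quantifiable()
    dt = np.abs(t - profile.nominal_trough_time)
    i = int(np.argmin(dt))
    if dt[i] <= window_frac * tau:
        return float(c[i])
    return None


def nca_single_dose(
    profile: ConcentrationProfile,
    tau: float,
    extrapolation_warn_fraction: float = 0.20,
) -> NCAResult:
    """Full single-dose NCA parameter set for one profile.

    ``tau`` is the nominal dosing interval (h) used for the AUC(0-tau)
    partial area (truncated to the last sample when sampling stops
    short).  Terminal-phase parameters are reported missing when
    lambda_z is not estimable.
    """
    t, c = profile.quantifiable()
    post = t > 0
    cmax = float(np.max(c[post]))
    tmax = float(t[post][np.argmax(c[post])])
    # integration starts at the first retained sample (a pre-dose zero
    # when present, otherwise the first quantifiable observation)
    t0, c0 = t, c
    auc_last = auc_lin_up_log_down(t0, c0)
    aumc_last = auc_lin_up_log_down(t0, c0, moment=1)
    auc_tau = auc_lin_up_log_down(t0, c0, t_end=min(tau, float(t0[-1])))
    ctrough = find_ctrough(profile, tau)

    lz_fit = lambda_z_fit(profile)
    if lz_fit is None:
        return NCAResult(
            subject_id=profile.subject_id,
            dose=profile.dose,
            cmax=cmax,
            tmax=tmax,
            ctrough=ctrough,
            auc_0_last=auc_last,
            auc_0_tau=auc_tau,
            auc_0_inf=None,
            aumc_0_inf=None,
            lambda_z=None,
            lambda_z_points=None,
            lambda_z_adj_r2=None,
            t_half_days=None,
            cl_l_per_day=None,
            vz_l=None,
            vss_l=None,
            extrapolated_fraction=None,
            body_weight=profile.body_weight,
            cohort=profile.cohort,
        )

    lz = lz_fit.lambda_z
    c_last, t_last = float(c0[-1]), float(t0[-1])
    auc_inf = auc_last + c_last / lz
    aumc_inf = aumc_last + c_last * t_last / lz + c_last / lz**2
    extrap = 1.0 - auc_last / auc_inf
    if extrap > extrapolation_warn_fraction:
        warnings.warn(
            f"{profile.subject_id}: extrapolated AUC fraction {extrap:.1%} exceeds "
            f"{extrapolation_warn_fraction:.0%}; AUC(0-inf) is reported but uncertain",
            stacklevel=2,
        )
    cl_h = profile.dose / auc_inf
    mrt = aumc_inf / auc_inf - profile.infusion_duration / 2.0
    return NCAResult(
        subject_id=profile.subject_id,
        dose=profile.dose,
        cmax=cmax,
        tmax=tmax,
        ctrough=ctrough,
        auc_0_last=auc_last,
        auc_0_tau=auc_tau,
        auc_0_inf=auc_inf,
        aumc_0_inf=aumc_inf,
        lambda_z=lz,
        lambda_z_points=lz_fit.points_used,
        lambda_z_adj_r2=lz_fit.adj_r_squared,
        t_half_days=LN2 / lz / 24.0,
        cl_l_per_day=cl_h * 24.0,
        vz_l=cl_h / lz,
        vss_l=cl_h * mrt,
        extrapolated_fraction=extrap,
        body_weight=profile.body_weight,
        cohort=profile.cohort,
    )


@dataclass(frozen=True)
class AccumulationRatio:
    auc_tau_pct: float | None
    cmax_pct: float | None


def accumulation_ratio(
    result_cycle_n: NCAResult, result_cycle_1: NCAResult
) -> AccumulationRatio:
    """Multiple-dose / single-dose exposure ratio in percent."""
    if result_cycle_n.subject_id != result_cycle_1.subject_id:
        raise NCAError("accumulation ratio requires matching subjects")

    def ratio(num: float | None, den: float | None) -> float | None:
        if num is None or den is None or den == 0:
            return None
        return 100.0 * num / den

    return AccumulationRatio(
        auc_tau_pct=ratio(result_cycle_n.auc_0_tau, result_cycle_1.auc_0_tau),
        cmax_pct=ratio(result_cycle_n.cmax, result_cycle_1.cmax),
    )


def geo_stats(values: Sequence[float]) -> GeoSummary:
    """Geometric mean and GCV% (``100 sqrt(exp(s^2) - 1)``).

    Follows the reporting convention that for n <= 2 only the min-max
    range is presented.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise NCAError("no values to summarise")
    if np.any(x <= 0):
        raise NCAError("geometric statistics require strictly positive values")
    if x.size <= 2:
        return GeoSummary(
            n=int(x.size),
            geometric_mean=None,
            gcv_pct=None,
            minimum=float(x.min()),
            maximum=float(x.max()),
        )
    logs = np.log(x)
    gm = float(np.exp(logs.mean()))
    s2 = float(np.var(logs, ddof=1))
    return GeoSummary(
        n=int(x.size),
        geometric_mean=gm,
        gcv_pct=100.0 * math.sqrt(math.exp(s2) - 1.0),
        minimum=float(x.min()),
        maximum=float(x.max()),
    )


#: NCAResult attributes summarised in cohort tables, with display units
TABLE_PARAMETERS = (
    ("auc_0_inf", "AUC(0-inf) (ug.h/mL)"),
    ("auc_0_tau", "AUC(0-tau) (ug.h/mL)"),
    ("cmax", "Cmax (ug/mL)"),
    ("ctrough", "Ctrough (ug/mL)"),
    ("t_half_days", "t1/2 (d)"),
    ("cl_l_per_day", "CL (L/d)"),
    ("vz_l", "Vz (L)"),
    ("vss_l", "Vss (L)"),
)


def cohort_summary(results_by_cohort: dict[str, Sequence[NCAResult]]):
    """Long-format cohort summary table of geometric statistics.

    Returns a pandas DataFrame with one row per (cohort, parameter):
    n, geometric mean, GCV%, min, max.  Missing individual values are
    dropped before summarising, mirroring per-parameter n in printed
    tables.
    """
    import pandas as pd

    rows = []
    for cohort, results in results_by_cohort.items():
        for attr, label in TABLE_PARAMETERS:
            vals = [getattr(r, attr) for r in results]
            vals = [v for v in vals if v is not None and v > 0]
            if not vals:
                continue
            g = geo_stats(vals)
            rows.append(
                {
                    "cohort": cohort,
                    "parameter": label,
                    "n": g.n,
                    "geometric_mean": g.geometric_mean,
                    "gcv_pct": g.gcv_pct,
                    "min": g.minimum,
                    "max": g.maximum,
                }
            )
    return pd.DataFrame(rows)
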
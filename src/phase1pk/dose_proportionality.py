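"""Power-model assessment of dose proportionality.

``ln(parameter)`` is regressed on ``ln(dose)``; pharmacokinetics are dose
proportional when the confidence interval for the slope encompasses one.
Doses are on the mg/kg scale for weight-based cohorts, and only cycle-1
single-dose parameters (Cmax, AUC(0-tau), AUC(0-inf)) are assessed, so
accumulation cannot confound the slope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .nca import NCAResult


@dataclass(frozen=True)
class DosePropResult:
    parameter: str
    n: int
    slope: float
    standard_error: float
    ci_low: float
    ci_high: float
    proportional: bool


def encompasses_one(ci_low: float, ci_high: float) -> bool:
    """The proportionality verdict rule: slope CI contains 1."""
    return ci_low <= 1.0 <= ci_high


def power_model_fit(
    doses: Sequence[float],
    values: Sequence[float],
    confidence: float = 0.90,
    parameter: str = "",
) -> DosePropResult:
    """OLS fit of ``ln(value) ~ ln(dose)`` with a t-based slope CI.

    Requires at least three subjects at two or more distinct dose
    levels and strictly positive doses and values.
    """
    d = np.asarray(doses, dtype=float)
    v = np.asarray(values, dtype=float)
    if d.size != v.size:
        raise ValueError("doses and values must align")
    if d.size < 3:
        raise ValueError("need at least 3 subjects for the power model")
    if np.any(d <= 0) or np.any(v <= 0):
        raise ValueError("doses and values must be strictly positive")
    if np.unique(d).size < 2:
        raise ValueError("slope is unidentifiable with a single dose level")
    X = sm.add_constant(np.log(d))
    fit = sm.OLS(np.log(v), X).fit()
    slope = float(fit.params[1])
    se = float(fit.bse[1])
    ci = fit.conf_int(alpha=1.0 - confidence)
    low, high = float(ci[1][0]), float(ci[1][1])
    return DosePropResult(
        parameter=parameter,
        n=int(d.size),
        slope=slope,
        standard_error=se,
        ci_low=low,
        ci_high=high,
        proportional=encompasses_one(low, high),
    )


#: cycle-1 parameters assessed for proportionality
DEFAULT_PARAMETERS = ("cmax", "auc_0_tau", "auc_0_inf")


def proportionality_table(
    results: Sequence[NCAResult],
    doses_mg_per_kg: Sequence[float],
    parameters: Sequence[str] = DEFAULT_PARAMETERS,
    confidence: float = 0.90,
) -> list[DosePropResult]:
    """Slope/CI/verdict rows for each PK parameter, excluding subjects
    with a missing value of that parameter (e.g. a non-estimable
    lambda_z drops the subject from the AUC(0-inf) row only)."""
    out = []
    for param in parameters:
        pairs = [
            (d, getattr(r, param))
            for d, r in zip(doses_mg_per_kg, results, strict=True)
            if getattr(r, param) is not None
        ]
        if len(pairs) < 3:
            continue
        d, v = zip(*pairs)
        out.append(power_model_fit(d, v, confidence=confidence, parameter=param))
    return out
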
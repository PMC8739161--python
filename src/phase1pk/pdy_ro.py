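"""PD-1 receptor-occupancy analytics.

Two ex vivo assay streams are supported with identical logic: a CD3+
binding ratio and an IL-2 stimulation ratio, each normalised so that a
value of 1 reflects saturation of the receptor (full RO).  The module
computes the full-RO flag, each subject's minimum serum concentration at
which full RO was seen, the cohort mean of those minima, and the Emax
concentration-response relation used by the synthetic generator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

CD3_BINDING = "cd3_binding"
IL2_STIMULATION = "il2_stimulation"
ASSAYS = (CD3_BINDING, IL2_STIMULATION)


@dataclass(frozen=True)
class ROMeasurement:
    subject_id: str
    time: float
    assay: str
    value: float
    concentration: float | None = None
    anomalous: bool = False

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("RO ratio must be non-negative")
        if self.concentration is not None and self.concentration < 0:
            raise ValueError("paired concentration must be non-negative")


def is_full_ro(m: ROMeasurement, tolerance: float = 0.10) -> bool:
    """True when the assay ratio is within ``tolerance`` of saturation (1)."""
    return m.value >= 1.0 - tolerance


@dataclass(frozen=True)
class ROSummary:
    assay: str
    per_subject_min: dict[str, float]
    cohort_mean: float | None
    non_achievers: tuple[str, ...]

    @property
    def n_achievers(self) -> int:
        return len(self.per_subject_min)


def min_full_ro_concentration(
    measurements: Iterable[ROMeasurement],
    tolerance: float = 0.10,
    assay: str | None = None,
) -> ROSummary:
    """Per-subject minimum full-RO concentration and its cohort mean.

    For each subject the lowest paired serum concentration among full-RO
    measurements is taken; subjects with no full-RO measurement are
    excluded from the mean and listed separately.  Anomalous-flagged
    measurements and measurements without a paired concentration are
    ignored.  The cohort mean is the arithmetic mean of per-subject
    minima.
    """
    by_subject: dict[str, list[ROMeasurement]] = {}
    for m in measurements:
        if assay is not None and m.assay != assay:
            continue
        by_subject.setdefault(m.subject_id, []).append(m)
    minima: dict[str, float] = {}
    non_achievers: list[str] = []
    for subject, ms in by_subject.items():
        usable = [
            m
            for m in ms
            if not m.anomalous and m.concentration is not None and is_full_ro(m, tolerance)
        ]
        if usable:
            minima[subject] = min(m.concentration for m in usable)  # type: ignore[type-var]
        else:
            non_achievers.append(subject)
    if not minima:
        warnings.warn("no subject achieved full RO; empty summary", stacklevel=2)
        mean = None
    else:
        mean = float(np.mean(list(minima.values())))
    return ROSummary(
        assay=assay or "all",
        per_subject_min=minima,
        cohort_mean=mean,
        non_achievers=tuple(sorted(non_achievers)),
    )


def summarize_by_assay(
    measurements: Sequence[ROMeasurement], tolerance: float = 0.10
) -> dict[str, ROSummary]:
    return {
        assay: min_full_ro_concentration(measurements, tolerance=tolerance, assay=assay)
        for assay in ASSAYS
    }


def emax_ro(concentration, ec50: float, hill: float = 1.0):
    """Sigmoid Emax occupancy: ``C^h / (EC50^h + C^h)``, bounded in [0, 1)."""
    if ec50 <= 0 or hill <= 0:
        raise ValueError("EC50 and hill must be positive")
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    ch = np.power(c, hill)
    out = ch / (ec50**hill + ch)
    if np.ndim(concentration) == 0:
        return float(out)
    return out


def full_ro_concentration(ec50: float, hill: float, tolerance: float = 0.10) -> float:
    """Concentration at which the Emax relation first reaches full RO,
    i.e. the inverse of ``emax_ro`` at ``1 - tolerance``."""
    target = 1.0 - tolerance
    return ec50 * (target / (1.0 - target)) ** (1.0 / hill)
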
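"""Trial-logic computations: dose escalation, AE summaries, responses.

Covers the three operational analyses of a phase-1 oncology study:

* dose-limiting-toxicity (DLT) escalation decisions under a 3+3 design
  and a modified 6+6 design, both built on the "safe if < 33% of
  evaluable patients experienced DLT" rule;
* treatment-emergent adverse-event (TEAE) tabulation with subject-level
  category counts and a per-term related-AE table filtered at a 10%
  incidence cutoff within each study part;
* immune-related RECIST (irRECIST) best-overall-response derivation with
  the >= 4-week confirmation requirement, and ORR/DCR rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .rounding import percent

# ---------------------------------------------------------------------------
# dose escalation

THREE_PLUS_THREE = "three_plus_three"
SIX_PLUS_SIX = "six_plus_six"

SAFE = "safe"
EXPAND = "expand"
EXCEEDED = "exceeded"


@dataclass(frozen=True)
class EscalationDecision:
    dose_level: str
    n_evaluable: int
    n_dlt: int
    decision: str


def dlt_decision(
    n_dlt: int,
    n_evaluable: int,
    design: str = THREE_PLUS_THREE,
    dose_level: str = "",
) -> EscalationDecision:
    """Escalation decision for a completed DLT-evaluation cohort.

    3+3: 0/3 safe; 1/3 expand to 6; >= 2 DLT at any point exceeded;
    <= 1/6 safe.  Modified 6+6: a level is safe when fewer than a third
    of evaluable patients had a DLT, with the borderline 1/6 cohort
    expanded to 12 before a final verdict.
    """
    if not 0 <= n_dlt <= n_evaluable:
        raise ValueError("require 0 <= n_dlt <= n_evaluable")
    if design == THREE_PLUS_THREE:
        if n_evaluable < 3:
            raise ValueError("3+3 cohorts have at least 3 evaluable patients")
        if n_dlt >= 2:
            decision = EXCEEDED
        elif n_evaluable >= 6:
            decision = SAFE  # 0 or 1 DLT among >= 6
        elif n_evaluable == 3 and n_dlt == 0:
            decision = SAFE
        else:
            decision = EXPAND  # 1/3, or an incomplete expansion with <= 1 DLT
    elif design == SIX_PLUS_SIX:
        if n_evaluable < 6:
            raise ValueError("6+6 cohorts have at least 6 evaluable patients")
        if n_dlt / n_evaluable >= 1.0 / 3.0:
            decision = EXCEEDED
        elif n_evaluable == 6 and n_dlt == 1:
            decision = EXPAND  # borderline: expand to 12
        else:
            decision = SAFE
    else:
        raise ValueError(f"unknown design {design!r}")
    return EscalationDecision(
        dose_level=dose_level, n_evaluable=n_evaluable, n_dlt=n_dlt, decision=decision
    )


# ---------------------------------------------------------------------------
# adverse events


@dataclass(frozen=True)
class AdverseEventRecord:
    subject_id: str
    term: str
    grade: int
    related: bool = False
    serious: bool = False
    led_to_withdrawal: bool = False
    led_to_interruption: bool = False
    immune_related: bool = False

    def __post_init__(self) -> None:
        if self.grade not in (1, 2, 3, 4, 5):
            raise ValueError(f"grade must be 1-5, got {self.grade}")


#: (label, predicate) pairs defining the category rows of the TEAE table
AE_CATEGORIES: tuple[tuple[str, object], ...] = (
    ("any_ae", lambda r: True),
    ("related_ae", lambda r: r.related),
    ("grade_ge3_ae", lambda r: r.grade >= 3),
    ("related_grade_ge3_ae", lambda r: r.related and r.grade >= 3),
    ("serious_ae", lambda r: r.serious),
    ("related_serious_ae", lambda r: r.related and r.serious),
    ("ae_leading_to_withdrawal", lambda r: r.led_to_withdrawal),
    ("related_ae_leading_to_withdrawal", lambda r: r.related and r.led_to_withdrawal),
    ("ae_leading_to_interruption", lambda r: r.led_to_interruption),
    ("immune_related_ae", lambda r: r.immune_related),
)


def summarize_aes(
    records: Iterable[AdverseEventRecord],
    rosters: Mapping[str, Sequence[str]],
    parts: Mapping[str, str] | None = None,
    term_incidence_cutoff: float = 0.10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """TEAE summary tables.

    ``rosters`` maps each dose group to its full subject list (so
    subjects without any AE contribute to denominators); ``parts``
    optionally maps groups to study parts, adding per-part and overall
    pooled columns.  Returns ``(categories, related_terms)``:

    * ``categories`` - one row per (category, group) with subject-level
      count ``n`` and percentage ``pct`` (half-up, 1 decimal); a subject
      with several qualifying events counts once per category.
    * ``related_terms`` - per-preferred-term counts of related AEs,
      restricted to terms whose related-AE incidence reaches the cutoff
      within the group's study part.
    """
    roster_sets = {g: set(s) for g, s in rosters.items()}
    for g, s in rosters.items():
        if len(roster_sets[g]) != len(s):
            raise ValueError(f"duplicate subject in roster {g!r}")
    subject_group: dict[str, str] = {}
    for g, subjects in roster_sets.items():
        for s in subjects:
            if s in subject_group:
                raise ValueError(f"subject {s!r} appears in several rosters")
            subject_group[s] = g
    records = list(records)
    for r in records:
        if r.subject_id not in subject_group:
            raise ValueError(f"subject {r.subject_id!r} not on any roster")

    parts = dict(parts or {})
    pools: dict[str, set[str]] = {g: set(s) for g, s in roster_sets.items()}
    if parts:
        for g, part in parts.items():
            pools.setdefault(f"{part}_total", set()).update(roster_sets[g])
    pools["overall"] = set(subject_group)

    cat_rows = []
    for label, pred in AE_CATEGORIES:
        hit = {r.subject_id for r in records if pred(r)}
        for pool_name, members in pools.items():
            n = len(hit & members)
            cat_rows.append(
                {
                    "category": label,
                    "group": pool_name,
                    "n": n,
                    "n_subjects": len(members),
                    "pct": percent(n, len(members)),
                }
            )
    categories = pd.DataFrame(cat_rows)

    # per-term related-AE incidence, filtered within each study part
    term_rows = []
    part_pools = {name: m for name, m in pools.items() if name.endswith("_total")}
    if not part_pools:
        part_pools = {"overall": pools["overall"]}
    terms = sorted({r.term for r in records if r.related})
    for term in terms:
        hit = {r.subject_id for r in records if r.related and r.term == term}
        keep = any(
            len(hit & members) / len(members) >= term_incidence_cutoff
            for members in part_pools.values()
            if members
        )
        if not keep:
            continue
        for pool_name, members in pools.items():
            n = len(hit & members)
            term_rows.append(
                {
                    "term": term,
                    "group": pool_name,
                    "n": n,
                    "n_subjects": len(members),
                    "pct": percent(n, len(members)),
                }
            )
    related_terms = pd.DataFrame(
        term_rows, columns=["term", "group", "n", "n_subjects", "pct"]
    )
    return categories, related_terms


# ---------------------------------------------------------------------------
# responses

IRCR = "irCR"
IRPR = "irPR"
IRSD = "irSD"
IRPD = "irPD"
NE = "NE"

_RANK = {IRCR: 4, IRPR: 3, IRSD: 2, IRPD: 1, NE: 0}


@dataclass(frozen=True)
class ResponseAssessment:
    subject_id: str
    day: float  # days from first dose
    category: str

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValueError("assessment day must be non-negative")
        if self.category not in _RANK:
            raise ValueError(f"unknown response category {self.category!r}")


@dataclass(frozen=True)
class BestResponse:
    subject_id: str
    category: str
    time_to_response_days: float | None
    duration_days: float | None
    duration_censored: bool


def best_overall_response(
    assessments: Sequence[ResponseAssessment],
    confirmation_window_days: float = 28.0,
) -> BestResponse:
    """Confirmed best overall response for one subject.

    irCR/irPR count only when a second assessment at least
    ``confirmation_window_days`` later shows the same or a better
    category; irPD likewise requires a confirmatory irPD.  Stable
    disease needs no confirmation and no minimum duration.  Time to
    response is the first assessment showing the confirmed response;
    duration runs until the first subsequent irPD, censored at the last
    assessment otherwise.
    """
    if not assessments:
        return BestResponse("", NE, None, None, False)
    subject = assessments[0].subject_id
    ordered = sorted(assessments, key=lambda a: a.day)
    if any(a.subject_id != subject for a in ordered):
        raise ValueError("assessments must belong to one subject")

    def confirmed(category: str) -> ResponseAssessment | None:
        for i, a in enumerate(ordered):
            if a.category != category:
                continue
            for b in ordered[i + 1 :]:
                if b.day - a.day >= confirmation_window_days and (
                    (_RANK[b.category] >= _RANK[category])
                    if category in (IRCR, IRPR)
                    else b.category == category
                ):
                    return a
        return None

    best_cat = NE
    onset: ResponseAssessment | None = None
    for cat in (IRCR, IRPR):
        hit = confirmed(cat)
        if hit is not None:
            best_cat, onset = cat, hit
            break
    if best_cat == NE:
        if any(a.category == IRSD for a in ordered):
            best_cat = IRSD
        elif confirmed(IRPD) is not None or ordered[-1].category == IRPD:
            best_cat = IRPD

    if onset is None:
        return BestResponse(subject, best_cat, None, None, False)
    later_pd = [a for a in ordered if a.day > onset.day and a.category == IRPD]
    if later_pd:
        return BestResponse(
            subject, best_cat, onset.day, later_pd[0].day - onset.day, False
        )
    return BestResponse(
        subject, best_cat, onset.day, ordered[-1].day - onset.day, True
    )


def response_rates(
    best_responses: Iterable[BestResponse | str], n_evaluable: int
) -> tuple[float, float]:
    """(ORR %, DCR %) with half-up rounding to one decimal.

    ORR counts confirmed irCR + irPR; DCR additionally counts irSD.
    """
    if n_evaluable <= 0:
        raise ValueError("n_evaluable must be positive")
    cats = [b.category if isinstance(b, BestResponse) else b for b in best_responses]
    responders = sum(c in (IRCR, IRPR) for c in cats)
    disease_control = responders + sum(c == IRSD for c in cats)
    return percent(responders, n_evaluable), percent(disease_control, n_evaluable)
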
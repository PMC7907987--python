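"""Therapy-course durations, clinical-benefit classification, and cohort rates.

The outcome definitions are operational, not survival-model based:

* a sequencing-directed therapy (SDT) course confers *clinical benefit* when
  the patient stays on it for six months or longer;
* an *exceptional response* is an SDT course of twelve months or longer.

Both thresholds are inclusive. Durations are computed from exact day counts
and converted with a fixed month of 30.4375 days (365.25 / 12), so a 183-day
course is ~6.01 months (benefit) and a 365-day course is ~11.99 months (not
exceptional). Ongoing courses are measured to a censor date; extending the
censor date can only lengthen a course, never shorten it.

``cohort_rates`` turns a table of cohort counts into the headline percentage
summary (actionability, SDT uptake, benefit, germline and
cancer-of-unknown-primary rates), with each rate rounded half-up to one
decimal as such tables are printed.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, fields
from typing import Iterable, Literal

from .tiering import ValidationError
from .utils import percent

DAYS_PER_MONTH = 30.4375  # 365.25 / 12
BENEFIT_MONTHS = 6.0
EXCEPTIONAL_MONTHS = 12.0

RESPONSES = ("CR", "PR", "SD", "PD", "NE")
SETTINGS = ("trial", "off_label", "on_label")


@dataclass(frozen=True)
class TherapyCourse:
    """One treatment episode; ``stop=None`` means ongoing at the censor date."""

    patient_id: str
    therapy: str
    sdt: bool
    start: dt.date
    stop: dt.date | None = None
    setting: str | None = None
    best_response: str = "NE"

    def __post_init__(self) -> None:
        if self.stop is not None and self.stop < self.start:
            raise ValidationError("course stop date precedes start date")
        if self.sdt and self.setting not in SETTINGS:
            raise ValidationError("SDT courses require a setting (trial/off_label/on_label)")
        if self.best_response not in RESPONSES:
            raise ValidationError(f"unknown best response {self.best_response!r}")


def duration_months(course: TherapyCourse, censor_date: dt.date | None = None) -> float:
    """Course duration in months of 30.4375 days, ongoing courses censored."""
    stop = course.stop
    if stop is None:
        if censor_date is None:
            raise ValidationError("ongoing course needs a censor date")
        stop = censor_date
    if stop < course.start:
        raise ValidationError("censor date precedes course start")
    return (stop - course.start).days / DAYS_PER_MONTH


def classify_course(
    course: TherapyCourse, censor_date: dt.date | None = None
) -> dict[str, bool]:
    """Benefit (>= 6 months) and exceptional-response (>= 12 months) flags.

    Only SDT courses are classified; by construction exceptional implies
    benefit.
    """
    if not course.sdt:
        raise ValidationError("only sequencing-directed courses are classified")
    months = duration_months(course, censor_date)
    return {
        "benefit": months >= BENEFIT_MONTHS,
        "exceptional": months >= EXCEPTIONAL_MONTHS,
    }


def clinical_benefit_rate(
    courses: Iterable[TherapyCourse],
    unit: Literal["patient", "instance"] = "patient",
    censor_date: dt.date | None = None,
) -> float:
    """Percent of SDT recipients (or SDT courses) reaching clinical benefit.

    ``unit="patient"``: patients with any benefit course over patients with
    any SDT course. ``unit="instance"``: benefit courses over SDT courses —
    the appropriate unit when a patient can receive several SDTs serially.
    """
    sdt_courses = [c for c in courses if c.sdt]
    if not sdt_courses:
        raise ValidationError("no SDT courses: benefit rate undefined")
    flags = [(c.patient_id, classify_course(c, censor_date)["benefit"]) for c in sdt_courses]
    if unit == "instance":
        return percent(sum(1 for _, b in flags if b), len(flags))
    if unit != "patient":
        raise ValidationError(f"unknown unit {unit!r}")
    sdt_patients = {p for p, _ in flags}
    benefit_patients = {p for p, b in flags if b}
    return percent(len(benefit_patients), len(sdt_patients))


@dataclass(frozen=True)
class CohortCounts:
    """Numerators and denominators behind every headline cohort rate."""

    n_cohort: int
    n_actionable: int
    n_tier2_somatic: int
    n_sdt_patients: int
    n_benefit: int
    n_exceptional: int
    n_pgv_patients: int
    n_pgv_total: int
    n_pgv_unknown_before: int
    n_pgv_penetrant: int
    n_second_hit: int
    n_pgv_therapeutic: int
    n_pgv_therapeutic_second_hit: int
    n_cup: int
    n_cup_reclassified: int
    n_cup_sdt_instances: int
    n_cup_benefit_instances: int

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValidationError(f"{f.name} must be a nonnegative count")
        checks = [
            (self.n_actionable, self.n_cohort),
            (self.n_sdt_patients, self.n_actionable),
            (self.n_benefit, self.n_sdt_patients),
            (self.n_exceptional, self.n_benefit),
            (self.n_pgv_patients, self.n_pgv_total),
            (self.n_second_hit, self.n_pgv_total),
            (self.n_pgv_unknown_before, self.n_pgv_total),
            (self.n_pgv_penetrant, self.n_pgv_total),
            (self.n_pgv_therapeutic_second_hit, self.n_pgv_therapeutic),
            (self.n_cup_reclassified, self.n_cup),
            (self.n_cup_benefit_instances, self.n_cup_sdt_instances),
        ]
        for num, den in checks:
            if num > den:
                raise ValidationError("count invariant violated: numerator exceeds denominator")


@dataclass(frozen=True)
class CohortSummary:
    """Headline rates, percent rounded half-up to one decimal."""

    actionable_pct: float
    tier2_somatic_pct: float
    sdt_initiation_pct: float
    clinical_benefit_pct: float
    exceptional_response_pct: float
    pgv_patient_pct: float
    pgv_unknown_before_pct: float
    pgv_penetrant_pct: float
    second_hit_pct: float
    therapeutic_second_hit_pct: float
    cup_reclassified_pct: float
    cup_benefit_pct: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def cohort_rates(counts: CohortCounts) -> CohortSummary:
    """All headline cohort percentages from their counts.

    A zero denominator with a zero numerator reports 0.0 rather than erroring,
    so empty synthetic cohorts summarize cleanly.
    """
    pct = lambda num, den: percent(num, den) if den else 0.0  # noqa: E731
    return CohortSummary(
        actionable_pct=pct(counts.n_actionable, counts.n_cohort),
        tier2_somatic_pct=pct(counts.n_tier2_somatic, counts.n_cohort),
        sdt_initiation_pct=pct(counts.n_sdt_patients, counts.n_actionable),
        clinical_benefit_pct=pct(counts.n_benefit, counts.n_sdt_patients),
        exceptional_response_pct=pct(counts.n_exceptional, counts.n_sdt_patients),
        pgv_patient_pct=pct(counts.n_pgv_patients, counts.n_cohort),
        pgv_unknown_before_pct=pct(counts.n_pgv_unknown_before, counts.n_pgv_total),
        pgv_penetrant_pct=pct(counts.n_pgv_penetrant, counts.n_pgv_total),
        second_hit_pct=pct(counts.n_second_hit, counts.n_pgv_total),
        therapeutic_second_hit_pct=pct(
            counts.n_pgv_therapeutic_second_hit, counts.n_pgv_therapeutic
        ),
        cup_reclassified_pct=pct(counts.n_cup_reclassified, counts.n_cup),
        cup_benefit_pct=pct(counts.n_cup_benefit_instances, counts.n_cup_sdt_instances),
    )
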
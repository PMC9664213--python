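"""Compact constructors used by the packaged criteria modules.

Age conventions (documented in docs/methods.md):

* "<N years" encodes as the half-open day range [0, floor(N * 365.25)).
* Day-denominated bounds ("<=14 days", "<=28 days") are inclusive as printed.
* A neonate is postnatal age <=28 days; premature means gestational age at
  birth <37 weeks; "children" with no qualifier means under 18 years.
"""

from __future__ import annotations

import math
from typing import Optional

from .model import (
    AgeInRange, AllOf, AnyOf, BirthWeightBelow, CoPrescribed,
    CurrentWeightBelow, DiagnosisPresent, DistinctDrugsAtLeast, DoseExceeds,
    DosesPerDayExceeds, DrugPresent, DurationExceeds, FrequencyPerDayBelow,
    GestationalAgeBelow, IsPremature, Not, Predicate, ProcedurePresent,
    SeverityClause, SexIs, TemporalWindow,
)

PEDIATRIC_MAX_YEARS = 18


def years_to_days(years: float) -> int:
    return math.floor(years * 365.25)


CHILD_MAX_DAYS = years_to_days(PEDIATRIC_MAX_YEARS)
NEONATE_MAX_DAY = 28  # inclusive


def age_lt(years: float, min_years: float = 0) -> AgeInRange:
    """Postnatal age in [min_years, years) on the day scale."""
    return AgeInRange(min_days=years_to_days(min_years), max_days=years_to_days(years))


def age_ge(years: float) -> AgeInRange:
    """Postnatal age >= ``years`` (still within the pediatric range)."""
    return AgeInRange(min_days=years_to_days(years), max_days=CHILD_MAX_DAYS)


def age_days_le(days: int) -> AgeInRange:
    return AgeInRange(min_days=0, max_days=days + 1)


def child() -> AgeInRange:
    """Any pediatric age (<18 years)."""
    return AgeInRange(min_days=0, max_days=CHILD_MAX_DAYS)


def neonate() -> AgeInRange:
    return age_days_le(NEONATE_MAX_DAY)


def infant_lt2y() -> AgeInRange:
    return age_lt(2)


def premature() -> IsPremature:
    return IsPremature()


def ga_below(weeks: float) -> GestationalAgeBelow:
    return GestationalAgeBelow(weeks=weeks)


def vlbw() -> BirthWeightBelow:
    """Very low birth weight, <1500 g as printed."""
    return BirthWeightBelow(grams=1500)


def weight_below(kg: float) -> CurrentWeightBelow:
    return CurrentWeightBelow(kg=kg)


def sex(which: str) -> SexIs:
    return SexIs(sex=which)


def drug(ref: str, route: Optional[str] = None) -> DrugPresent:
    return DrugPresent(drug=ref, route=route)


def dose_gt(ref: str, metric: str, threshold: float, unit: str = "mg",
            inclusive: bool = False, route: Optional[str] = None) -> DoseExceeds:
    return DoseExceeds(drug=ref, metric=metric, threshold=threshold, unit=unit,
                       inclusive=inclusive, route=route)


def duration_gt(ref: str, value: float, unit: str = "days",
                inclusive: bool = False) -> DurationExceeds:
    return DurationExceeds(drug=ref, value=value, unit=unit, inclusive=inclusive)


def freq_below(ref: str, per_day: int) -> FrequencyPerDayBelow:
    return FrequencyPerDayBelow(drug=ref, per_day=per_day)


def freq_above(ref: str, per_day: int) -> DosesPerDayExceeds:
    return DosesPerDayExceeds(drug=ref, per_day=per_day)


def within_after(hours: float) -> TemporalWindow:
    return TemporalWindow(relation="within_after", after_hours=hours)


def simultaneous() -> TemporalWindow:
    return TemporalWindow(relation="simultaneous")


def required_gap(before_hours: float, after_hours: float) -> TemporalWindow:
    return TemporalWindow(relation="required_gap_before_and_after",
                          before_hours=before_hours, after_hours=after_hours)


def pair(drug_a: str, drug_b: str, window: TemporalWindow,
         route_a: Optional[str] = None, route_b: Optional[str] = None) -> CoPrescribed:
    return CoPrescribed(drug_a=drug_a, drug_b=drug_b, window=window,
                        route_a=route_a, route_b=route_b)


def n_of_class(class_id: str, count: int = 2) -> DistinctDrugsAtLeast:
    return DistinctDrugsAtLeast(drug=class_id, count=count)


def dx(tag: str) -> DiagnosisPresent:
    return DiagnosisPresent(tag=tag)


def proc(tag: str, linked_drug: Optional[str] = None) -> ProcedurePresent:
    return ProcedurePresent(tag=tag, linked_drug=linked_drug)


def all_of(*children: Predicate) -> AllOf:
    return AllOf(children=list(children))


def any_of(*children: Predicate) -> AnyOf:
    return AnyOf(children=list(children))


def not_(childp: Predicate) -> Not:
    return Not(child=childp)


def avoid(predicate: Predicate) -> SeverityClause:
    return SeverityClause(predicate=predicate, severity="avoid")


def caution(predicate: Predicate) -> SeverityClause:
    return SeverityClause(predicate=predicate, severity="caution")
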
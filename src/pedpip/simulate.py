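"""Seeded synthetic pediatric cohorts with planted, labeled violations.

``plant_positive`` walks a criterion's trigger predicate and constructs the
smallest record that satisfies it (choosing the first satisfiable branch of
each disjunction, the first non-forbidden member of each drug class),
leaves every exception context absent, and — for omission criteria — omits
the required action.  ``plant_boundary_negative`` repeats the construction
but places the first numeric threshold encountered exactly on the
non-flagging side (dose at the printed cutoff for a strict comparator, age
at the excluded birthday, the interacting order just outside the window).

Planted patients are fully specified (sex, gestational age, birth weight,
current weight, timestamps) so that every planted evaluation is
determinate; background records are drawn from verified non-triggering
drug/dose combinations and may omit timestamps or weight to exercise the
engine's indeterminate paths.  Every plant is re-checked against the
evaluation semantics at generation time and construction fails loudly if
the record does not behave as labeled.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field as dc_field
from datetime import date, datetime, timedelta
from typing import Optional

import numpy as np

from .engine import Flag, _Evaluator, _screen_one
from .kb.dsl import CHILD_MAX_DAYS
from .kb.model import Criterion, KnowledgeBase
from .patients import (
    MedicationOrder, PatientProfile, PrescriptionRecord, ProcedureOrder,
    mass_to_mg,
)

_BASE_DATE = date(2024, 1, 15)
_BASE_TIME = datetime(2024, 1, 15, 8, 0)


class PlantingError(RuntimeError):
    """A record satisfying (or cleanly missing) the criterion could not be built."""


class NoNumericThresholdError(ValueError):
    """Boundary negatives need at least one numeric threshold in the trigger."""


def default_weight_kg(age_days: int) -> float:
    """Rough weight-for-age used when no constraint pins the weight."""
    years = age_days / 365.25
    if age_days <= 28:
        return 3.4
    if years < 2:
        return round(4.0 + 4.0 * years, 1)
    return round(min(2.0 * years + 8.0, 60.0), 1)


@dataclass
class _OrderSpec:
    drug_id: str
    route: str = "oral"
    dose_mg: float = 10.0
    freq: int = 1
    duration_days: float = 3.0
    cumulative_mg: Optional[float] = None
    offset_hours: float = 0.0


@dataclass
class _Plan:
    age_lo: int = 0
    age_hi: int = CHILD_MAX_DAYS
    age_pin: Optional[int] = None
    sex: Optional[str] = None
    ga_weeks: Optional[float] = None
    birth_weight_g: Optional[float] = None
    weight_kg: Optional[float] = None
    weight_max_kg: Optional[float] = None
    diagnoses: set = dc_field(default_factory=set)
    orders: dict = dc_field(default_factory=dict)  # (drug_id, route) -> _OrderSpec
    procedures: list = dc_field(default_factory=list)  # (tag, linked_drug_id)
    forbidden_drugs: set = dc_field(default_factory=set)
    forbidden_tags: set = dc_field(default_factory=set)


def _collect_forbidden(p, kb: KnowledgeBase, drugs: set, tags: set) -> None:
    """(drug_id, route) pairs / tags appearing under a negation: never add
    them (route None forbids the drug on every route)."""
    kind = p.kind
    if kind == "not":
        child = p.child
        _collect_positive_refs(child, kb, drugs, tags)
    elif kind in {"all_of", "any_of"}:
        for c in p.children:
            _collect_forbidden(c, kb, drugs, tags)


def _collect_positive_refs(p, kb: KnowledgeBase, drugs: set, tags: set) -> None:
    kind = p.kind
    if kind == "drug_present":
        drugs |= {(d, p.route) for d in kb.lexicon.expand(p.drug)}
    elif kind in {"dose_exceeds", "duration_exceeds",
                  "frequency_per_day_below", "doses_per_day_exceeds"}:
        route = getattr(p, "route", None)
        drugs |= {(d, route) for d in kb.lexicon.expand(p.drug)}
    elif kind == "co_prescribed":
        drugs |= {(d, p.route_a) for d in kb.lexicon.expand(p.drug_a)}
        drugs |= {(d, p.route_b) for d in kb.lexicon.expand(p.drug_b)}
    elif kind == "diagnosis_present":
        tags.add(p.tag)
    elif kind in {"all_of", "any_of"}:
        for c in p.children:
            _collect_positive_refs(c, kb, drugs, tags)
    elif kind == "not":
        pass  # double negation: ignore rather than force


def _window_hit(dt_hours: float, w) -> bool:
    """Mirror of the engine's window semantics on planned offsets."""
    if w.relation == "simultaneous":
        return dt_hours == 0
    if w.relation == "within_after":
        return 0 <= dt_hours <= w.after_hours
    if w.relation == "within_before":
        return 0 <= -dt_hours <= w.before_hours
    respected = (w.before_hours is not None and dt_hours >= w.before_hours) or \
                (w.after_hours is not None and dt_hours <= -w.after_hours)
    return not respected


class _Planter:
    def __init__(self, kb: KnowledgeBase, criterion: Criterion, boundary: bool):
        self.kb = kb
        self.criterion = criterion
        # 'pending' until the first eligible numeric atom consumes it
        self.boundary = {"pending": boundary}

    # -- helpers ------------------------------------------------------------

    def _choose(self, plan: _Plan, ref: str, route: Optional[str] = None) -> str:
        for d in sorted(self.kb.lexicon.expand(ref)):
            if (d, None) in plan.forbidden_drugs:
                continue
            if (d, route) in plan.forbidden_drugs:
                continue
            return d
        raise PlantingError(f"no usable drug for {ref!r}")

    def _order(self, plan: _Plan, drug_id: str, route: Optional[str]) -> _OrderSpec:
        key = (drug_id, route or "oral")
        if key not in plan.orders:
            plan.orders[key] = _OrderSpec(drug_id=drug_id, route=route or "oral")
        return plan.orders[key]

    def _intersect_age(self, plan: _Plan, lo: int, hi: Optional[int]) -> None:
        plan.age_lo = max(plan.age_lo, lo)
        if hi is not None:
            plan.age_hi = min(plan.age_hi, hi)
        if plan.age_lo >= plan.age_hi:
            raise PlantingError("empty age interval")

    def _take_boundary(self) -> bool:
        if self.boundary["pending"]:
            self.boundary["pending"] = False
            return True
        return False

    # -- planning -----------------------------------------------------------

    def plan(self, plan: _Plan, p) -> None:
        getattr(self, "_plan_" + p.kind)(plan, p)

    def _plan_all_of(self, plan: _Plan, p) -> None:
        for c in p.children:
            self.plan(plan, c)

    def _plan_any_of(self, plan: _Plan, p) -> None:
        last_error: Optional[Exception] = None
        for i, c in enumerate(p.children):
            trial = copy.deepcopy(plan)
            state = dict(self.boundary)
            try:
                self.plan(trial, c)
            except PlantingError as exc:
                self.boundary.update(state)
                last_error = exc
                continue
            consumed = state.get("pending") and not self.boundary["pending"]
            if consumed:
                # the chosen branch was pushed to its clean side; no sibling
                # may rescue the disjunction
                for j, sibling in enumerate(p.children):
                    if j != i:
                        self._suppress(trial, sibling)
            plan.__dict__.update(trial.__dict__)
            return
        raise PlantingError(f"no satisfiable branch: {last_error}")

    # -- suppression: make a sibling branch not-satisfied -------------------

    def _candidate_age(self, plan: _Plan) -> int:
        if plan.age_pin is not None:
            return plan.age_pin
        lo, hi = plan.age_lo, plan.age_hi
        return 1461 if lo <= 1461 < hi else lo + (hi - lo) // 2

    def _suppress(self, plan: _Plan, p) -> None:
        """Ensure a predicate evaluates not-satisfied on the final record;
        raises PlantingError when that cannot be arranged."""
        kind = p.kind
        planned_drugs = {d for (d, _r) in plan.orders}
        if kind == "not":
            self.plan(plan, p.child)  # satisfy the child so the negation fails
        elif kind == "diagnosis_present":
            if p.tag in plan.diagnoses:
                raise PlantingError(f"cannot suppress planned tag {p.tag!r}")
        elif kind == "procedure_present":
            if any(t == p.tag for t, _l in plan.procedures):
                raise PlantingError(f"cannot suppress planned procedure {p.tag!r}")
        elif kind in {"drug_present", "distinct_drugs_at_least"}:
            if self.kb.lexicon.expand(p.drug) & planned_drugs:
                raise PlantingError(f"cannot suppress planned drug {p.drug!r}")
        elif kind == "co_prescribed":
            a_specs = [s for (d, _r), s in plan.orders.items()
                       if d in self.kb.lexicon.expand(p.drug_a)]
            b_specs = [s for (d, _r), s in plan.orders.items()
                       if d in self.kb.lexicon.expand(p.drug_b)]
            for sa in a_specs:
                for sb in b_specs:
                    if sa is sb:
                        continue
                    if _window_hit(sb.offset_hours - sa.offset_hours, p.window):
                        raise PlantingError("cannot suppress planned drug pair")
        elif kind in {"dose_exceeds", "duration_exceeds",
                      "frequency_per_day_below", "doses_per_day_exceeds"}:
            self._suppress_order_atom(plan, p)
        elif kind == "age_in_range":
            a = self._candidate_age(plan)
            if a >= p.min_days and (p.max_days is None or a < p.max_days):
                raise PlantingError("cannot place age outside sibling range")
        elif kind == "current_weight_below":
            if plan.weight_kg is not None and plan.weight_kg < p.kg:
                raise PlantingError("weight already pinned below sibling cutoff")
            plan.weight_kg = float(p.kg) if plan.weight_kg is None \
                else plan.weight_kg
            plan.weight_max_kg = None
        elif kind == "gestational_age_below":
            if plan.ga_weeks is not None and plan.ga_weeks < p.weeks:
                raise PlantingError("gestational age already below sibling cutoff")
            if plan.ga_weeks is None:
                plan.ga_weeks = max(p.weeks, 38.0)
        elif kind == "birth_weight_below":
            if plan.birth_weight_g is not None and plan.birth_weight_g < p.grams:
                raise PlantingError("birth weight already below sibling cutoff")
            if plan.birth_weight_g is None:
                plan.birth_weight_g = max(p.grams, 3300.0)
        elif kind == "is_premature":
            if plan.ga_weeks is not None and plan.ga_weeks < 37:
                raise PlantingError("prematurity already planned")
            if plan.ga_weeks is None:
                plan.ga_weeks = 40.0
        elif kind == "sex_is":
            other = "female" if p.sex == "male" else "male"
            if plan.sex == p.sex:
                raise PlantingError("sex already pinned to sibling value")
            plan.sex = plan.sex or other
        elif kind == "all_of":
            # false as soon as any one child is false
            last: Optional[Exception] = None
            for c in p.children:
                trial = copy.deepcopy(plan)
                try:
                    self._suppress(trial, c)
                except PlantingError as exc:
                    last = exc
                    continue
                plan.__dict__.update(trial.__dict__)
                return
            raise PlantingError(f"cannot suppress conjunction: {last}")
        elif kind == "any_of":
            for c in p.children:
                self._suppress(plan, c)
        else:
            raise PlantingError(f"cannot suppress {kind}")

    def _suppress_order_atom(self, plan: _Plan, p) -> None:
        """Push an already-planned order of the same drug to the clean side
        of a sibling numeric atom (dose/duration/frequency)."""
        ids = self.kb.lexicon.expand(p.drug)
        specs = [s for (d, _r), s in plan.orders.items() if d in ids]
        for spec in specs:
            if p.kind == "dose_exceeds":
                thr = mass_to_mg(p.threshold, p.unit)
                weight = plan.weight_kg or default_weight_kg(
                    self._candidate_age(plan))
                per_day = spec.dose_mg * spec.freq
                value = {
                    "per_kg_per_day": per_day / weight,
                    "per_day": per_day,
                    "per_dose": spec.dose_mg,
                    "per_kg_per_hour": per_day / weight / 24,
                    "cumulative_total": spec.cumulative_mg,
                    "cumulative_per_kg": (spec.cumulative_mg / weight
                                          if spec.cumulative_mg else None),
                }[p.metric]
                if value is None:
                    continue
                hit = value >= thr if p.inclusive else value > thr
                if hit:
                    raise PlantingError(
                        f"planned dose of {p.drug!r} already exceeds sibling "
                        f"threshold")
            elif p.kind == "duration_exceeds":
                hours = {"hours": 1.0, "days": 24.0, "weeks": 168.0,
                         "months": 730.56}
                thr_days = p.value * hours[p.unit] / 24.0
                hit = (spec.duration_days >= thr_days if p.inclusive
                       else spec.duration_days > thr_days)
                if hit:
                    spec.duration_days = (thr_days if not p.inclusive
                                          else thr_days - 0.5)
            elif p.kind == "frequency_per_day_below":
                if spec.freq < p.per_day:
                    spec.freq = p.per_day
            elif p.kind == "doses_per_day_exceeds":
                if spec.freq > p.per_day:
                    spec.freq = p.per_day

    def _plan_not(self, plan: _Plan, p) -> None:
        pass  # absence is the default; forbidden refs collected up front

    def _plan_age_in_range(self, plan: _Plan, p) -> None:
        nontrivial = p.min_days > 0 or (p.max_days is not None
                                        and p.max_days < CHILD_MAX_DAYS)
        if nontrivial and self._take_boundary():
            plan.age_pin = p.max_days if (p.max_days is not None
                                          and p.max_days < CHILD_MAX_DAYS) \
                else p.min_days - 1
            return
        self._intersect_age(plan, p.min_days, p.max_days)

    def _plan_gestational_age_below(self, plan: _Plan, p) -> None:
        plan.ga_weeks = float(p.weeks) if self._take_boundary() \
            else max(p.weeks - 2.0, 24.0)

    def _plan_birth_weight_below(self, plan: _Plan, p) -> None:
        plan.birth_weight_g = float(p.grams) if self._take_boundary() \
            else round(p.grams * 0.8)

    def _plan_current_weight_below(self, plan: _Plan, p) -> None:
        if self._take_boundary():
            plan.weight_kg = float(p.kg)
        else:
            plan.weight_max_kg = min(plan.weight_max_kg or 1e9, p.kg * 0.8)

    def _plan_is_premature(self, plan: _Plan, p) -> None:
        if plan.ga_weeks is None or plan.ga_weeks >= 37:
            plan.ga_weeks = 32.0

    def _plan_sex_is(self, plan: _Plan, p) -> None:
        if plan.sex is not None and plan.sex != p.sex:
            raise PlantingError("conflicting sex constraints")
        plan.sex = p.sex

    def _plan_drug_present(self, plan: _Plan, p) -> None:
        self._order(plan, self._choose(plan, p.drug, p.route), p.route)

    def _plan_dose_exceeds(self, plan: _Plan, p) -> None:
        thr = mass_to_mg(p.threshold, p.unit)
        boundary = self._take_boundary()
        # fail side: exactly at threshold for strict '>', 5% under for '>='
        factor = (1.0 if not p.inclusive else 0.95) if boundary else 1.25
        target = thr * factor
        spec = self._order(plan, self._choose(plan, p.drug, p.route), p.route)
        weight = plan.weight_kg
        if "per_kg" in p.metric and weight is None:
            # fix the weight now so the dose can be computed
            mid_age = plan.age_lo + (plan.age_hi - plan.age_lo) // 2
            weight = default_weight_kg(mid_age)
            if plan.weight_max_kg is not None:
                weight = min(weight, plan.weight_max_kg)
            plan.weight_kg = weight
        if p.metric == "per_kg_per_day":
            spec.freq = 1
            spec.dose_mg = target * weight
        elif p.metric == "per_day":
            spec.freq = 1
            spec.dose_mg = target
        elif p.metric == "per_dose":
            spec.dose_mg = target
        elif p.metric == "per_kg_per_hour":
            spec.freq = 1
            spec.dose_mg = target * 24 * weight
        elif p.metric == "cumulative_total":
            spec.cumulative_mg = target
        elif p.metric == "cumulative_per_kg":
            spec.cumulative_mg = target * weight

    def _plan_duration_exceeds(self, plan: _Plan, p) -> None:
        hours = {"hours": 1.0, "days": 24.0, "weeks": 168.0, "months": 730.56}
        thr_days = p.value * hours[p.unit] / 24.0
        boundary = self._take_boundary()
        spec = self._order(plan, self._choose(plan, p.drug), None)
        if boundary:
            spec.duration_days = thr_days if not p.inclusive else thr_days - 0.5
        else:
            spec.duration_days = thr_days * 1.5

    def _plan_frequency_per_day_below(self, plan: _Plan, p) -> None:
        spec = self._order(plan, self._choose(plan, p.drug), None)
        spec.freq = p.per_day if self._take_boundary() else max(p.per_day - 1, 1)

    def _plan_doses_per_day_exceeds(self, plan: _Plan, p) -> None:
        spec = self._order(plan, self._choose(plan, p.drug), None)
        spec.freq = p.per_day if self._take_boundary() else p.per_day + 1

    def _plan_co_prescribed(self, plan: _Plan, p) -> None:
        a = self._order(plan, self._choose(plan, p.drug_a, p.route_a), p.route_a)
        b = self._order(plan, self._choose(plan, p.drug_b, p.route_b), p.route_b)
        w = p.window
        boundary = self._take_boundary() if w.relation != "simultaneous" else False
        if w.relation == "simultaneous":
            b.offset_hours = a.offset_hours
        elif w.relation == "within_after":
            b.offset_hours = a.offset_hours + (w.after_hours + 1.0 if boundary
                                               else w.after_hours / 2.0)
        elif w.relation == "within_before":
            b.offset_hours = a.offset_hours - (w.before_hours + 1.0 if boundary
                                               else w.before_hours / 2.0)
        else:  # required_gap: violate unless boundary
            dt = w.before_hours if boundary else max(w.before_hours - 1.0, 0.5)
            b.offset_hours = a.offset_hours + dt

    def _plan_distinct_drugs_at_least(self, plan: _Plan, p) -> None:
        members = [d for d in sorted(self.kb.lexicon.expand(p.drug))
                   if d not in plan.forbidden_drugs]
        if len(members) < p.count:
            raise PlantingError(f"class {p.drug!r} too small for {p.count}")
        for d in members[:p.count]:
            self._order(plan, d, None)

    def _plan_diagnosis_present(self, plan: _Plan, p) -> None:
        if p.tag in plan.forbidden_tags:
            raise PlantingError(f"tag {p.tag!r} is forbidden by a negation")
        plan.diagnoses.add(p.tag)

    def _plan_procedure_present(self, plan: _Plan, p) -> None:
        linked = None
        if p.linked_drug is not None:
            linked = self._choose(plan, p.linked_drug)
        plan.procedures.append((p.tag, linked))


def _finalize(plan: _Plan, record_id: str) -> PrescriptionRecord:
    if plan.age_pin is not None:
        age = plan.age_pin
    else:
        lo, hi = plan.age_lo, plan.age_hi
        preemie_context = (plan.ga_weeks is not None and plan.ga_weeks < 37) \
            or (plan.birth_weight_g is not None and plan.birth_weight_g < 1500)
        if preemie_context and lo <= 5 < hi:
            age = 5
        elif lo <= 1461 < hi:
            age = 1461  # a 4-year-old unless the criterion says otherwise
        else:
            age = lo + (hi - lo) // 2
    ga = plan.ga_weeks if plan.ga_weeks is not None else 40.0
    if plan.birth_weight_g is not None:
        bw = plan.birth_weight_g
    else:
        bw = 3300.0 if ga >= 37 else 1800.0
    if plan.weight_kg is not None:
        weight = plan.weight_kg
    else:
        weight = default_weight_kg(age)
        if plan.weight_max_kg is not None:
            weight = min(weight, plan.weight_max_kg)
    patient = PatientProfile(
        patient_id=record_id,
        sex=plan.sex or "male",
        age_days_at_encounter=age,
        gestational_age_weeks=ga,
        birth_weight_g=bw,
        current_weight_kg=weight,
        diagnosis_tags=sorted(plan.diagnoses),
    )
    orders = [
        MedicationOrder(
            order_id=f"{record_id}-o{i}",
            drug_text=spec.drug_id,
            drug_id=spec.drug_id,
            dose_amount=round(spec.dose_mg, 4),
            dose_unit="mg",
            frequency_per_day=spec.freq,
            route=spec.route,
            start_time=_BASE_TIME + timedelta(hours=spec.offset_hours),
            duration_days=spec.duration_days,
            cumulative_dose=spec.cumulative_mg,
            cumulative_unit="mg",
        )
        for i, (_, spec) in enumerate(sorted(plan.orders.items()))
    ]
    procedures = [ProcedureOrder(procedure_tag=t, linked_drug_id=l)
                  for t, l in plan.procedures]
    return PrescriptionRecord(
        record_id=record_id, encounter_date=_BASE_DATE, patient=patient,
        orders=orders, procedures=procedures,
    )


def _build(criterion: Criterion, kb: KnowledgeBase, record_id: str,
           boundary: bool) -> PrescriptionRecord:
    plan = _Plan()
    _collect_forbidden(criterion.trigger, kb, plan.forbidden_drugs,
                       plan.forbidden_tags)
    if criterion.exception is not None:
        _collect_positive_refs(criterion.exception, kb, plan.forbidden_drugs,
                               plan.forbidden_tags)
    planter = _Planter(kb, criterion, boundary)
    planter.plan(plan, criterion.trigger)
    if boundary and planter.boundary["pending"]:
        raise NoNumericThresholdError(
            f"{criterion.criterion_id} has no numeric threshold in its trigger")
    if not boundary and criterion.category == "PIM":
        # make some severity clause hold so the flag is actually emitted
        for clause in criterion.severity_clauses:
            trial = copy.deepcopy(plan)
            try:
                planter.plan(trial, clause.predicate)
            except PlantingError:
                continue
            plan.__dict__.update(trial.__dict__)
            break
    return _finalize(plan, record_id)


def _verify(record: PrescriptionRecord, criterion: Criterion,
            kb: KnowledgeBase, expect_flag: bool) -> None:
    outcome = _screen_one(_Evaluator(record, kb), criterion)
    flagged = isinstance(outcome, Flag)
    if expect_flag and not flagged:
        raise PlantingError(
            f"{criterion.criterion_id}: planted positive not flagged ({outcome})")
    if not expect_flag and outcome is not None:
        raise PlantingError(
            f"{criterion.criterion_id}: boundary negative not clean ({outcome})")


def plant_positive(criterion: Criterion, kb: KnowledgeBase,
                   record_id: str = "P1", seed: int = 0) -> PrescriptionRecord:
    """A record the engine must flag for this criterion (verified)."""
    record = _build(criterion, kb, record_id, boundary=False)
    _verify(record, criterion, kb, expect_flag=True)
    return record


def plant_boundary_negative(criterion: Criterion, kb: KnowledgeBase,
                            record_id: str = "N1",
                            seed: int = 0) -> PrescriptionRecord:
    """A structurally identical record with the decisive quantity on the
    non-flagging side of its printed threshold (verified clean)."""
    record = _build(criterion, kb, record_id, boundary=True)
    _verify(record, criterion, kb, expect_flag=False)
    return record


def constructible_criteria(kb: KnowledgeBase) -> list[Criterion]:
    """Criteria for which a positive can be planted (all packaged ones)."""
    out = []
    for c in kb.criteria:
        try:
            plant_positive(c, kb, record_id="probe")
        except PlantingError:
            continue
        out.append(c)
    return out


# --- cohort generation ------------------------------------------------------

#: background orders verified non-triggering at generation time:
#: (drug_text, dose, unit, freq/day, route)
BACKGROUND_DRUGS: list[tuple[str, float, str, int, str]] = [
    ("cetirizine", 5.0, "mg", 1, "oral"),
    ("loratadine", 5.0, "mg", 1, "oral"),
    ("budesonide", 200.0, "ug", 2, "inhaled"),
    ("omeprazole", 10.0, "mg", 1, "oral"),
    ("acetaminophen", 250.0, "mg", 2, "oral"),
    ("ibuprofen", 50.0, "mg", 2, "oral"),  # <=40 mg/kg/d even for a neonate
    ("salbutamol", 2.0, "mg", 2, "inhaled"),  # not in the lexicon: unknown-drug path
]

#: default stratum weights over the pediatric age bands
DEFAULT_STRATA: dict[str, float] = {
    "premature_neonate": 0.05,
    "term_neonate": 0.10,
    "infant": 0.25,
    "child": 0.40,
    "adolescent": 0.20,
}

_STRATUM_AGE = {
    "premature_neonate": (2, 28),
    "term_neonate": (1, 28),
    "infant": (29, 729),
    "child": (730, 4382),
    "adolescent": (4383, 6573),
}


@dataclass
class PlantSpec:
    criterion_id: str
    count_positives: int = 1
    count_boundary_negatives: int = 0


@dataclass
class CohortConfig:
    n_records: int = 50
    seed: int = 0
    stratum_weights: dict = dc_field(default_factory=lambda: dict(DEFAULT_STRATA))
    violation_plan: list = dc_field(default_factory=list)  # list[PlantSpec]
    background_drugs: list = dc_field(default_factory=lambda: list(BACKGROUND_DRUGS))


@dataclass(frozen=True)
class Label:
    record_id: str
    criterion_id: str
    expectation: str  # "flag" | "clean"


@dataclass
class CohortLabelSet:
    labels: list[Label] = dc_field(default_factory=list)

    def expected_flags(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for lb in self.labels:
            if lb.expectation == "flag":
                out.setdefault(lb.record_id, set()).add(lb.criterion_id)
        return out

    def expected_clean(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for lb in self.labels:
            if lb.expectation == "clean":
                out.setdefault(lb.record_id, set()).add(lb.criterion_id)
        return out


class ConfigError(ValueError):
    pass


def _background_record(rng: np.random.Generator, record_id: str,
                       config: CohortConfig, kb: KnowledgeBase) -> PrescriptionRecord:
    names = list(config.stratum_weights)
    w = np.array([config.stratum_weights[n] for n in names], dtype=float)
    if w.sum() <= 0 or (w < 0).any():
        raise ConfigError("stratum weights must be nonnegative with positive sum")
    stratum = names[int(rng.choice(len(names), p=w / w.sum()))]
    lo, hi = _STRATUM_AGE[stratum]
    age = int(rng.integers(lo, hi + 1))
    ga = float(rng.uniform(28, 34)) if stratum == "premature_neonate" \
        else float(rng.uniform(37, 41))
    weight = default_weight_kg(age) * float(rng.uniform(0.9, 1.1))
    synonyms = kb.lexicon.synonym_index()
    n_drugs = int(rng.integers(0, 3))
    picks = rng.choice(len(config.background_drugs), size=n_drugs, replace=False)
    orders = []
    for i, k in enumerate(sorted(int(x) for x in picks)):
        name, dose, unit, freq, route = config.background_drugs[k]
        with_time = bool(rng.random() < 0.7)
        orders.append(MedicationOrder(
            order_id=f"{record_id}-o{i}",
            drug_text=name,
            drug_id=synonyms.get(name.casefold(), "__unknown__"),
            dose_amount=dose, dose_unit=unit, frequency_per_day=freq,
            route=route,
            start_time=_BASE_TIME if with_time else None,
            duration_days=float(rng.integers(1, 8)),
        ))
    patient = PatientProfile(
        patient_id=record_id,
        sex="male" if rng.random() < 0.5 else "female",
        age_days_at_encounter=age,
        gestational_age_weeks=round(ga, 1),
        birth_weight_g=1300.0 if stratum == "premature_neonate" else 3300.0,
        current_weight_kg=round(weight, 2) if rng.random() < 0.85 else None,
        diagnosis_tags=[],
    )
    return PrescriptionRecord(record_id=record_id, encounter_date=_BASE_DATE,
                              patient=patient, orders=orders, procedures=[])


def generate_cohort(config: CohortConfig,
                    kb: KnowledgeBase) -> tuple[list[PrescriptionRecord], CohortLabelSet]:
    """Planted records interleaved with verified-clean background records.

    Reproducible: the same config (including seed) yields an identical
    cohort.  Raises :class:`ConfigError` when the violation plan needs more
    records than ``n_records``.
    """
    by_id = {c.criterion_id: c for c in kb.criteria}
    planted: list[PrescriptionRecord] = []
    labels = CohortLabelSet()
    for spec in config.violation_plan:
        if spec.criterion_id not in by_id:
            raise ConfigError(f"unknown criterion {spec.criterion_id!r}")
        c = by_id[spec.criterion_id]
        for j in range(spec.count_positives):
            rid = f"P-{spec.criterion_id}-{j}"
            planted.append(plant_positive(c, kb, record_id=rid, seed=config.seed))
            labels.labels.append(Label(rid, c.criterion_id, "flag"))
        for j in range(spec.count_boundary_negatives):
            rid = f"N-{spec.criterion_id}-{j}"
            planted.append(plant_boundary_negative(c, kb, record_id=rid,
                                                   seed=config.seed))
            labels.labels.append(Label(rid, c.criterion_id, "clean"))
    if len(planted) > config.n_records:
        raise ConfigError(
            f"violation plan needs {len(planted)} records but n_records = "
            f"{config.n_records}")

    rng = np.random.default_rng(config.seed)
    records = list(planted)
    n_background = config.n_records - len(planted)
    for i in range(n_background):
        rec = _background_record(rng, f"B-{i:04d}", config, kb)
        res = _screen_all_flags(rec, kb)
        if res:  # background must be flag-free by construction
            raise PlantingError(f"background record {rec.record_id} flagged {res}")
        records.append(rec)
    return records, labels


def _screen_all_flags(record: PrescriptionRecord, kb: KnowledgeBase) -> list[str]:
    ev = _Evaluator(record, kb)
    hits = []
    for c in kb.criteria:
        if isinstance(_screen_one(ev, c), Flag):
            hits.append(c.criterion_id)
    return hits


def full_sweep_plan(kb: KnowledgeBase, with_negatives: bool = True) -> list[PlantSpec]:
    """One positive (and, where a threshold exists, one boundary negative)
    per packaged criterion."""
    plan = []
    for c in kb.criteria:
        neg = 0
        if with_negatives:
            try:
                plant_boundary_negative(c, kb, record_id="probe")
                neg = 1
            except NoNumericThresholdError:
                neg = 0
        plan.append(PlantSpec(c.criterion_id, 1, neg))
    return plan
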
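"""Three-valued screening engine.

Every criterion is evaluated against a prescription record under
strong-Kleene semantics: an atom whose inputs are missing (weight for a
per-kg dose, a timestamp for an interaction window, unknown sex) is
*indeterminate* rather than false, and conjunction/disjunction/negation
propagate indeterminacy only when it is decisive.  A record therefore
yields three disjoint criterion sets: flagged, clean, and unscreenable.

Flagging rules:

* PIM: trigger satisfied AND exception not satisfied AND at least one
  severity clause satisfied; reported severity is the maximum (avoid >
  caution) over satisfied clauses.
* PPO: trigger satisfied AND exception not satisfied AND the required
  action absent from the record.
* An indeterminate exception or required action makes the criterion
  indeterminate — the engine never flags through an unverifiable exception.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .kb.model import (
    Criterion, KnowledgeBase, TemporalWindow,
)
from .patients import (
    MedicationOrder, PrescriptionRecord, derive_age_profile,
    derive_dose_profile, mass_to_mg, UNKNOWN_DRUG,
)


class Status(str, Enum):
    SATISFIED = "satisfied"
    NOT_SATISFIED = "not_satisfied"
    INDETERMINATE = "indeterminate"


@dataclass
class EvaluationOutcome:
    status: Status
    missing_inputs: tuple[str, ...] = ()
    matched_order_ids: tuple[str, ...] = ()


def _sat(*order_ids: str) -> EvaluationOutcome:
    return EvaluationOutcome(Status.SATISFIED, matched_order_ids=tuple(order_ids))


_NOT = EvaluationOutcome(Status.NOT_SATISFIED)


def _indet(*missing: str) -> EvaluationOutcome:
    return EvaluationOutcome(Status.INDETERMINATE, missing_inputs=tuple(sorted(set(missing))))


_METRIC_FIELD = {
    "per_kg_per_day": "mg_per_kg_per_day",
    "per_day": "mg_per_day",
    "per_dose": "mg_per_dose",
    "per_kg_per_hour": "mg_per_kg_per_hour",
    "cumulative_total": "cumulative_mg",
    "cumulative_per_kg": "cumulative_mg_per_kg",
}

_DURATION_HOURS = {"hours": 1.0, "days": 24.0, "weeks": 24 * 7.0,
                   "months": 24 * 30.44}


def within_window(a: MedicationOrder, b: MedicationOrder,
                  w: TemporalWindow) -> EvaluationOutcome:
    """Timing check for an order pair already known to be co-present.

    Both timestamps missing: the pair is treated as simultaneous (orders on
    one record with no recorded times).  One missing: indeterminate.
    """
    ta, tb = a.start_time, b.start_time
    if ta is None and tb is None:
        dt = 0.0
    elif ta is None or tb is None:
        return _indet("start_time")
    else:
        dt = (tb - ta).total_seconds() / 3600.0

    if w.relation == "simultaneous":
        # concomitant: same start (or no recorded times on the same record)
        return _sat(a.order_id, b.order_id) if dt == 0 else _NOT
    if w.relation == "within_after":
        ok = 0 <= dt <= w.after_hours
    elif w.relation == "within_before":
        ok = 0 <= -dt <= w.before_hours
    else:  # required_gap_before_and_after: satisfied = the gap is violated
        respected = (w.before_hours is not None and dt >= w.before_hours) or \
                    (w.after_hours is not None and dt <= -w.after_hours)
        ok = not respected
    return _sat(a.order_id, b.order_id) if ok else _NOT


class _Evaluator:
    """Per-record predicate evaluator with cached derived profiles."""

    def __init__(self, record: PrescriptionRecord, kb: KnowledgeBase):
        self.record = record
        self.kb = kb
        self.age = derive_age_profile(record.patient, record.encounter_date)
        self._doses = {o.order_id: derive_dose_profile(o, record.patient)
                       for o in record.orders}

    def _orders_for(self, ref: str, route: Optional[str] = None,
                    check_route: bool = True):
        """(matching, route_indeterminate) orders for a drug/class ref."""
        ids = self.kb.lexicon.expand(ref)
        exact, maybe = [], []
        for o in self.record.orders:
            if o.drug_id == UNKNOWN_DRUG or o.drug_id not in ids:
                continue
            if route is None or not check_route:
                exact.append(o)
            elif o.route == route:
                exact.append(o)
            elif o.route is None:
                maybe.append(o)
        return exact, maybe

    def _exists(self, orders, maybe, missing_field: str, test) -> EvaluationOutcome:
        """Existential aggregation over candidate orders."""
        indeterminate_missing: list[str] = []
        for o in orders:
            out = test(o)
            if out.status is Status.SATISFIED:
                return out
            if out.status is Status.INDETERMINATE:
                indeterminate_missing.extend(out.missing_inputs)
        if maybe:
            indeterminate_missing.append(missing_field)
        if indeterminate_missing:
            return _indet(*indeterminate_missing)
        return _NOT

    # --- atoms -------------------------------------------------------------

    def evaluate(self, p) -> EvaluationOutcome:
        return getattr(self, "_eval_" + p.kind)(p)

    def _eval_age_in_range(self, p) -> EvaluationOutcome:
        d = self.age.postnatal_days
        ok = d >= p.min_days and (p.max_days is None or d < p.max_days)
        return _sat() if ok else _NOT

    def _eval_gestational_age_below(self, p) -> EvaluationOutcome:
        ga = self.record.patient.gestational_age_weeks
        if ga is None:
            return _indet("gestational_age_weeks")
        return _sat() if ga < p.weeks else _NOT

    def _eval_birth_weight_below(self, p) -> EvaluationOutcome:
        bw = self.record.patient.birth_weight_g
        if bw is None:
            return _indet("birth_weight_g")
        return _sat() if bw < p.grams else _NOT

    def _eval_current_weight_below(self, p) -> EvaluationOutcome:
        w = self.record.patient.current_weight_kg
        if w is None:
            return _indet("current_weight_kg")
        return _sat() if w < p.kg else _NOT

    def _eval_is_premature(self, p) -> EvaluationOutcome:
        if self.age.is_premature is None:
            return _indet("gestational_age_weeks")
        return _sat() if self.age.is_premature else _NOT

    def _eval_sex_is(self, p) -> EvaluationOutcome:
        s = self.record.patient.sex
        if s == "unknown":
            return _indet("sex")
        return _sat() if s == p.sex else _NOT

    def _eval_drug_present(self, p) -> EvaluationOutcome:
        exact, maybe = self._orders_for(p.drug, p.route)
        if exact:
            return _sat(*[o.order_id for o in exact])
        if maybe:
            return _indet("route")
        return _NOT

    def _eval_dose_exceeds(self, p) -> EvaluationOutcome:
        thr = mass_to_mg(p.threshold, p.unit)
        fieldname = _METRIC_FIELD[p.metric]
        exact, maybe = self._orders_for(p.drug, p.route)

        def test(o: MedicationOrder) -> EvaluationOutcome:
            prof = self._doses[o.order_id]
            value = getattr(prof, fieldname)
            if value is None:
                return _indet(*(prof.missing_inputs or [fieldname]))
            hit = value >= thr if p.inclusive else value > thr
            return _sat(o.order_id) if hit else _NOT

        return self._exists(exact, maybe, "route", test)

    def _eval_duration_exceeds(self, p) -> EvaluationOutcome:
        thr_days = p.value * _DURATION_HOURS[p.unit] / 24.0
        exact, maybe = self._orders_for(p.drug)

        def test(o: MedicationOrder) -> EvaluationOutcome:
            if o.duration_days is None:
                return _indet("duration_days")
            hit = (o.duration_days >= thr_days if p.inclusive
                   else o.duration_days > thr_days)
            return _sat(o.order_id) if hit else _NOT

        return self._exists(exact, maybe, "route", test)

    def _eval_frequency_per_day_below(self, p) -> EvaluationOutcome:
        exact, maybe = self._orders_for(p.drug)

        def test(o: MedicationOrder) -> EvaluationOutcome:
            if o.frequency_per_day is None:
                return _indet("frequency_per_day")
            return _sat(o.order_id) if o.frequency_per_day < p.per_day else _NOT

        return self._exists(exact, maybe, "route", test)

    def _eval_doses_per_day_exceeds(self, p) -> EvaluationOutcome:
        exact, maybe = self._orders_for(p.drug)

        def test(o: MedicationOrder) -> EvaluationOutcome:
            if o.frequency_per_day is None:
                return _indet("frequency_per_day")
            return _sat(o.order_id) if o.frequency_per_day > p.per_day else _NOT

        return self._exists(exact, maybe, "route", test)

    def _eval_co_prescribed(self, p) -> EvaluationOutcome:
        a_orders, a_maybe = self._orders_for(p.drug_a, p.route_a)
        b_orders, b_maybe = self._orders_for(p.drug_b, p.route_b)
        missing: list[str] = []
        for a in a_orders:
            for b in b_orders:
                if a.order_id == b.order_id:
                    continue
                out = within_window(a, b, p.window)
                if out.status is Status.SATISFIED:
                    return out
                if out.status is Status.INDETERMINATE:
                    missing.extend(out.missing_inputs)
        if (a_orders or a_maybe) and (b_orders or b_maybe) and (a_maybe or b_maybe):
            missing.append("route")
        if missing:
            return _indet(*missing)
        return _NOT

    def _eval_distinct_drugs_at_least(self, p) -> EvaluationOutcome:
        exact, _ = self._orders_for(p.drug)
        distinct = {o.drug_id for o in exact}
        if len(distinct) >= p.count:
            return _sat(*[o.order_id for o in exact])
        return _NOT

    def _eval_diagnosis_present(self, p) -> EvaluationOutcome:
        pt = self.record.patient
        present = p.tag in pt.diagnosis_tags or p.tag in pt.clinical_flags
        return _sat() if present else _NOT

    def _eval_procedure_present(self, p) -> EvaluationOutcome:
        for pr in self.record.procedures:
            if pr.procedure_tag != p.tag:
                continue
            if p.linked_drug is None or pr.linked_drug_id is None:
                return _sat()
            if pr.linked_drug_id in self.kb.lexicon.expand(p.linked_drug):
                return _sat()
        return _NOT

    # --- combinators (strong Kleene) --------------------------------------

    def _eval_all_of(self, p) -> EvaluationOutcome:
        missing: list[str] = []
        matched: list[str] = []
        indeterminate = False
        for childp in p.children:
            out = self.evaluate(childp)
            if out.status is Status.NOT_SATISFIED:
                return _NOT
            if out.status is Status.INDETERMINATE:
                indeterminate = True
                missing.extend(out.missing_inputs)
            matched.extend(out.matched_order_ids)
        if indeterminate:
            return _indet(*missing)
        return EvaluationOutcome(Status.SATISFIED,
                                 matched_order_ids=tuple(dict.fromkeys(matched)))

    def _eval_any_of(self, p) -> EvaluationOutcome:
        missing: list[str] = []
        indeterminate = False
        for childp in p.children:
            out = self.evaluate(childp)
            if out.status is Status.SATISFIED:
                return out
            if out.status is Status.INDETERMINATE:
                indeterminate = True
                missing.extend(out.missing_inputs)
        if indeterminate:
            return _indet(*missing)
        return _NOT

    def _eval_not(self, p) -> EvaluationOutcome:
        out = self.evaluate(p.child)
        if out.status is Status.SATISFIED:
            return _NOT
        if out.status is Status.NOT_SATISFIED:
            return _sat()
        return out


def evaluate_predicate(p, record: PrescriptionRecord,
                       kb: KnowledgeBase) -> EvaluationOutcome:
    """Evaluate one predicate tree against a record (three-valued)."""
    return _Evaluator(record, kb).evaluate(p)


OMISSION = "omission"

_SEVERITY_RANK = {"caution": 0, "avoid": 1}


@dataclass
class Flag:
    criterion_id: str
    category: str
    severity: str  # avoid | caution | omission
    matched_order_ids: tuple[str, ...]
    rationale: str
    indeterminate_basis: bool = False


@dataclass
class Indeterminacy:
    criterion_id: str
    missing_inputs: tuple[str, ...]


@dataclass
class ScreeningResult:
    record_id: str
    flags: list[Flag]
    indeterminate_criteria: list[Indeterminacy]


def _screen_one(ev: _Evaluator, c: Criterion):
    """None = clean, Flag = flagged, Indeterminacy = unscreenable."""
    trig = ev.evaluate(c.trigger)
    if trig.status is Status.NOT_SATISFIED:
        return None

    exc = ev.evaluate(c.exception) if c.exception is not None else _NOT
    if exc.status is Status.SATISFIED:
        return None

    if c.category == "PPO":
        req = ev.evaluate(c.required_action)
        if req.status is Status.SATISFIED:
            return None
        missing = trig.missing_inputs + exc.missing_inputs + req.missing_inputs
        if Status.INDETERMINATE in {trig.status, exc.status, req.status}:
            return Indeterminacy(c.criterion_id, tuple(sorted(set(missing))))
        return Flag(c.criterion_id, "PPO", OMISSION, trig.matched_order_ids,
                    c.risk_text)

    # PIM
    if trig.status is Status.INDETERMINATE or exc.status is Status.INDETERMINATE:
        missing = trig.missing_inputs + exc.missing_inputs
        return Indeterminacy(c.criterion_id, tuple(sorted(set(missing))))

    best: Optional[str] = None
    clause_missing: list[str] = []
    for clause in c.severity_clauses:
        out = ev.evaluate(clause.predicate)
        if out.status is Status.SATISFIED:
            if best is None or _SEVERITY_RANK[clause.severity] > _SEVERITY_RANK[best]:
                best = clause.severity
        elif out.status is Status.INDETERMINATE:
            clause_missing.extend(out.missing_inputs)
    if best == "avoid" or (best == "caution" and not clause_missing):
        # an indeterminate clause can only upgrade caution -> avoid
        return Flag(c.criterion_id, "PIM", best, trig.matched_order_ids,
                    c.risk_text)
    if clause_missing:
        return Indeterminacy(c.criterion_id, tuple(sorted(set(clause_missing))))
    if best is not None:
        return Flag(c.criterion_id, "PIM", best, trig.matched_order_ids,
                    c.risk_text)
    return None


def screen_record(record: PrescriptionRecord, kb: KnowledgeBase) -> ScreeningResult:
    """Screen one record against every criterion; output ordered by id."""
    ev = _Evaluator(record, kb)
    flags: list[Flag] = []
    indeterminate: list[Indeterminacy] = []
    for c in sorted(kb.criteria, key=lambda c: c.criterion_id):
        res = _screen_one(ev, c)
        if isinstance(res, Flag):
            flags.append(res)
        elif isinstance(res, Indeterminacy):
            indeterminate.append(res)
    return ScreeningResult(record.record_id, flags, indeterminate)


@dataclass
class CohortSummary:
    n_records: int
    records_flagged: int
    prevalence: Optional[float]  # None for an empty cohort
    pim_flags: int
    ppo_flags: int
    per_criterion: dict[str, int] = field(default_factory=dict)
    indeterminate_per_criterion: dict[str, int] = field(default_factory=dict)


def screen_cohort(records: list[PrescriptionRecord],
                  kb: KnowledgeBase) -> tuple[list[ScreeningResult], CohortSummary]:
    seen: set[str] = set()
    for r in records:
        if r.record_id in seen:
            raise ValueError(f"duplicate record_id {r.record_id!r}")
        seen.add(r.record_id)
    results = [screen_record(r, kb) for r in records]
    per_criterion: dict[str, int] = {}
    indet: dict[str, int] = {}
    pim = ppo = flagged = 0
    for res in results:
        if res.flags:
            flagged += 1
        for f in res.flags:
            per_criterion[f.criterion_id] = per_criterion.get(f.criterion_id, 0) + 1
            if f.category == "PIM":
                pim += 1
            else:
                ppo += 1
        for i in res.indeterminate_criteria:
            indet[i.criterion_id] = indet.get(i.criterion_id, 0) + 1
    summary = CohortSummary(
        n_records=len(records),
        records_flagged=flagged,
        prevalence=(flagged / len(records)) if records else None,
        pim_flags=pim,
        ppo_flags=ppo,
        per_criterion=dict(sorted(per_criterion.items())),
        indeterminate_per_criterion=dict(sorted(indet.items())),
    )
    return results, summary
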
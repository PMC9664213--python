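"""Independent brute-force reference evaluator.

A direct recursive interpretation of each criterion written separately from
the screening engine: plain three-valued values (True / False / None for
indeterminate), its own dose arithmetic, and its own flag decision.  Any
divergence from the engine on a generated record is a bug in one of the two.
"""

from __future__ import annotations

from typing import Optional

TRUE, FALSE, INDET = True, False, None

_MASS = {"mg": 1.0, "g": 1000.0, "ug": 0.001, "µg": 0.001, "mcg": 0.001}
_DUR_DAYS = {"hours": 1 / 24, "days": 1.0, "weeks": 7.0, "months": 30.44}


def _mg(amount, unit):
    return amount * _MASS[unit.strip().lower().replace("μ", "µ")]


def _age_days(rec):
    p = rec.patient
    if p.age_days_at_encounter is not None:
        return p.age_days_at_encounter
    return (rec.encounter_date - p.birth_date).days


def _drug_orders(rec, kb, ref, route):
    """(exact, route_unknown) orders whose drug resolves to the reference."""
    ids = kb.lexicon.expand(ref)
    exact, unknown_route = [], []
    for o in rec.orders:
        if o.drug_id == "__unknown__" or o.drug_id not in ids:
            continue
        if route is None or o.route == route:
            exact.append(o)
        elif o.route is None:
            unknown_route.append(o)
    return exact, unknown_route


def _metric_value(order, rec, metric):
    """(value_in_mg, available) for a dose metric of one order."""
    weight = rec.patient.current_weight_kg
    per_dose = _mg(order.dose_amount, order.dose_unit) \
        if order.dose_amount is not None else None
    per_day = per_dose * order.frequency_per_day \
        if per_dose is not None and order.frequency_per_day is not None else None
    if metric == "per_dose":
        return per_dose
    if metric == "per_day":
        return per_day
    if metric == "per_kg_per_day":
        return per_day / weight if per_day is not None and weight else None
    if metric == "per_kg_per_hour":
        return per_day / weight / 24 if per_day is not None and weight else None
    cum = (_mg(order.cumulative_dose, order.cumulative_unit)
           if order.cumulative_dose is not None
           else (per_day * order.duration_days
                 if per_day is not None and order.duration_days is not None
                 else None))
    if metric == "cumulative_total":
        return cum
    if metric == "cumulative_per_kg":
        return cum / weight if cum is not None and weight else None
    raise AssertionError(metric)


def _exists(candidates, unknown_route, test):
    """Three-valued exists: True beats indeterminate beats False."""
    indet = bool(unknown_route)
    for o in candidates:
        v = test(o)
        if v is TRUE:
            return TRUE
        if v is INDET:
            indet = True
    return INDET if indet else FALSE


def _window_value(a, b, w):
    ta, tb = a.start_time, b.start_time
    if ta is None and tb is None:
        dt = 0.0
    elif ta is None or tb is None:
        return INDET
    else:
        dt = (tb - ta).total_seconds() / 3600.0
    if w.relation == "simultaneous":
        return dt == 0
    if w.relation == "within_after":
        return 0 <= dt <= w.after_hours
    if w.relation == "within_before":
        return 0 <= -dt <= w.before_hours
    gap_ok = (w.before_hours is not None and dt >= w.before_hours) or \
             (w.after_hours is not None and dt <= -w.after_hours)
    return not gap_ok


def ev(p, rec, kb) -> Optional[bool]:
    k = p.kind
    if k == "age_in_range":
        d = _age_days(rec)
        return d >= p.min_days and (p.max_days is None or d < p.max_days)
    if k == "gestational_age_below":
        ga = rec.patient.gestational_age_weeks
        return INDET if ga is None else ga < p.weeks
    if k == "birth_weight_below":
        bw = rec.patient.birth_weight_g
        return INDET if bw is None else bw < p.grams
    if k == "current_weight_below":
        w = rec.patient.current_weight_kg
        return INDET if w is None else w < p.kg
    if k == "is_premature":
        ga = rec.patient.gestational_age_weeks
        return INDET if ga is None else ga < 37
    if k == "sex_is":
        s = rec.patient.sex
        return INDET if s == "unknown" else s == p.sex
    if k == "drug_present":
        exact, maybe = _drug_orders(rec, kb, p.drug, p.route)
        if exact:
            return TRUE
        return INDET if maybe else FALSE
    if k == "dose_exceeds":
        thr = _mg(p.threshold, p.unit)
        exact, maybe = _drug_orders(rec, kb, p.drug, p.route)

        def test(o):
            v = _metric_value(o, rec, p.metric)
            if v is None:
                return INDET
            return v >= thr if p.inclusive else v > thr

        return _exists(exact, maybe, test)
    if k == "duration_exceeds":
        thr = p.value * _DUR_DAYS[p.unit]
        exact, maybe = _drug_orders(rec, kb, p.drug, None)

        def test(o):
            if o.duration_days is None:
                return INDET
            return (o.duration_days >= thr if p.inclusive
                    else o.duration_days > thr)

        return _exists(exact, maybe, test)
    if k == "frequency_per_day_below":
        exact, maybe = _drug_orders(rec, kb, p.drug, None)
        return _exists(exact, maybe,
                       lambda o: INDET if o.frequency_per_day is None
                       else o.frequency_per_day < p.per_day)
    if k == "doses_per_day_exceeds":
        exact, maybe = _drug_orders(rec, kb, p.drug, None)
        return _exists(exact, maybe,
                       lambda o: INDET if o.frequency_per_day is None
                       else o.frequency_per_day > p.per_day)
    if k == "co_prescribed":
        a_exact, a_maybe = _drug_orders(rec, kb, p.drug_a, p.route_a)
        b_exact, b_maybe = _drug_orders(rec, kb, p.drug_b, p.route_b)
        indet = False
        for a in a_exact:
            for b in b_exact:
                if a.order_id == b.order_id:
                    continue
                v = _window_value(a, b, p.window)
                if v is TRUE:
                    return TRUE
                if v is INDET:
                    indet = True
        if (a_exact or a_maybe) and (b_exact or b_maybe) and (a_maybe or b_maybe):
            indet = True
        return INDET if indet else FALSE
    if k == "distinct_drugs_at_least":
        exact, _ = _drug_orders(rec, kb, p.drug, None)
        return len({o.drug_id for o in exact}) >= p.count
    if k == "diagnosis_present":
        pt = rec.patient
        return p.tag in pt.diagnosis_tags or p.tag in pt.clinical_flags
    if k == "procedure_present":
        for pr in rec.procedures:
            if pr.procedure_tag != p.tag:
                continue
            if p.linked_drug is None or pr.linked_drug_id is None:
                return TRUE
            if pr.linked_drug_id in kb.lexicon.expand(p.linked_drug):
                return TRUE
        return FALSE
    if k == "all_of":
        vals = [ev(c, rec, kb) for c in p.children]
        if FALSE in vals:
            return FALSE
        return INDET if INDET in vals else TRUE
    if k == "any_of":
        vals = [ev(c, rec, kb) for c in p.children]
        if TRUE in vals:
            return TRUE
        return INDET if INDET in vals else FALSE
    if k == "not":
        v = ev(p.child, rec, kb)
        return INDET if v is INDET else (not v)
    raise AssertionError(k)


def oracle_screen(rec, kb):
    """(flags, indeterminate) criterion-id maps, by direct interpretation.

    ``flags`` maps criterion_id -> severity ('avoid'/'caution'/'omission').
    """
    flags: dict[str, str] = {}
    indeterminate: set[str] = set()
    for c in kb.criteria:
        t = ev(c.trigger, rec, kb)
        if t is FALSE:
            continue
        e = ev(c.exception, rec, kb) if c.exception is not None else FALSE
        if e is TRUE:
            continue
        if c.category == "PPO":
            r = ev(c.required_action, rec, kb)
            if r is TRUE:
                continue
            if INDET in (t, e, r):
                indeterminate.add(c.criterion_id)
            else:
                flags[c.criterion_id] = "omission"
            continue
        if t is INDET or e is INDET:
            indeterminate.add(c.criterion_id)
            continue
        clause_vals = [(ev(cl.predicate, rec, kb), cl.severity)
                       for cl in c.severity_clauses]
        if any(v is TRUE and s == "avoid" for v, s in clause_vals):
            flags[c.criterion_id] = "avoid"
        elif any(v is INDET for v, _ in clause_vals):
            indeterminate.add(c.criterion_id)
        elif any(v is TRUE for v, _ in clause_vals):
            flags[c.criterion_id] = "caution"
    return flags, indeterminate
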
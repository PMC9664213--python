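"""Screening-engine semantics: three-valued logic, windows, flag rules."""

import copy

import numpy as np
import pytest

from pedpip.engine import (
    Status, evaluate_predicate, screen_cohort, screen_record, within_window,
)
from pedpip.kb.dsl import required_gap, within_after
from pedpip.patients import ProcedureOrder
from conftest import make_order, make_record, random_record
from oracle import ev as oracle_ev, oracle_screen


def _criterion(kb, cid):
    return next(c for c in kb.criteria if c.criterion_id == cid)


class TestPredicateEvaluation:
    def test_aminophylline_dose_over_threshold(self, kb):
        # 150 mg/day over 14 kg = 10.71 mg/kg/d, just above the 10 mg/kg/d cutoff
        rec = make_record(age_days=1096, weight_kg=14.0,
                          orders=(make_order("aminophylline", dose=150, freq=1),))
        trig = _criterion(kb, "rs_aminophylline").trigger
        assert evaluate_predicate(trig, rec, kb).status is Status.SATISFIED

    def test_aminophylline_missing_weight_indeterminate(self, kb):
        rec = make_record(age_days=1096, weight_kg=None,
                          orders=(make_order("aminophylline", dose=150, freq=1),))
        out = evaluate_predicate(_criterion(kb, "rs_aminophylline").trigger,
                                 rec, kb)
        assert out.status is Status.INDETERMINATE
        assert "current_weight_kg" in out.missing_inputs

    def test_aminophylline_at_threshold_not_satisfied(self, kb):
        # exactly 10.0 mg/kg/d: the printed comparator is strict
        rec = make_record(age_days=1096, weight_kg=14.0,
                          orders=(make_order("aminophylline", dose=140, freq=1),))
        out = evaluate_predicate(_criterion(kb, "rs_aminophylline").trigger,
                                 rec, kb)
        assert out.status is Status.NOT_SATISFIED

    def test_drug_atom_on_empty_record_not_satisfied(self, kb):
        rec = make_record(orders=())
        for cid in ["ns_opioids", "rs_aminophylline", "ai_quinolones"]:
            out = evaluate_predicate(_criterion(kb, cid).trigger, rec, kb)
            assert out.status is Status.NOT_SATISFIED

    def test_unknown_drug_never_matches(self, kb):
        order = make_order("morphine")
        order = order.model_copy(update={"drug_id": "__unknown__"})
        rec = make_record(orders=(order,))
        out = evaluate_predicate(_criterion(kb, "ns_opioids").trigger, rec, kb)
        assert out.status is Status.NOT_SATISFIED


class TestTemporalWindows:
    def test_calcium_within_48h_of_ceftriaxone(self):
        a = make_order("ceftriaxone", route="intravenous", offset_hours=0)
        b = make_order("calcium_gluconate", route="intravenous", offset_hours=24)
        assert within_window(a, b, within_after(48)).status is Status.SATISFIED

    def test_calcium_beyond_48h_clean(self):
        a = make_order("ceftriaxone", offset_hours=0)
        b = make_order("calcium_gluconate", offset_hours=72)
        assert within_window(a, b, within_after(48)).status is Status.NOT_SATISFIED

    def test_window_boundary_inclusive(self):
        a = make_order("ceftriaxone", offset_hours=0)
        at48 = make_order("calcium_gluconate", offset_hours=48)
        at49 = make_order("calcium_gluconate", offset_hours=49)
        assert within_window(a, at48, within_after(48)).status is Status.SATISFIED
        assert within_window(a, at49, within_after(48)).status is Status.NOT_SATISFIED

    def test_ciprofloxacin_dtcc_gap_violation(self):
        # ciprofloxacin 4 h after the cation compound: needs >=6 h
        cipro = make_order("ciprofloxacin", offset_hours=0)
        dtcc = make_order("calcium_carbonate", offset_hours=-4)
        out = within_window(cipro, dtcc, required_gap(2, 6))
        assert out.status is Status.SATISFIED  # violation detected

    def test_ciprofloxacin_dtcc_gap_respected(self):
        cipro = make_order("ciprofloxacin", offset_hours=0)
        six_after = make_order("calcium_carbonate", offset_hours=-6)
        two_before = make_order("calcium_carbonate", offset_hours=2)
        assert within_window(cipro, six_after,
                             required_gap(2, 6)).status is Status.NOT_SATISFIED
        assert within_window(cipro, two_before,
                             required_gap(2, 6)).status is Status.NOT_SATISFIED

    def test_missing_timestamps(self):
        timed = make_order("ceftriaxone", offset_hours=0)
        untimed = make_order("calcium_gluconate", offset_hours=None)
        both_untimed = make_order("ceftriaxone", offset_hours=None)
        assert within_window(timed, untimed,
                             within_after(48)).status is Status.INDETERMINATE
        # both missing on one record: treated as simultaneous
        assert within_window(both_untimed, untimed,
                             within_after(48)).status is Status.SATISFIED


class TestFlagRules:
    def test_penicillin_without_skin_test_is_omission(self, kb):
        rec = make_record(age_days=1826,
                          orders=(make_order("penicillin_v"),))
        result = screen_record(rec, kb)
        assert "ai_penicillin_skin_test" in {f.criterion_id for f in result.flags}

    def test_penicillin_with_skin_test_clean(self, kb):
        rec = make_record(
            age_days=1826, orders=(make_order("penicillin_v"),),
            procedures=(ProcedureOrder(procedure_tag="skin_test"),))
        result = screen_record(rec, kb)
        assert "ai_penicillin_skin_test" not in {f.criterion_id
                                                 for f in result.flags}

    def test_laba_without_ics_is_omission(self, kb):
        rec = make_record(age_days=3652,  # a 10-year-old
                          orders=(make_order("salmeterol", route="inhaled"),))
        flags = {f.criterion_id: f for f in screen_record(rec, kb).flags}
        assert "sr_ics_with_laba" in flags
        assert flags["sr_ics_with_laba"].severity == "omission"

    def test_laba_with_ics_clean(self, kb):
        rec = make_record(age_days=3652,
                          orders=(make_order("salmeterol", route="inhaled"),
                                  make_order("budesonide", route="inhaled")))
        assert "sr_ics_with_laba" not in {f.criterion_id
                                          for f in screen_record(rec, kb).flags}

    def test_empty_record_zero_flags(self, kb):
        result = screen_record(make_record(orders=()), kb)
        assert result.flags == []

    def test_severity_dominance_avoid_beats_caution(self, kb):
        # dopamine antagonist in a 1-year-old matches both the avoid (<2 y)
        # and the caution (children) clauses
        rec = make_record(age_days=365, orders=(make_order("haloperidol"),))
        flags = {f.criterion_id: f for f in screen_record(rec, kb).flags}
        assert flags["ns_dopamine_antagonists"].severity == "avoid"
        older = make_record(age_days=3652, orders=(make_order("haloperidol"),))
        flags = {f.criterion_id: f for f in screen_record(older, kb).flags}
        assert flags["ns_dopamine_antagonists"].severity == "caution"

    def test_exception_suppresses_flag(self, kb):
        base = dict(age_days=1461, orders=(make_order("gentamicin",
                                                      route="intravenous"),))
        flagged = screen_record(make_record(**base), kb)
        assert "ai_aminoglycosides_under6" in {f.criterion_id
                                               for f in flagged.flags}
        excused = make_record(
            **base,
            procedures=(ProcedureOrder(procedure_tag="tdm",
                                       linked_drug_id="gentamicin"),))
        assert "ai_aminoglycosides_under6" not in {
            f.criterion_id for f in screen_record(excused, kb).flags}

    def test_flag_lists_are_disjoint_and_ordered(self, kb):
        rng = np.random.default_rng(11)
        for i in range(25):
            rec = random_record(rng, kb, f"d{i}")
            res = screen_record(rec, kb)
            flagged = [f.criterion_id for f in res.flags]
            indet = [i.criterion_id for i in res.indeterminate_criteria]
            assert not set(flagged) & set(indet)
            assert flagged == sorted(flagged)

    def test_determinism_identical_results(self, kb):
        rng = np.random.default_rng(5)
        rec = random_record(rng, kb, "det")
        assert screen_record(rec, kb) == screen_record(copy.deepcopy(rec), kb)


class TestCohortScreening:
    def test_prevalence_arithmetic(self, kb):
        flagged = make_record("f1", age_days=365,
                              orders=(make_order("haloperidol"),))
        clean = make_record("c1", orders=())
        _, summary = screen_cohort([flagged, clean], kb)
        assert summary.prevalence == 0.5
        assert summary.records_flagged == 1

    def test_empty_cohort_prevalence_not_applicable(self, kb):
        results, summary = screen_cohort([], kb)
        assert results == [] and summary.prevalence is None

    def test_duplicate_record_id_rejected(self, kb):
        rec = make_record("same")
        with pytest.raises(ValueError, match="duplicate"):
            screen_cohort([rec, copy.deepcopy(rec)], kb)


class TestOracleEquivalence:
    def test_engine_matches_brute_force_on_random_records(self, kb):
        rng = np.random.default_rng(2024)
        for i in range(1000):
            rec = random_record(rng, kb, f"r{i}")
            res = screen_record(rec, kb)
            got_flags = {f.criterion_id: f.severity for f in res.flags}
            got_indet = {x.criterion_id for x in res.indeterminate_criteria}
            want_flags, want_indet = oracle_screen(rec, kb)
            assert got_flags == want_flags, rec.record_id
            assert got_indet == want_indet, rec.record_id


class TestMonotonicity:
    def test_filling_missing_inputs_never_flips_definite_outcomes(self, kb):
        rng = np.random.default_rng(99)
        fills = {"current_weight_kg": 12.0, "gestational_age_weeks": 39.0,
                 "birth_weight_g": 3100.0}
        for i in range(120):
            rec = random_record(rng, kb, f"m{i}")
            before = {c.criterion_id:
                      evaluate_predicate(c.trigger, rec, kb).status
                      for c in kb.criteria}
            filled = rec.model_copy(deep=True)
            for attr, value in fills.items():
                if getattr(filled.patient, attr) is None:
                    setattr(filled.patient, attr, value)
            if filled.patient.sex == "unknown":
                filled.patient.sex = "female"
            for o in filled.orders:
                if o.frequency_per_day is None:
                    o.frequency_per_day = 2
                if o.start_time is None:
                    o.start_time = filled.orders[0].start_time
            after = {c.criterion_id:
                     evaluate_predicate(c.trigger, filled, kb).status
                     for c in kb.criteria}
            for cid, status in before.items():
                if status is not Status.INDETERMINATE:
                    assert after[cid] is status, cid
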
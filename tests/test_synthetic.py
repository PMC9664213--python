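"""Synthetic cohort generator: planting, boundaries, determinism, labels."""

import pytest

from pedpip.engine import screen_cohort, screen_record
from pedpip.simulate import (
    CohortConfig, ConfigError, NoNumericThresholdError, PlantSpec,
    full_sweep_plan, generate_cohort, plant_boundary_negative, plant_positive,
)


def _criterion(kb, cid):
    return next(c for c in kb.criteria if c.criterion_id == cid)


class TestPlantPositive:
    def test_midazolam_vlbw_neonate(self, kb):
        c = _criterion(kb, "ns_midazolam_vlbw")
        rec = plant_positive(c, kb)
        assert rec.patient.age_days_at_encounter <= 28
        assert rec.patient.birth_weight_g < 1500
        assert any(o.drug_id == "midazolam" for o in rec.orders)
        assert c.criterion_id in {f.criterion_id
                                  for f in screen_record(rec, kb).flags}

    def test_aminoglycoside_positive_and_exception_variant(self, kb):
        from pedpip.patients import ProcedureOrder
        c = _criterion(kb, "ai_aminoglycosides_under6")
        rec = plant_positive(c, kb)
        assert rec.patient.age_days_at_encounter < 6 * 365
        assert not rec.procedures  # no TDM, no resistant-TB tag
        assert "drug_resistant_tuberculosis" not in rec.patient.diagnosis_tags
        # adding the TDM exception makes the same record clean
        excused = rec.model_copy(deep=True)
        excused.procedures.append(
            ProcedureOrder(procedure_tag="tdm", linked_drug_id="amikacin"))
        assert c.criterion_id not in {f.criterion_id
                                      for f in screen_record(excused, kb).flags}

    def test_every_packaged_criterion_constructible(self, kb):
        for c in kb.criteria:
            rec = plant_positive(c, kb)  # raises PlantingError on failure
            flagged = {f.criterion_id for f in screen_record(rec, kb).flags}
            assert c.criterion_id in flagged, c.criterion_id


class TestPlantBoundaryNegative:
    def test_aminophylline_dose_exactly_at_cutoff(self, kb):
        c = _criterion(kb, "rs_aminophylline")
        rec = plant_boundary_negative(c, kb)
        order = next(o for o in rec.orders if o.drug_id == "aminophylline")
        per_kg = (order.dose_amount * order.frequency_per_day
                  / rec.patient.current_weight_kg)
        assert per_kg == pytest.approx(10.0)  # 10.0 is not > 10
        assert c.criterion_id not in {f.criterion_id
                                      for f in screen_record(rec, kb).flags}

    def test_under_two_years_criterion_at_second_birthday(self, kb):
        c = _criterion(kb, "ns_benzocaine")
        rec = plant_boundary_negative(c, kb)
        assert rec.patient.age_days_at_encounter == 730  # first excluded day

    def test_ceftriaxone_calcium_outside_window(self, kb):
        c = _criterion(kb, "ai_ceftriaxone_calcium")
        rec = plant_boundary_negative(c, kb)
        times = sorted(o.start_time for o in rec.orders)
        gap_hours = (times[-1] - times[0]).total_seconds() / 3600
        assert gap_hours == pytest.approx(49.0)

    def test_without_numeric_threshold_not_applicable(self, kb):
        with pytest.raises(NoNumericThresholdError):
            plant_boundary_negative(_criterion(kb, "cp_houttuynia"), kb)

    def test_all_boundary_negatives_clean_for_target(self, kb):
        n_constructed = 0
        for c in kb.criteria:
            try:
                rec = plant_boundary_negative(c, kb)
            except NoNumericThresholdError:
                continue
            n_constructed += 1
            flagged = {f.criterion_id for f in screen_record(rec, kb).flags}
            assert c.criterion_id not in flagged, c.criterion_id
        assert n_constructed >= 50  # most thresholds are numeric


class TestGenerateCohort:
    def test_seed_determinism(self, kb):
        cfg = CohortConfig(n_records=40, seed=7,
                           violation_plan=[PlantSpec("rs_aminophylline", 2, 1)])
        a, la = generate_cohort(cfg, kb)
        b, lb = generate_cohort(cfg, kb)
        assert a == b and la == lb

    def test_different_seeds_differ(self, kb):
        a, _ = generate_cohort(CohortConfig(n_records=40, seed=1), kb)
        b, _ = generate_cohort(CohortConfig(n_records=40, seed=2), kb)
        assert a != b

    def test_empty_violation_plan_empty_labels(self, kb):
        records, labels = generate_cohort(CohortConfig(n_records=10, seed=0), kb)
        assert len(records) == 10 and labels.labels == []

    def test_infeasible_plan_rejected(self, kb):
        cfg = CohortConfig(n_records=1, seed=0,
                           violation_plan=[PlantSpec("rs_aminophylline", 5)])
        with pytest.raises(ConfigError):
            generate_cohort(cfg, kb)

    def test_unknown_criterion_rejected(self, kb):
        cfg = CohortConfig(n_records=5, violation_plan=[PlantSpec("nope", 1)])
        with pytest.raises(ConfigError):
            generate_cohort(cfg, kb)

    def test_background_records_never_flag(self, kb):
        records, labels = generate_cohort(CohortConfig(n_records=60, seed=21), kb)
        results, summary = screen_cohort(records, kb)
        assert summary.records_flagged == 0

    def test_full_sweep_recall_and_boundary_specificity(self, kb):
        plan = full_sweep_plan(kb)
        assert len(plan) == 136
        cfg = CohortConfig(n_records=sum(p.count_positives +
                                         p.count_boundary_negatives
                                         for p in plan),
                           seed=3, violation_plan=plan)
        records, labels = generate_cohort(cfg, kb)
        results, _ = screen_cohort(records, kb)
        by_id = {r.record_id: r for r in results}
        missed = [
            (rid, cid)
            for rid, cids in labels.expected_flags().items()
            for cid in cids
            if cid not in {f.criterion_id for f in by_id[rid].flags}
        ]
        false_flags = [
            (rid, cid)
            for rid, cids in labels.expected_clean().items()
            for cid in cids
            if cid in {f.criterion_id for f in by_id[rid].flags}
        ]
        assert missed == []       # recall 1.0 over every packaged criterion
        assert false_flags == []  # boundary negatives stay clean
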
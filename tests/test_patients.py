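"""Age/dose normalization, drug canonicalization, CSV ingestion."""

from datetime import date

import pytest

from pedpip.patients import (
    MedicationOrder, PatientProfile, SchemaError, UnitError,
    canonicalize_drug, derive_age_profile, derive_dose_profile,
    read_prescriptions, write_prescriptions, UNKNOWN_DRUG,
)
from conftest import make_order, make_record


@pytest.mark.parametrize("days,neonate", [(0, True), (28, True), (29, False)])
def test_neonate_boundary(days, neonate):
    p = PatientProfile(patient_id="p", age_days_at_encounter=days)
    assert derive_age_profile(p).is_neonate is neonate


@pytest.mark.parametrize("ga,premature", [(30.0, True), (36.9, True),
                                          (37.0, False), (None, None)])
def test_prematurity_from_gestational_age(ga, premature):
    p = PatientProfile(patient_id="p", age_days_at_encounter=5,
                       gestational_age_weeks=ga)
    assert derive_age_profile(p).is_premature is premature


def test_age_from_birth_date_matches_age_days():
    by_days = PatientProfile(patient_id="a", age_days_at_encounter=365)
    by_date = PatientProfile(patient_id="b", birth_date=date(2023, 1, 15))
    at = date(2024, 1, 15)
    assert derive_age_profile(by_days, at).postnatal_days == \
        derive_age_profile(by_date, at).postnatal_days == 365


def test_negative_age_rejected():
    p = PatientProfile(patient_id="p", birth_date=date(2024, 6, 1))
    with pytest.raises(ValueError, match="negative"):
        derive_age_profile(p, date(2024, 1, 1))


def test_exactly_one_age_source_required():
    with pytest.raises(ValueError):
        PatientProfile(patient_id="p")
    with pytest.raises(ValueError):
        PatientProfile(patient_id="p", birth_date=date(2020, 1, 1),
                       age_days_at_encounter=100)


def test_dose_profile_arithmetic():
    patient = PatientProfile(patient_id="p", age_days_at_encounter=1000,
                             current_weight_kg=10.0)
    order = make_order("aminophylline", dose=100.0, freq=2)
    prof = derive_dose_profile(order, patient)
    assert prof.mg_per_dose == 100.0
    assert prof.mg_per_day == 200.0
    assert prof.mg_per_kg_per_day == pytest.approx(20.0)
    assert prof.mg_per_kg_per_hour == pytest.approx(20.0 / 24)


def test_dose_profile_missing_weight_names_input():
    patient = PatientProfile(patient_id="p", age_days_at_encounter=1000)
    prof = derive_dose_profile(make_order("x", dose=150.0, freq=1), patient)
    assert prof.mg_per_day == 150.0
    assert prof.mg_per_kg_per_day is None
    assert "current_weight_kg" in prof.missing_inputs


def test_dose_scale_invariance_g_vs_mg():
    patient = PatientProfile(patient_id="p", age_days_at_encounter=1000,
                             current_weight_kg=20.0)
    in_mg = derive_dose_profile(make_order("x", dose=100.0, unit="mg"), patient)
    in_g = derive_dose_profile(make_order("x", dose=0.1, unit="g"), patient)
    in_ug = derive_dose_profile(make_order("x", dose=100000.0, unit="ug"), patient)
    assert in_mg.mg_per_day == in_g.mg_per_day == in_ug.mg_per_day == 100.0
    assert in_mg.mg_per_kg_per_day == in_g.mg_per_kg_per_day


def test_cumulative_fallback_is_flagged_as_derived():
    patient = PatientProfile(patient_id="p", age_days_at_encounter=1000,
                             current_weight_kg=30.0)
    explicit = derive_dose_profile(
        make_order("thalidomide", dose=50, freq=1, cumulative=25000), patient)
    assert explicit.cumulative_mg == 25000 and not explicit.cumulative_is_derived
    derived = derive_dose_profile(
        make_order("thalidomide", dose=100, freq=2, duration_days=10), patient)
    assert derived.cumulative_mg == 2000 and derived.cumulative_is_derived


def test_unknown_mass_unit_raises():
    patient = PatientProfile(patient_id="p", age_days_at_encounter=10)
    with pytest.raises(UnitError):
        derive_dose_profile(make_order("x", dose=5, unit="furlongs"), patient)


@pytest.mark.parametrize("text,expected", [
    ("Erythromycin", "erythromycin"),
    ("ERYTHROMYCIN ", "erythromycin"),
    ("paracetamol", "acetaminophen"),
    ("Phenoxymethylpenicillin", "penicillin_v"),
    ("foomycin", UNKNOWN_DRUG),
])
def test_canonicalize_drug(kb, text, expected):
    assert canonicalize_drug(text, kb.lexicon) == expected


def _write_cohort_csvs(tmp_path, orders_extra=""):
    (tmp_path / "patients.csv").write_text(
        "patient_id,sex,age_days,gestational_age_weeks,birth_weight_g,"
        "weight_kg,diagnoses,flags\n"
        "p1,male,1461,40,3300,16,fever;pain,\n"
        "p2,female,14,31,1300,3.2,,\n"
        "p3,male,3000,,,30,,\n")
    (tmp_path / "orders.csv").write_text(
        "record_id,patient_id,drug,dose,dose_unit,freq_per_day,route,"
        "start_time,duration_days,cumulative_dose,cumulative_unit\n"
        "r1,p1,Ibuprofen,100,mg,2,oral,2024-01-15T08:00:00,3,,\n"
        "r2,p2,gentamicin,10,mg,1,intravenous,,5,,\n"
        "r3,p3,Erythromycin,250,mg,3,oral,2024-01-15T09:00:00,7,,\n"
        + orders_extra)
    (tmp_path / "procedures.csv").write_text(
        "record_id,procedure_tag,linked_drug,time\n"
        "r2,tdm,gentamicin,\n")


def test_read_prescriptions_clean_fixture(kb, tmp_path):
    _write_cohort_csvs(tmp_path)
    records, report = read_prescriptions(
        tmp_path / "patients.csv", tmp_path / "orders.csv",
        tmp_path / "procedures.csv", kb.lexicon)
    assert len(records) == 3 and report.ok
    by_id = {r.record_id: r for r in records}
    assert by_id["r1"].patient.diagnosis_tags == ["fever", "pain"]
    assert by_id["r2"].orders[0].drug_id == "gentamicin"
    assert by_id["r2"].procedures[0].procedure_tag == "tdm"


def test_read_prescriptions_bad_dose_is_reported_not_fatal(kb, tmp_path):
    _write_cohort_csvs(tmp_path,
                       orders_extra="r1,p1,Ibuprofen,abc,mg,1,oral,,,,\n")
    records, report = read_prescriptions(
        tmp_path / "patients.csv", tmp_path / "orders.csv",
        tmp_path / "procedures.csv", kb.lexicon)
    assert len(records) == 3
    assert any("unparseable dose" in p for p in report.problems)


def test_read_prescriptions_missing_column_fatal(kb, tmp_path):
    _write_cohort_csvs(tmp_path)
    (tmp_path / "patients.csv").write_text("sex,age_days\nmale,100\n")
    with pytest.raises(SchemaError, match="patient_id"):
        read_prescriptions(tmp_path / "patients.csv", tmp_path / "orders.csv",
                           None, kb.lexicon)


def test_unknown_drug_marked_and_reported(kb, tmp_path):
    _write_cohort_csvs(tmp_path, orders_extra="r1,p1,foomycin,5,mg,1,oral,,,,\n")
    records, report = read_prescriptions(
        tmp_path / "patients.csv", tmp_path / "orders.csv", None, kb.lexicon)
    assert "foomycin" in report.unknown_drugs
    r1 = next(r for r in records if r.record_id == "r1")
    assert any(o.drug_id == UNKNOWN_DRUG for o in r1.orders)


def test_ingestion_round_trip_lossless(kb, tmp_path):
    rec = make_record(
        "rt1", age_days=100, weight_kg=5.5, diagnoses=("fever",),
        orders=(make_order("gentamicin", dose=12.5, freq=2,
                           route="intravenous", duration_days=5),),
    )
    write_prescriptions([rec], tmp_path / "p.csv", tmp_path / "o.csv",
                        tmp_path / "c.csv")
    back, report = read_prescriptions(tmp_path / "p.csv", tmp_path / "o.csv",
                                      tmp_path / "c.csv", kb.lexicon)
    assert report.ok and len(back) == 1
    b = back[0]
    assert b.patient.model_dump(exclude={"patient_id"}) == \
        rec.patient.model_dump(exclude={"patient_id"})
    fields = {"drug_id", "dose_amount", "dose_unit", "frequency_per_day",
              "route", "start_time", "duration_days"}
    assert [o.model_dump(include=fields) for o in b.orders] == \
        [o.model_dump(include=fields) for o in rec.orders]
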
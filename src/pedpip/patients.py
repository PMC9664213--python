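"""Prescription records and normalization of ages, weights, doses, drugs.

The screening predicates consume derived quantities (postnatal days,
mg/kg/day, canonical drug ids); this module owns the conventions that
produce them.  Missing inputs are carried along by name rather than raised,
so that the engine can report which criteria were unscreenable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .kb.model import DrugLexicon, Route

UNKNOWN_DRUG = "__unknown__"

_MASS_TO_MG = {"mg": 1.0, "g": 1000.0, "µg": 0.001, "ug": 0.001, "mcg": 0.001}
_DURATION_TO_DAYS = {"hours": 1 / 24, "days": 1.0, "weeks": 7.0, "months": 30.44}

ROUTES = {"oral", "intravenous", "intramuscular", "nasal", "topical",
          "rectal", "ophthalmic", "inhaled", "other"}


class UnitError(ValueError):
    """Unknown mass unit on a dose."""


def mass_to_mg(amount: float, unit: str) -> float:
    try:
        return amount * _MASS_TO_MG[unit.strip().lower().replace("μ", "µ")]
    except KeyError:
        raise UnitError(f"unknown mass unit {unit!r}") from None


def duration_to_days(value: float, unit: str) -> float:
    return value * _DURATION_TO_DAYS[unit]


class PatientProfile(BaseModel):
    patient_id: str
    sex: str = "unknown"  # male | female | unknown
    birth_date: Optional[date] = None
    age_days_at_encounter: Optional[int] = Field(default=None, ge=0)
    gestational_age_weeks: Optional[float] = Field(default=None, gt=0)
    birth_weight_g: Optional[float] = Field(default=None, gt=0)
    current_weight_kg: Optional[float] = Field(default=None, gt=0)
    diagnosis_tags: list[str] = Field(default_factory=list)
    clinical_flags: list[str] = Field(default_factory=list)

    @model_validator(mode="after")
    def _one_age_source(self) -> "PatientProfile":
        if (self.birth_date is None) == (self.age_days_at_encounter is None):
            raise ValueError(
                "exactly one of birth_date / age_days_at_encounter required"
            )
        return self


class MedicationOrder(BaseModel):
    order_id: str
    drug_text: str
    drug_id: str = UNKNOWN_DRUG
    dose_amount: Optional[float] = Field(default=None, ge=0)
    dose_unit: str = "mg"
    frequency_per_day: Optional[int] = Field(default=None, ge=1)
    route: Optional[Route] = None
    start_time: Optional[datetime] = None
    duration_days: Optional[float] = Field(default=None, ge=0)
    cumulative_dose: Optional[float] = Field(default=None, ge=0)
    cumulative_unit: str = "mg"


class ProcedureOrder(BaseModel):
    procedure_tag: str
    linked_drug_id: Optional[str] = None
    time: Optional[datetime] = None


class PrescriptionRecord(BaseModel):
    record_id: str
    encounter_date: Optional[date] = None
    patient: PatientProfile
    orders: list[MedicationOrder] = Field(default_factory=list)
    procedures: list[ProcedureOrder] = Field(default_factory=list)


@dataclass(frozen=True)
class AgeProfile:
    postnatal_days: int
    age_years: float
    is_neonate: bool
    is_premature: Optional[bool]  # None when gestational age unknown


@dataclass
class DoseProfile:
    """Derived dose quantities in mg; None = not derivable.

    ``missing_inputs`` names the patient/order fields whose absence blocked
    a derivation (per-kg metrics need the current weight, cumulative
    fallback needs frequency and duration).
    """

    mg_per_dose: Optional[float] = None
    mg_per_day: Optional[float] = None
    mg_per_kg_per_day: Optional[float] = None
    mg_per_kg_per_hour: Optional[float] = None
    cumulative_mg: Optional[float] = None
    cumulative_mg_per_kg: Optional[float] = None
    cumulative_is_derived: bool = False
    missing_inputs: list[str] = field(default_factory=list)


def derive_age_profile(patient: PatientProfile, at: Optional[date] = None) -> AgeProfile:
    """Postnatal age at the encounter, plus neonate/premature status.

    A neonate is postnatal age <=28 days.  Premature means gestational age
    at birth <37 weeks; unknown gestational age leaves it undetermined.
    """
    if patient.age_days_at_encounter is not None:
        days = patient.age_days_at_encounter
    else:
        if at is None:
            raise ValueError("encounter date required with birth_date ages")
        days = (at - patient.birth_date).days
    if days < 0:
        raise ValueError(f"negative derived age for {patient.patient_id}")
    premature: Optional[bool] = None
    if patient.gestational_age_weeks is not None:
        premature = patient.gestational_age_weeks < 37
    return AgeProfile(
        postnatal_days=days,
        age_years=days / 365.25,
        is_neonate=days <= 28,
        is_premature=premature,
    )


def derive_dose_profile(order: MedicationOrder, patient: PatientProfile) -> DoseProfile:
    """All derivable dose quantities for one order, normalized to mg.

    Rate metrics assume the prescribed daily amount is spread over 24 h.
    The cumulative amount falls back to dose x frequency x duration when no
    explicit cumulative dose was recorded; the fallback is flagged via
    ``cumulative_is_derived``.
    """
    prof = DoseProfile()
    weight = patient.current_weight_kg

    if order.dose_amount is not None:
        prof.mg_per_dose = mass_to_mg(order.dose_amount, order.dose_unit)
        if order.frequency_per_day is not None:
            prof.mg_per_day = prof.mg_per_dose * order.frequency_per_day
        else:
            prof.missing_inputs.append("frequency_per_day")
    else:
        prof.missing_inputs.append("dose_amount")

    if prof.mg_per_day is not None:
        if weight is not None:
            prof.mg_per_kg_per_day = prof.mg_per_day / weight
            prof.mg_per_kg_per_hour = prof.mg_per_kg_per_day / 24
        else:
            prof.missing_inputs.append("current_weight_kg")

    if order.cumulative_dose is not None:
        prof.cumulative_mg = mass_to_mg(order.cumulative_dose, order.cumulative_unit)
    elif prof.mg_per_day is not None and order.duration_days is not None:
        prof.cumulative_mg = prof.mg_per_day * order.duration_days
        prof.cumulative_is_derived = True
    elif order.duration_days is None:
        prof.missing_inputs.append("duration_days")

    if prof.cumulative_mg is not None:
        if weight is not None:
            prof.cumulative_mg_per_kg = prof.cumulative_mg / weight
        elif "current_weight_kg" not in prof.missing_inputs:
            prof.missing_inputs.append("current_weight_kg")
    return prof


def canonicalize_drug(text: str, lexicon: DrugLexicon) -> str:
    """Case-insensitive exact synonym match; unknown names map to the
    unknown marker (never an exception)."""
    return lexicon.synonym_index().get(text.strip().casefold(), UNKNOWN_DRUG)


@dataclass
class IngestionReport:
    problems: list[str] = field(default_factory=list)
    unknown_drugs: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.problems


class SchemaError(ValueError):
    """A mandatory column is missing from an input CSV."""


PATIENT_COLUMNS = {"patient_id", "sex"}
ORDER_COLUMNS = {"record_id", "patient_id", "drug", "dose", "dose_unit",
                 "freq_per_day", "route"}
PROCEDURE_COLUMNS = {"record_id", "procedure_tag"}


def _require(df: pd.DataFrame, needed: set[str], name: str) -> None:
    missing = needed - set(df.columns)
    if missing:
        raise SchemaError(f"{name} missing mandatory columns: {sorted(missing)}")


def _opt(row: pd.Series, col: str):
    if col not in row.index:
        return None
    v = row[col]
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return v


def _split_tags(value) -> list[str]:
    if value is None:
        return []
    return [t.strip() for t in str(value).split(";") if t.strip()]


def read_prescriptions(
    patients_csv: str | Path,
    orders_csv: str | Path,
    procedures_csv: Optional[str | Path],
    lexicon: DrugLexicon,
    encounter_date: Optional[date] = None,
) -> tuple[list[PrescriptionRecord], IngestionReport]:
    """Build prescription records from the documented CSV trio.

    Per-row problems (unparseable dose, unknown drug, unknown route) are
    collected in the report, not raised; only a missing mandatory column is
    fatal.  Every patient yields one record; ``record_id`` is taken from the
    order rows when present, else derived from the patient id.
    """
    report = IngestionReport()
    patients = pd.read_csv(patients_csv, dtype=str)
    orders = pd.read_csv(orders_csv, dtype=str)
    _require(patients, PATIENT_COLUMNS, "patients.csv")
    _require(orders, ORDER_COLUMNS, "orders.csv")
    if not ({"age_days", "birth_date"} & set(patients.columns)):
        raise SchemaError("patients.csv needs an age_days or birth_date column")
    procs = None
    if procedures_csv is not None:
        procs = pd.read_csv(procedures_csv, dtype=str)
        _require(procs, PROCEDURE_COLUMNS, "procedures.csv")

    synonyms = lexicon.synonym_index()
    profiles: dict[str, PatientProfile] = {}
    for _, row in patients.iterrows():
        pid = str(row["patient_id"])
        age_days = _opt(row, "age_days")
        birth = _opt(row, "birth_date")
        try:
            profiles[pid] = PatientProfile(
                patient_id=pid,
                sex=_opt(row, "sex") or "unknown",
                birth_date=date.fromisoformat(birth) if birth and age_days is None else None,
                age_days_at_encounter=int(float(age_days)) if age_days is not None else None,
                gestational_age_weeks=(lambda v: float(v) if v else None)(_opt(row, "gestational_age_weeks")),
                birth_weight_g=(lambda v: float(v) if v else None)(_opt(row, "birth_weight_g")),
                current_weight_kg=(lambda v: float(v) if v else None)(_opt(row, "weight_kg")),
                diagnosis_tags=_split_tags(_opt(row, "diagnoses")),
                clinical_flags=_split_tags(_opt(row, "flags")),
            )
        except Exception as exc:
            report.problems.append(f"patients.csv {pid}: {exc}")

    record_ids: dict[str, str] = {}
    orders_by_patient: dict[str, list[MedicationOrder]] = {p: [] for p in profiles}
    for i, row in orders.iterrows():
        pid = str(row["patient_id"])
        if pid not in profiles:
            report.problems.append(f"orders.csv row {i}: unknown patient {pid!r}")
            continue
        record_ids.setdefault(pid, str(row["record_id"]))
        drug_text = str(row["drug"])
        drug_id = synonyms.get(drug_text.strip().casefold(), UNKNOWN_DRUG)
        if drug_id == UNKNOWN_DRUG:
            report.unknown_drugs.append(drug_text)
        dose = _opt(row, "dose")
        try:
            dose_val = float(dose) if dose is not None else None
        except ValueError:
            report.problems.append(f"orders.csv row {i}: unparseable dose {dose!r}")
            dose_val = None
        route = _opt(row, "route")
        if route is not None and route not in ROUTES:
            report.problems.append(f"orders.csv row {i}: unknown route {route!r}")
            route = "other"
        freq = _opt(row, "freq_per_day")
        start = _opt(row, "start_time")
        dur = _opt(row, "duration_days")
        cum = _opt(row, "cumulative_dose")
        try:
            orders_by_patient[pid].append(MedicationOrder(
                order_id=f"{pid}-o{i}",
                drug_text=drug_text,
                drug_id=drug_id,
                dose_amount=dose_val,
                dose_unit=_opt(row, "dose_unit") or "mg",
                frequency_per_day=int(float(freq)) if freq is not None else None,
                route=route,
                start_time=datetime.fromisoformat(start) if start else None,
                duration_days=float(dur) if dur is not None else None,
                cumulative_dose=float(cum) if cum is not None else None,
                cumulative_unit=_opt(row, "cumulative_unit") or "mg",
            ))
        except Exception as exc:
            report.problems.append(f"orders.csv row {i}: {exc}")

    procs_by_patient: dict[str, list[ProcedureOrder]] = {p: [] for p in profiles}
    rid_to_pid = {rid: pid for pid, rid in record_ids.items()}
    if procs is not None:
        for i, row in procs.iterrows():
            rid = str(row["record_id"])
            pid = rid_to_pid.get(rid, rid.removeprefix("R-"))
            if pid not in profiles:
                report.problems.append(f"procedures.csv row {i}: unknown record {rid!r}")
                continue
            t = _opt(row, "time")
            procs_by_patient[pid].append(ProcedureOrder(
                procedure_tag=str(row["procedure_tag"]),
                linked_drug_id=_opt(row, "linked_drug"),
                time=datetime.fromisoformat(t) if t else None,
            ))

    records = [
        PrescriptionRecord(
            record_id=record_ids.get(pid, f"R-{pid}"),
            encounter_date=encounter_date,
            patient=prof,
            orders=orders_by_patient[pid],
            procedures=procs_by_patient[pid],
        )
        for pid, prof in profiles.items()
    ]
    return records, report


def write_prescriptions(
    records: list[PrescriptionRecord],
    patients_csv: str | Path,
    orders_csv: str | Path,
    procedures_csv: str | Path,
) -> None:
    """Serialize records back to the CSV trio (inverse of read_prescriptions)."""
    prows, orows, crows = [], [], []
    for rec in records:
        p = rec.patient
        prows.append({
            "patient_id": p.patient_id, "sex": p.sex,
            "age_days": p.age_days_at_encounter,
            "gestational_age_weeks": p.gestational_age_weeks,
            "birth_weight_g": p.birth_weight_g,
            "weight_kg": p.current_weight_kg,
            "diagnoses": ";".join(p.diagnosis_tags),
            "flags": ";".join(p.clinical_flags),
        })
        for o in rec.orders:
            orows.append({
                "record_id": rec.record_id, "patient_id": p.patient_id,
                "drug": o.drug_text, "dose": o.dose_amount,
                "dose_unit": o.dose_unit, "freq_per_day": o.frequency_per_day,
                "route": o.route,
                "start_time": o.start_time.isoformat() if o.start_time else None,
                "duration_days": o.duration_days,
                "cumulative_dose": o.cumulative_dose,
                "cumulative_unit": o.cumulative_unit if o.cumulative_dose is not None else None,
            })
        for pr in rec.procedures:
            crows.append({
                "record_id": rec.record_id,
                "procedure_tag": pr.procedure_tag,
                "linked_drug": pr.linked_drug_id,
                "time": pr.time.isoformat() if pr.time else None,
            })
    pcols = ["patient_id", "sex", "age_days", "gestational_age_weeks",
             "birth_weight_g", "weight_kg", "diagnoses", "flags"]
    pd.DataFrame(prows, columns=pcols).to_csv(patients_csv, index=False)
    cols = ["record_id", "patient_id", "drug", "dose", "dose_unit",
            "freq_per_day", "route", "start_time", "duration_days",
            "cumulative_dose", "cumulative_unit"]
    pd.DataFrame(orows, columns=cols).to_csv(orders_csv, index=False)
    pd.DataFrame(crows, columns=["record_id", "procedure_tag", "linked_drug",
                                 "time"]).to_csv(procedures_csv, index=False)
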
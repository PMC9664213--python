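from __future__ import annotations

from datetime import date, datetime, timedelta
from typing import Optional

import numpy as np
import pytest

from pedpip import packaged_kb
from pedpip.patients import (
    MedicationOrder, PatientProfile, PrescriptionRecord, ProcedureOrder,
)

BASE_TIME = datetime(2024, 1, 15, 8, 0)


@pytest.fixture(scope="session")
def kb():
    return packaged_kb()


def make_record(
    record_id: str = "R1",
    age_days: int = 1461,
    sex: str = "male",
    weight_kg: Optional[float] = 16.0,
    ga_weeks: Optional[float] = 40.0,
    birth_weight_g: Optional[float] = 3300.0,
    diagnoses: tuple[str, ...] = (),
    orders: tuple[MedicationOrder, ...] = (),
    procedures: tuple[ProcedureOrder, ...] = (),
) -> PrescriptionRecord:
    return PrescriptionRecord(
        record_id=record_id,
        encounter_date=date(2024, 1, 15),
        patient=PatientProfile(
            patient_id=record_id, sex=sex, age_days_at_encounter=age_days,
            gestational_age_weeks=ga_weeks, birth_weight_g=birth_weight_g,
            current_weight_kg=weight_kg, diagnosis_tags=list(diagnoses),
        ),
        orders=list(orders),
        procedures=list(procedures),
    )


def make_order(
    drug_id: str,
    dose: Optional[float] = 100.0,
    unit: str = "mg",
    freq: Optional[int] = 1,
    route: Optional[str] = "oral",
    offset_hours: Optional[float] = 0.0,
    duration_days: Optional[float] = 3.0,
    cumulative: Optional[float] = None,
    order_id: Optional[str] = None,
) -> MedicationOrder:
    return MedicationOrder(
        order_id=order_id or f"o-{drug_id}",
        drug_text=drug_id,
        drug_id=drug_id,
        dose_amount=dose,
        dose_unit=unit,
        frequency_per_day=freq,
        route=route,
        start_time=(BASE_TIME + timedelta(hours=offset_hours)
                    if offset_hours is not None else None),
        duration_days=duration_days,
        cumulative_dose=cumulative,
    )


_SOME_TAGS = [
    "fever", "pain", "asthma", "acute_uri", "uri_symptoms_lt_4_days",
    "diarrhea", "dehydration", "acute_otitis_media", "epilepsy",
    "nocturnal_enuresis", "adhd", "depression", "acne", "impetigo",
    "scabies", "atopic_eczema", "bronchiolitis", "acute_cough",
    "gastroesophageal_reflux", "nausea_or_vomiting", "migraine",
    "tuberculosis", "cystic_fibrosis", "immunocompromised",
    "suspected_viral_infection", "respiratory_infection",
]

_SOME_PROCS = ["tdm", "skin_test", "cyp2d6_test", "iv_bolus", "repeat_dose"]

_ROUTES = ["oral", "intravenous", "topical", "rectal", "nasal", "inhaled",
           "ophthalmic", None]


def random_record(rng: np.random.Generator, kb, record_id: str) -> PrescriptionRecord:
    """A random (often messy) pediatric record exercising missing-data paths."""
    drug_pool = sorted(kb.lexicon.drug_ids())
    age = int(rng.integers(0, 6574))
    n_orders = int(rng.integers(0, 5))
    orders = []
    for i in range(n_orders):
        drug_id = str(rng.choice(drug_pool))
        orders.append(MedicationOrder(
            order_id=f"{record_id}-o{i}",
            drug_text=drug_id,
            drug_id=drug_id if rng.random() < 0.95 else "__unknown__",
            dose_amount=float(rng.choice([5, 20, 100, 500, 2000, 60000]))
            if rng.random() < 0.9 else None,
            dose_unit=str(rng.choice(["mg", "g", "ug"])),
            frequency_per_day=int(rng.integers(1, 6)) if rng.random() < 0.85 else None,
            route=rng.choice(_ROUTES),
            start_time=(BASE_TIME + timedelta(hours=float(rng.integers(-96, 96)))
                        if rng.random() < 0.6 else None),
            duration_days=float(rng.integers(1, 400)) if rng.random() < 0.7 else None,
            cumulative_dose=float(rng.choice([100, 5000, 30000]))
            if rng.random() < 0.15 else None,
        ))
    n_tags = int(rng.integers(0, 4))
    tags = sorted(set(str(t) for t in rng.choice(_SOME_TAGS, size=n_tags)))
    procedures = []
    if rng.random() < 0.3:
        procedures.append(ProcedureOrder(
            procedure_tag=str(rng.choice(_SOME_PROCS)),
            linked_drug_id=str(rng.choice(drug_pool)) if rng.random() < 0.5 else None,
        ))
    return PrescriptionRecord(
        record_id=record_id,
        encounter_date=date(2024, 1, 15),
        patient=PatientProfile(
            patient_id=record_id,
            sex=str(rng.choice(["male", "female", "unknown"])),
            age_days_at_encounter=age,
            gestational_age_weeks=float(rng.uniform(25, 42))
            if rng.random() < 0.6 else None,
            birth_weight_g=float(rng.uniform(900, 4200))
            if rng.random() < 0.6 else None,
            current_weight_kg=round(float(rng.uniform(1.5, 70)), 1)
            if rng.random() < 0.8 else None,
            diagnosis_tags=tags,
        ),
        orders=orders,
        procedures=procedures,
    )
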
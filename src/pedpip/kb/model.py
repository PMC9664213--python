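"""Machine-readable knowledge base of pediatric prescribing criteria.

The knowledge base holds explicit screening rules of two categories:

* **PIM** (potentially inappropriate medication): a drug order whose risks
  are judged to outweigh its benefits in a given pediatric context (wrong
  age band, dose, duration, route, interaction, or diagnosis).
* **PPO** (potential prescribing omission): a clearly beneficial drug or
  action (skin test, therapeutic drug monitoring, a controller inhaler)
  that is absent from the record although its trigger context is present.

Each criterion is a small declarative program: a *trigger* predicate, an
optional *exception* predicate, and either severity clauses (PIM) or a
*required action* predicate (PPO).  Predicates form a finite tree of typed
atoms combined with ``all_of`` / ``any_of`` / ``not``; every drug, drug
class and condition tag they mention must resolve against the packaged
lexicon and vocabulary.
"""

from __future__ import annotations

import json
from collections import Counter
from pathlib import Path
from typing import Annotated, Literal, Optional, Union

import yaml
from pydantic import BaseModel, Field, model_validator

SCHEMA_VERSION = "1.0"

Severity = Literal["avoid", "caution"]
Category = Literal["PIM", "PPO"]
Part = Literal["non_specific", "specific"]
Route = Literal[
    "oral", "intravenous", "intramuscular", "nasal", "topical",
    "rectal", "ophthalmic", "inhaled", "other",
]
DoseMetric = Literal[
    "per_kg_per_day", "per_day", "per_dose", "per_kg_per_hour",
    "cumulative_total", "cumulative_per_kg",
]
DurationUnit = Literal["hours", "days", "weeks", "months"]


class TemporalWindow(BaseModel):
    """Timing relation between two orders of an interacting pair.

    ``within_after``: the second drug starts no more than ``after_hours``
    after the first.  ``within_before`` mirrors it.  ``simultaneous`` means
    concomitant prescribing on the same record.
    ``required_gap_before_and_after`` encodes separation rules such as
    "take at least 2 h before or 6 h after": the window is *violated*
    (and the atom satisfied) when neither gap is respected.
    """

    relation: Literal[
        "within_after", "within_before", "simultaneous",
        "required_gap_before_and_after",
    ]
    before_hours: Optional[float] = Field(default=None, ge=0)
    after_hours: Optional[float] = Field(default=None, ge=0)

    @model_validator(mode="after")
    def _bounds(self) -> "TemporalWindow":
        if self.relation != "simultaneous" and (
            self.before_hours is None and self.after_hours is None
        ):
            raise ValueError(f"window {self.relation!r} needs at least one bound")
        return self


class AgeInRange(BaseModel):
    """Postnatal age in [min_days, max_days); open-ended when max is None."""

    kind: Literal["age_in_range"] = "age_in_range"
    min_days: int = Field(default=0, ge=0)
    max_days: Optional[int] = Field(default=None, ge=1)


class GestationalAgeBelow(BaseModel):
    kind: Literal["gestational_age_below"] = "gestational_age_below"
    weeks: float = Field(gt=0)


class BirthWeightBelow(BaseModel):
    kind: Literal["birth_weight_below"] = "birth_weight_below"
    grams: float = Field(gt=0)


class CurrentWeightBelow(BaseModel):
    kind: Literal["current_weight_below"] = "current_weight_below"
    kg: float = Field(gt=0)


class IsPremature(BaseModel):
    kind: Literal["is_premature"] = "is_premature"


class SexIs(BaseModel):
    kind: Literal["sex_is"] = "sex_is"
    sex: Literal["male", "female"]


class DrugPresent(BaseModel):
    """An order for the drug (or any member of the class), optionally by route."""

    kind: Literal["drug_present"] = "drug_present"
    drug: str
    route: Optional[Route] = None


class DoseExceeds(BaseModel):
    """Some order of ``drug`` exceeds ``threshold`` on the given metric.

    Strictness follows the printed comparator: ``inclusive=False`` means
    strictly greater (">10 mg/kg/d"), ``inclusive=True`` means ">=".
    """

    kind: Literal["dose_exceeds"] = "dose_exceeds"
    drug: str
    metric: DoseMetric
    threshold: float = Field(gt=0)
    unit: str = "mg"
    inclusive: bool = False
    route: Optional[Route] = None


class DurationExceeds(BaseModel):
    kind: Literal["duration_exceeds"] = "duration_exceeds"
    drug: str
    value: float = Field(gt=0)
    unit: DurationUnit = "days"
    inclusive: bool = False


class FrequencyPerDayBelow(BaseModel):
    """Some order of ``drug`` has daily frequency strictly below ``per_day``."""

    kind: Literal["frequency_per_day_below"] = "frequency_per_day_below"
    drug: str
    per_day: int = Field(ge=1)


class DosesPerDayExceeds(BaseModel):
    """Some order of ``drug`` has daily frequency strictly above ``per_day``."""

    kind: Literal["doses_per_day_exceeds"] = "doses_per_day_exceeds"
    drug: str
    per_day: int = Field(ge=1)


class CoPrescribed(BaseModel):
    """Orders for ``drug_a`` and ``drug_b`` related by the temporal window."""

    kind: Literal["co_prescribed"] = "co_prescribed"
    drug_a: str
    drug_b: str
    window: TemporalWindow
    route_a: Optional[Route] = None
    route_b: Optional[Route] = None


class DistinctDrugsAtLeast(BaseModel):
    """At least ``count`` distinct drugs of a class on the record."""

    kind: Literal["distinct_drugs_at_least"] = "distinct_drugs_at_least"
    drug: str
    count: int = Field(ge=2)


class DiagnosisPresent(BaseModel):
    kind: Literal["diagnosis_present"] = "diagnosis_present"
    tag: str


class ProcedurePresent(BaseModel):
    kind: Literal["procedure_present"] = "procedure_present"
    tag: str
    linked_drug: Optional[str] = None


class AllOf(BaseModel):
    kind: Literal["all_of"] = "all_of"
    children: list["Predicate"] = Field(min_length=1)


class AnyOf(BaseModel):
    kind: Literal["any_of"] = "any_of"
    children: list["Predicate"] = Field(min_length=1)


class Not(BaseModel):
    kind: Literal["not"] = "not"
    child: "Predicate"


Predicate = Annotated[
    Union[
        AgeInRange, GestationalAgeBelow, BirthWeightBelow, CurrentWeightBelow,
        IsPremature, SexIs, DrugPresent, DoseExceeds, DurationExceeds,
        FrequencyPerDayBelow, DosesPerDayExceeds, CoPrescribed,
        DistinctDrugsAtLeast, DiagnosisPresent, ProcedurePresent,
        AllOf, AnyOf, Not,
    ],
    Field(discriminator="kind"),
]

AllOf.model_rebuild()
AnyOf.model_rebuild()
Not.model_rebuild()


class SeverityClause(BaseModel):
    predicate: Predicate
    severity: Severity


class Provenance(BaseModel):
    table: str
    row_label: str
    note: Optional[str] = None


class Criterion(BaseModel):
    criterion_id: str
    part: Part
    category: Category
    group: str
    subgroup: Optional[str] = None
    trigger: Predicate
    exception: Optional[Predicate] = None
    required_action: Optional[Predicate] = None
    severity_clauses: list[SeverityClause] = Field(default_factory=list)
    risk_text: str = ""
    provenance: Provenance

    @model_validator(mode="after")
    def _category_shape(self) -> "Criterion":
        if self.category == "PPO":
            if self.required_action is None:
                raise ValueError(f"{self.criterion_id}: PPO requires required_action")
            if self.severity_clauses:
                raise ValueError(f"{self.criterion_id}: PPO carries no severity clauses")
        else:
            if not self.severity_clauses:
                raise ValueError(f"{self.criterion_id}: PIM requires >=1 severity clause")
            if self.required_action is not None:
                raise ValueError(f"{self.criterion_id}: PIM carries no required_action")
        return self


class DrugEntry(BaseModel):
    canonical_id: str
    label: str
    synonyms: list[str] = Field(default_factory=list)


class DrugClass(BaseModel):
    class_id: str
    label: str
    member_ids: list[str]


class DrugLexicon(BaseModel):
    drugs: list[DrugEntry]
    classes: list[DrugClass]

    def drug_ids(self) -> set[str]:
        return {d.canonical_id for d in self.drugs}

    def class_ids(self) -> set[str]:
        return {c.class_id for c in self.classes}

    def members(self, class_id: str) -> set[str]:
        for c in self.classes:
            if c.class_id == class_id:
                return set(c.member_ids)
        raise KeyError(class_id)

    def resolves(self, ref: str) -> bool:
        return ref in self.drug_ids() or ref in self.class_ids()

    def expand(self, ref: str) -> set[str]:
        """Set of drug ids denoted by a drug or class reference."""
        if ref in self.class_ids():
            return self.members(ref)
        return {ref}

    def synonym_index(self) -> dict[str, str]:
        index: dict[str, str] = {}
        for d in self.drugs:
            for name in [d.canonical_id, d.label, *d.synonyms]:
                index[name.strip().casefold()] = d.canonical_id
        return index


class ConditionTag(BaseModel):
    tag_id: str
    label: str


class ConditionVocabulary(BaseModel):
    tags: list[ConditionTag]

    def tag_ids(self) -> set[str]:
        return {t.tag_id for t in self.tags}


class KnowledgeBase(BaseModel):
    version: str = SCHEMA_VERSION
    criteria: list[Criterion]
    lexicon: DrugLexicon
    vocabulary: ConditionVocabulary


class ValidationReport(BaseModel):
    total: int
    by_part_category: dict[str, int]
    by_group: dict[str, int]
    violations: list[str]

    @property
    def ok(self) -> bool:
        return not self.violations


class KnowledgeBaseError(Exception):
    """Schema violation, unresolved reference, or duplicate id in a KB document."""


def _predicate_refs(p: BaseModel) -> tuple[set[str], set[str]]:
    """Collect (drug_refs, tag_refs) from a predicate tree."""
    drugs: set[str] = set()
    tags: set[str] = set()
    kind = getattr(p, "kind", None)
    if kind in {"drug_present", "dose_exceeds", "duration_exceeds",
                "frequency_per_day_below", "doses_per_day_exceeds",
                "distinct_drugs_at_least"}:
        drugs.add(p.drug)
    elif kind == "co_prescribed":
        drugs.update({p.drug_a, p.drug_b})
    elif kind == "diagnosis_present":
        tags.add(p.tag)
    elif kind == "procedure_present":
        tags.add(p.tag)
        if p.linked_drug:
            drugs.add(p.linked_drug)
    elif kind in {"all_of", "any_of"}:
        for child in p.children:
            d, t = _predicate_refs(child)
            drugs |= d
            tags |= t
    elif kind == "not":
        d, t = _predicate_refs(p.child)
        drugs |= d
        tags |= t
    return drugs, tags


def criterion_refs(c: Criterion) -> tuple[set[str], set[str]]:
    drugs: set[str] = set()
    tags: set[str] = set()
    for p in [c.trigger, c.exception, c.required_action,
              *[cl.predicate for cl in c.severity_clauses]]:
        if p is not None:
            d, t = _predicate_refs(p)
            drugs |= d
            tags |= t
    return drugs, tags


def validate_knowledge_base(kb: KnowledgeBase) -> ValidationReport:
    """Referential-integrity and composition report for a knowledge base.

    Violations are reported, never raised: an invalid KB yields a report
    whose ``violations`` list names every offending entry.
    """
    violations: list[str] = []

    ids = [c.criterion_id for c in kb.criteria]
    for cid, n in Counter(ids).items():
        if n > 1:
            violations.append(f"duplicate criterion_id {cid!r} ({n} occurrences)")

    rows = [(c.provenance.table, c.provenance.row_label) for c in kb.criteria]
    for row, n in Counter(rows).items():
        if n > 1:
            violations.append(f"duplicate provenance row {row!r}")

    drug_ids = kb.lexicon.drug_ids()
    for cid, n in Counter(d.canonical_id for d in kb.lexicon.drugs).items():
        if n > 1:
            violations.append(f"duplicate drug canonical_id {cid!r}")
    seen_syn: dict[str, str] = {}
    for d in kb.lexicon.drugs:
        for name in [d.label, *d.synonyms]:
            key = name.strip().casefold()
            owner = seen_syn.setdefault(key, d.canonical_id)
            if owner != d.canonical_id:
                violations.append(
                    f"synonym {name!r} claimed by both {owner!r} and {d.canonical_id!r}"
                )
    for cls in kb.lexicon.classes:
        for m in cls.member_ids:
            if m not in drug_ids:
                violations.append(f"class {cls.class_id!r} member {m!r} not in lexicon")

    tag_ids = kb.vocabulary.tag_ids()
    for tid, n in Counter(t.tag_id for t in kb.vocabulary.tags).items():
        if n > 1:
            violations.append(f"duplicate tag_id {tid!r}")

    for c in kb.criteria:
        drugs, tags = criterion_refs(c)
        for ref in sorted(drugs):
            if not kb.lexicon.resolves(ref):
                violations.append(f"{c.criterion_id}: unresolved drug/class ref {ref!r}")
        for ref in sorted(tags):
            if ref not in tag_ids:
                violations.append(f"{c.criterion_id}: unresolved condition tag {ref!r}")

    by_pc = Counter(f"{c.part}/{c.category}" for c in kb.criteria)
    by_group = Counter(f"{c.part}/{c.group}" for c in kb.criteria)
    return ValidationReport(
        total=len(kb.criteria),
        by_part_category=dict(sorted(by_pc.items())),
        by_group=dict(sorted(by_group.items())),
        violations=violations,
    )


def count_criteria(
    kb: KnowledgeBase,
    part: Optional[Part] = None,
    category: Optional[Category] = None,
    group: Optional[str] = None,
) -> int:
    """Count criteria matching all supplied filters; no filter counts all."""
    if group is not None and group not in {c.group for c in kb.criteria}:
        raise KeyError(f"unknown group {group!r}")
    n = 0
    for c in kb.criteria:
        if part is not None and c.part != part:
            continue
        if category is not None and c.category != category:
            continue
        if group is not None and c.group != group:
            continue
        n += 1
    return n


def save_knowledge_base(kb: KnowledgeBase, path: str | Path) -> None:
    """Serialize to one structured JSON (canonical) or YAML document."""
    path = Path(path)
    doc = kb.model_dump(mode="json", exclude_none=True)
    if path.suffix in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(doc, sort_keys=False, allow_unicode=True))
    else:
        path.write_text(json.dumps(doc, indent=1, ensure_ascii=False))


def load_knowledge_base(path: str | Path) -> KnowledgeBase:
    """Load and fully resolve a KB document (JSON canonical, YAML accepted).

    Raises :class:`KnowledgeBaseError` on schema violations, unresolved
    drug/class/tag references, or duplicate criterion ids.
    """
    path = Path(path)
    if not path.exists():
        raise KnowledgeBaseError(f"knowledge base file not found: {path}")
    text = path.read_text()
    try:
        if path.suffix in {".yaml", ".yml"}:
            doc = yaml.safe_load(text)
        else:
            doc = json.loads(text)
    except Exception as exc:  # malformed document
        raise KnowledgeBaseError(f"unparseable KB document {path}: {exc}") from exc
    try:
        kb = KnowledgeBase.model_validate(doc)
    except Exception as exc:
        raise KnowledgeBaseError(f"KB schema violation in {path}: {exc}") from exc
    report = validate_knowledge_base(kb)
    hard = [v for v in report.violations
            if "unresolved" in v or "duplicate criterion_id" in v]
    if hard:
        raise KnowledgeBaseError("; ".join(hard))
    return kb


def knowledge_base_schema() -> dict:
    """JSON Schema for the KB document format."""
    return KnowledgeBase.model_json_schema()
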
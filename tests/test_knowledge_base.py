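"""Knowledge-base composition, validation, counting, and serialization."""

import json

import pytest

from pedpip.kb import (
    KnowledgeBase, KnowledgeBaseError, count_criteria, criterion_refs,
    knowledge_base_schema, load_knowledge_base, save_knowledge_base,
    validate_knowledge_base,
)
from pedpip.kb.model import (
    ConditionVocabulary, Criterion, DrugEntry, DrugLexicon, DrugPresent,
    Provenance, SeverityClause, AgeInRange,
)


def test_packaged_composition(kb):
    report = validate_knowledge_base(kb)
    assert report.violations == []
    assert report.total == 136
    assert report.by_part_category == {
        "non_specific/PIM": 68, "non_specific/PPO": 3,
        "specific/PIM": 55, "specific/PPO": 10,
    }


@pytest.mark.parametrize("filters,expected", [
    (dict(), 136),
    (dict(part="non_specific"), 71),
    (dict(part="specific"), 65),
    (dict(part="non_specific", category="PIM"), 68),
    (dict(part="non_specific", category="PPO"), 3),
    (dict(part="specific", category="PIM"), 55),
    (dict(part="specific", category="PPO"), 10),
    (dict(group="Antiinfectives For Systemic Use"), 22),
    (dict(group="Nervous system"), 15),
    (dict(part="specific", group="Respiratory problems"), 17),
])
def test_count_criteria(kb, filters, expected):
    assert count_criteria(kb, **filters) == expected


def test_count_criteria_unknown_group(kb):
    with pytest.raises(KeyError):
        count_criteria(kb, group="No Such Group")


def test_group_counts_partition_part_totals(kb):
    report = validate_knowledge_base(kb)
    for part, total in [("non_specific", 71), ("specific", 65)]:
        groups = {k: v for k, v in report.by_group.items()
                  if k.startswith(part + "/")}
        assert sum(groups.values()) == total
    assert sum(report.by_part_category.values()) == report.total


def test_row_provenance_unique_and_exhaustive(kb):
    rows = {(c.provenance.table, c.provenance.row_label) for c in kb.criteria}
    assert len(rows) == 136
    assert sum(1 for t, _ in rows if t == "Table 1") == 71
    assert sum(1 for t, _ in rows if t == "Table 2") == 65


def test_every_reference_resolves(kb):
    tag_ids = kb.vocabulary.tag_ids()
    for c in kb.criteria:
        drugs, tags = criterion_refs(c)
        for ref in drugs:
            assert kb.lexicon.resolves(ref), (c.criterion_id, ref)
        for ref in tags:
            assert ref in tag_ids, (c.criterion_id, ref)


@pytest.mark.parametrize("suffix", [".json", ".yaml"])
def test_round_trip_identity(kb, tmp_path, suffix):
    path = tmp_path / f"kb{suffix}"
    save_knowledge_base(kb, path)
    reloaded = load_knowledge_base(path)
    assert reloaded == kb


def test_empty_kb_valid():
    empty = KnowledgeBase(criteria=[],
                          lexicon=DrugLexicon(drugs=[], classes=[]),
                          vocabulary=ConditionVocabulary(tags=[]))
    report = validate_knowledge_base(empty)
    assert report.total == 0 and report.violations == []
    assert count_criteria(empty) == 0


def _toy_criterion(cid="c1", drug="aspirin"):
    return Criterion(
        criterion_id=cid, part="non_specific", category="PIM",
        group="G", trigger=DrugPresent(drug=drug),
        severity_clauses=[SeverityClause(
            predicate=AgeInRange(min_days=0, max_days=100), severity="avoid")],
        provenance=Provenance(table="T", row_label=cid),
    )


def test_unresolved_drug_reference_is_load_error(tmp_path):
    kb = KnowledgeBase(
        criteria=[_toy_criterion(drug="not_a_drug")],
        lexicon=DrugLexicon(drugs=[DrugEntry(canonical_id="aspirin",
                                             label="Aspirin")], classes=[]),
        vocabulary=ConditionVocabulary(tags=[]),
    )
    path = tmp_path / "bad.json"
    save_knowledge_base(kb, path)
    with pytest.raises(KnowledgeBaseError, match="unresolved"):
        load_knowledge_base(path)


def test_duplicate_criterion_id_is_load_error(tmp_path):
    kb = KnowledgeBase(
        criteria=[_toy_criterion("dup"), _toy_criterion("dup")],
        lexicon=DrugLexicon(drugs=[DrugEntry(canonical_id="aspirin",
                                             label="Aspirin")], classes=[]),
        vocabulary=ConditionVocabulary(tags=[]),
    )
    path = tmp_path / "dup.json"
    save_knowledge_base(kb, path)
    with pytest.raises(KnowledgeBaseError, match="duplicate"):
        load_knowledge_base(path)


def test_schema_violation_names_problem(tmp_path):
    path = tmp_path / "broken.json"
    path.write_text(json.dumps({"criteria": "not-a-list"}))
    with pytest.raises(KnowledgeBaseError, match="schema"):
        load_knowledge_base(path)


def test_missing_file(tmp_path):
    with pytest.raises(KnowledgeBaseError, match="not found"):
        load_knowledge_base(tmp_path / "absent.json")


def test_published_schema_covers_document(kb):
    schema = knowledge_base_schema()
    assert schema["title"] == "KnowledgeBase"
    assert {"criteria", "lexicon", "vocabulary"} <= set(schema["properties"])


def test_category_shape_invariants(kb):
    for c in kb.criteria:
        if c.category == "PPO":
            assert c.required_action is not None and not c.severity_clauses
        else:
            assert c.severity_clauses and c.required_action is None
        assert all(cl.severity in {"avoid", "caution"}
                   for cl in c.severity_clauses)
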
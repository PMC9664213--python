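"""Knowledge base: the packaged pediatric prescribing criteria and their
document format (load / save / validate / count)."""

from __future__ import annotations

from .lexicon_data import build_lexicon
from .model import (
    Criterion, KnowledgeBase, KnowledgeBaseError, Predicate, SeverityClause,
    TemporalWindow, ValidationReport, count_criteria, criterion_refs,
    knowledge_base_schema, load_knowledge_base, save_knowledge_base,
    validate_knowledge_base,
)
from .table1 import build_table1
from .table2 import build_table2
from .vocabulary_data import build_vocabulary

__all__ = [
    "Criterion", "KnowledgeBase", "KnowledgeBaseError", "Predicate",
    "SeverityClause", "TemporalWindow", "ValidationReport", "count_criteria",
    "criterion_refs", "knowledge_base_schema", "load_knowledge_base",
    "packaged_kb", "save_knowledge_base", "validate_knowledge_base",
]


def packaged_kb() -> KnowledgeBase:
    """The packaged knowledge base: all 136 criteria, lexicon, vocabulary."""
    kb = KnowledgeBase(
        criteria=build_table1() + build_table2(),
        lexicon=build_lexicon(),
        vocabulary=build_vocabulary(),
    )
    report = validate_knowledge_base(kb)
    if report.violations:  # construction bug, not user error
        raise KnowledgeBaseError("; ".join(report.violations))
    return kb
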
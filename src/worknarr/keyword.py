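"""Basic keyword search: flag narratives containing "work".

Matching is case-insensitive *substring* matching on the raw narrative,
so "worker", "work-related" and "woodworking" all flag.  Negation
phrases ("saw that was not working properly") deliberately still flag:
such wording occurs inside genuinely work-related narratives, and the
design goal is high-recall first-round case selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .corpus import LabeledCorpus, NarrativeRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KeywordRule:
    pattern: str = "work"
    label: str = "keyword"

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("keyword pattern must be non-empty")
        if self.pattern != self.pattern.casefold():
            raise ValueError("keyword pattern must be lower-case")


def keyword_flag(record: NarrativeRecord, rule: KeywordRule | None = None) -> bool:
    """True iff the pattern occurs case-insensitively in the narrative."""
    rule = rule or KeywordRule()
    return rule.pattern in record.narrative.casefold()


def keyword_flag_corpus(
    corpus: LabeledCorpus, rule: KeywordRule | None = None
) -> dict[str, bool]:
    rule = rule or KeywordRule()
    flags = {r.record_id: keyword_flag(r, rule) for r in corpus}
    logger.info(
        "keyword %r flagged %d of %d records", rule.pattern, sum(flags.values()), len(flags)
    )
    return flags
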
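"""Index search: build a work-term index from an annotated review sample,
then flag any narrative containing an index stem.

The study design this implements: draw a random sample of work-labelled
cases whose text does *not* contain "work"; a health-information manager
manually extracts the words describing the injury event under 16 fixed
headings; the work-specific headings (activity task, object involved,
work location, occupation, safety/preventative devices) are pooled,
stemmed and reduced to the smallest discriminating word-stems; stems
recorded fewer than ``min_frequency`` times are dropped; the surviving
stems form the index.  Flagging matches each index stem as a substring
of the narrative's stemmed token stream, so "weld" covers "welding" and
"welder", and "factori" (the stem of factory/factories) matches both
surface forms.
"""

from __future__ import annotations

import logging
import random
from collections import defaultdict
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from importlib import resources

from .corpus import WORK, LabeledCorpus, NarrativeRecord
from .normalize import porter_stem, tokenize

logger = logging.getLogger(__name__)

#: The 16 manual-extraction headings used when annotating the review sample.
HEADINGS = frozenset(
    {
        "nature of injury",
        "body site",
        "activity task",
        "precipitating mechanism",
        "contributory factor",
        "injury event/exposure",
        "object involved",
        "physical force involved",
        "substance involved",
        "human agency involved",
        "organism involved",
        "work location",
        "occupation",
        "industry",
        "nature of work",
        "safety/preventative devices",
    }
)

#: Headings pooled into the index: the most work-specific of the 16.
DEFAULT_INDEX_HEADINGS = (
    "activity task",
    "object involved",
    "work location",
    "occupation",
    "safety/preventative devices",
)

DEFAULT_MIN_FREQUENCY = 5


@dataclass(frozen=True)
class AnnotationRow:
    """One manually extracted keyword: (record, heading, word or phrase)."""

    record_id: str
    heading: str
    keyword: str

    def __post_init__(self) -> None:
        if self.heading not in HEADINGS:
            raise ValueError(f"unknown annotation heading: {self.heading!r}")
        if not self.keyword.strip():
            raise ValueError("annotation keyword must be non-empty")


@dataclass(frozen=True)
class IndexEntry:
    stem: str
    frequency: int
    headings: frozenset[str]


@dataclass(frozen=True)
class TermIndex:
    """Ordered index of minimal work-term stems (descending frequency)."""

    entries: tuple[IndexEntry, ...]
    min_frequency: int = DEFAULT_MIN_FREQUENCY

    def __post_init__(self) -> None:
        stems = [e.stem for e in self.entries]
        if len(stems) != len(set(stems)):
            raise ValueError("index stems must be unique")
        for e in self.entries:
            if e.frequency < self.min_frequency:
                raise ValueError(
                    f"entry {e.stem!r} below min_frequency {self.min_frequency}"
                )
        for a in stems:
            for b in stems:
                if a != b and b.startswith(a):
                    raise ValueError(f"{a!r} is a prefix of {b!r}: index not minimal")

    def __len__(self) -> int:
        return len(self.entries)

    def stems(self) -> tuple[str, ...]:
        return tuple(e.stem for e in self.entries)


def select_review_sample(
    corpus: LabeledCorpus,
    keyword_flags: Mapping[str, bool],
    n: int,
    seed: int,
) -> LabeledCorpus:
    """Sample ``n`` work-labelled, keyword-negative records for manual review.

    Deterministic per seed; sampling is without replacement.
    """
    eligible = [
        r for r in corpus
        if r.activity_label == WORK and not keyword_flags[r.record_id]
    ]
    if len(eligible) < n:
        raise ValueError(
            f"only {len(eligible)} work-labelled keyword-negative records; need {n}"
        )
    rng = random.Random(seed)
    sample = rng.sample(eligible, n)
    return LabeledCorpus(sample, provenance=f"review-sample(n={n},seed={seed})")


def _stem_phrase(keyword: str) -> str:
    """Stem each word of a (possibly multi-word) keyword, join by one space."""
    return " ".join(tokenize(keyword).stems)


def build_index(
    annotations: Iterable[AnnotationRow],
    headings_used: Sequence[str] = DEFAULT_INDEX_HEADINGS,
    min_frequency: int = DEFAULT_MIN_FREQUENCY,
) -> TermIndex:
    """Pool annotation keywords, stem, merge to minimal stems, threshold.

    Merging: after stemming, an entry that is a string-prefix of another
    absorbs it (frequencies summed, headings pooled) — "weld" covers
    "welder"/"welding" whichever heading they came from.  Merging runs
    before the frequency threshold.  Permutation-invariant.
    """
    rows = [a for a in annotations]
    if not rows:
        raise ValueError("no annotations supplied")
    used = set(headings_used)
    unknown = used - HEADINGS
    if unknown:
        raise ValueError(f"unknown headings: {sorted(unknown)}")
    freq: dict[str, int] = defaultdict(int)
    heads: dict[str, set[str]] = defaultdict(set)
    for row in rows:
        if row.heading not in used:
            continue
        phrase = _stem_phrase(row.keyword)
        if not phrase:
            continue
        freq[phrase] += 1
        heads[phrase].add(row.heading)
    if not freq:
        raise ValueError("no annotations under the selected headings")

    # minimal-stem reduction: shortest phrases become roots; any phrase a
    # kept root prefixes is folded into that root
    roots: list[str] = []
    merged_freq: dict[str, int] = {}
    merged_heads: dict[str, set[str]] = {}
    for phrase in sorted(freq, key=lambda p: (len(p), p)):
        root = next((r for r in roots if phrase.startswith(r)), None)
        if root is None:
            roots.append(phrase)
            merged_freq[phrase] = freq[phrase]
            merged_heads[phrase] = set(heads[phrase])
        else:
            merged_freq[root] += freq[phrase]
            merged_heads[root] |= heads[phrase]

    entries = [
        IndexEntry(stem, merged_freq[stem], frozenset(merged_heads[stem]))
        for stem in roots
        if merged_freq[stem] >= min_frequency
    ]
    if not entries:
        raise ValueError(
            f"no stems reach min_frequency={min_frequency}; index would be empty"
        )
    entries.sort(key=lambda e: (-e.frequency, e.stem))
    index = TermIndex(tuple(entries), min_frequency)
    logger.info("built index of %d stems from %d annotation rows", len(index), len(rows))
    return index


def index_matches(record: NarrativeRecord, index: TermIndex) -> list[str]:
    """Index stems occurring as substrings of the stemmed token stream."""
    hay = tokenize(record.narrative).stemmed_text
    return [e.stem for e in index.entries if e.stem in hay]


def index_flag(record: NarrativeRecord, index: TermIndex) -> bool:
    """True iff any index stem matches the narrative."""
    if not index.entries:
        raise ValueError("index is empty")
    hay = tokenize(record.narrative).stemmed_text
    return any(e.stem in hay for e in index.entries)


def index_flag_corpus(corpus: LabeledCorpus, index: TermIndex) -> dict[str, bool]:
    flags = {r.record_id: index_flag(r, index) for r in corpus}
    logger.info("index flagged %d of %d records", sum(flags.values()), len(flags))
    return flags


def union_flag(
    keyword_flags: Mapping[str, bool], index_flags: Mapping[str, bool]
) -> dict[str, bool]:
    """Per-record keyword OR index flag; domains must agree exactly."""
    ka, kb = set(keyword_flags), set(index_flags)
    if ka != kb:
        diff = sorted(ka ^ kb)
        preview = ", ".join(diff[:10])
        raise ValueError(f"flag domains differ on {len(diff)} id(s): {preview}")
    return {rid: keyword_flags[rid] or index_flags[rid] for rid in keyword_flags}


# ---------------------------------------------------------------------------
# file formats

def read_annotations(path: str, delimiter: str = ",") -> list[AnnotationRow]:
    """Annotation file: record_id, heading, keyword (one row per extraction)."""
    import csv

    rows: list[AnnotationRow] = []
    with open(path, newline="", encoding="utf-8") as handle:
        for row_no, row in enumerate(csv.reader(handle, delimiter=delimiter), start=1):
            if not row:
                continue
            if len(row) != 3:
                raise ValueError(f"annotation row {row_no}: expected 3 columns")
            rows.append(AnnotationRow(row[0], row[1], row[2]))
    return rows


def write_annotations(rows: Iterable[AnnotationRow], path: str, delimiter: str = ",") -> None:
    import csv

    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter=delimiter)
        for row in rows:
            writer.writerow([row.record_id, row.heading, row.keyword])


def write_index(index: TermIndex, path: str) -> None:
    """One line per entry: stem<TAB>frequency<TAB>headings(;-joined)."""
    with open(path, "w", encoding="utf-8") as handle:
        for e in index.entries:
            handle.write(f"{e.stem}\t{e.frequency}\t{';'.join(sorted(e.headings))}\n")


def _parse_index_lines(lines: Iterable[str], min_frequency: int) -> TermIndex:
    entries = []
    for line in lines:
        line = line.split("#", 1)[0].rstrip("\n")
        if not line.strip():
            continue
        stem_, freq, headings = line.split("\t")
        entries.append(
            IndexEntry(stem_.strip(), int(freq), frozenset(h for h in headings.split(";") if h))
        )
    entries.sort(key=lambda e: (-e.frequency, e.stem))
    return TermIndex(tuple(entries), min_frequency)


def read_index(path: str, min_frequency: int = 1) -> TermIndex:
    with open(path, encoding="utf-8") as handle:
        return _parse_index_lines(handle, min_frequency)


def default_index() -> TermIndex:
    """The shipped exemplar index (published terms + synthetic vocabulary).

    The study's full 50-term index was never published; only seven terms
    are known.  Real analyses should build their own index from an
    annotated sample.
    """
    text = resources.files("worknarr.data").joinpath("default_index.txt").read_text("utf-8")
    return _parse_index_lines(text.splitlines(), min_frequency=1)
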
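"""Labelled narrative corpora: reading, writing, and the record container.

A corpus is a delimited text file with three columns — record ID, binary
activity label (1/work, 0/other; anything else becomes *missing*) and the
free-text injury description captured at triage (at most 255 characters).
Records with a missing label are retained on load; exclusion happens in
the evaluation layer, where it is counted and logged.
"""

from __future__ import annotations

import csv
import logging
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field, replace

import pandas as pd

logger = logging.getLogger(__name__)

WORK = "work"
OTHER = "other"
MISSING = "missing"

MAX_NARRATIVE_LEN = 255

_LABEL_ALIASES = {
    "1": WORK,
    "work": WORK,
    "0": OTHER,
    "other": OTHER,
}


class CorpusFormatError(ValueError):
    """A corpus file violates the three-column contract."""


@dataclass(frozen=True)
class NarrativeRecord:
    """One ED presentation: ID, injury-description text, gold activity label."""

    record_id: str
    narrative: str
    activity_label: str = MISSING

    def __post_init__(self) -> None:
        if self.activity_label not in (WORK, OTHER, MISSING):
            raise ValueError(f"invalid activity label: {self.activity_label!r}")
        if self.narrative is None:  # pragma: no cover - defensive
            object.__setattr__(self, "narrative", "")


@dataclass
class LabeledCorpus:
    """Ordered collection of :class:`NarrativeRecord` with unique IDs."""

    records: list[NarrativeRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))
            raise ValueError(f"duplicate record_id in corpus: {dup!r}")

    def __iter__(self) -> Iterator[NarrativeRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i: int) -> NarrativeRecord:
        return self.records[i]

    def ids(self) -> list[str]:
        return [r.record_id for r in self.records]

    def label_counts(self) -> dict[str, int]:
        counts = {WORK: 0, OTHER: 0, MISSING: 0}
        for r in self.records:
            counts[r.activity_label] += 1
        return counts

    def labels(self) -> dict[str, str]:
        return {r.record_id: r.activity_label for r in self.records}

    def subset(self, ids: Iterable[str], provenance: str | None = None) -> "LabeledCorpus":
        wanted = set(ids)
        return LabeledCorpus(
            [r for r in self.records if r.record_id in wanted],
            provenance if provenance is not None else self.provenance,
        )

    def append(self, record: NarrativeRecord) -> "LabeledCorpus":
        """Return a new corpus with ``record`` added (IDs stay unique)."""
        return LabeledCorpus(self.records + [record], self.provenance)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "record_id": [r.record_id for r in self.records],
                "activity_label": [r.activity_label for r in self.records],
                "narrative": [r.narrative for r in self.records],
            }
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        id_col: str = "record_id",
        label_col: str = "activity_label",
        text_col: str = "narrative",
        provenance: str = "dataframe",
    ) -> "LabeledCorpus":
        records = [
            NarrativeRecord(
                str(row[id_col]),
                _clean_narrative(row[text_col]),
                parse_label(row[label_col]),
            )
            for _, row in df.iterrows()
        ]
        return cls(records, provenance)


@dataclass(frozen=True)
class CorpusDialect:
    """Delimited-text configuration for corpus files."""

    delimiter: str = ","
    has_header: bool = False
    allow_extra_columns: bool = False


def parse_label(value: object) -> str:
    """Map a raw label cell to work/other/missing (robust, case-insensitive)."""
    if value is None:
        return MISSING
    text = str(value).strip().casefold()
    if text.endswith(".0"):  # pandas float round-trips of 0/1
        text = text[:-2]
    return _LABEL_ALIASES.get(text, MISSING)


def _clean_narrative(value: object) -> str:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ""
    text = str(value)
    if len(text) > MAX_NARRATIVE_LEN:
        text = text[:MAX_NARRATIVE_LEN]
    return text


def read_corpus(
    path: str,
    dialect: CorpusDialect | None = None,
    provenance: str | None = None,
) -> LabeledCorpus:
    """Read a three-column delimited file of (id, label, narrative).

    Narratives longer than 255 characters are truncated (logged);
    unparseable labels map to *missing*; rows are never dropped.
    """
    dialect = dialect or CorpusDialect()
    records: list[NarrativeRecord] = []
    n_truncated = 0
    with open(path, newline="", encoding="utf-8", errors="replace") as handle:
        reader = csv.reader(handle, delimiter=dialect.delimiter)
        for row_no, row in enumerate(reader, start=1):
            if row_no == 1 and dialect.has_header:
                continue
            if not row:
                continue
            if len(row) < 3 or (len(row) > 3 and not dialect.allow_extra_columns):
                raise CorpusFormatError(
                    f"row {row_no}: expected 3 columns, got {len(row)}"
                )
            rid, raw_label, narrative = row[0], row[1], row[2]
            if len(narrative) > MAX_NARRATIVE_LEN:
                narrative = narrative[:MAX_NARRATIVE_LEN]
                n_truncated += 1
            records.append(NarrativeRecord(rid, narrative, parse_label(raw_label)))
    if n_truncated:
        logger.warning("%d narratives truncated to %d characters", n_truncated, MAX_NARRATIVE_LEN)
    corpus = LabeledCorpus(records, provenance or path)
    counts = corpus.label_counts()
    logger.info(
        "loaded %d records (%d work, %d other, %d missing label)",
        len(corpus), counts[WORK], counts[OTHER], counts[MISSING],
    )
    return corpus


def write_corpus(corpus: LabeledCorpus, path: str, dialect: CorpusDialect | None = None) -> None:
    """Write a corpus back to the three-column format (no header)."""
    dialect = dialect or CorpusDialect()
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter=dialect.delimiter)
        for r in corpus:
            writer.writerow([r.record_id, _LABEL_OUT[r.activity_label], r.narrative])


_LABEL_OUT = {WORK: "1", OTHER: "0", MISSING: ""}


def write_predictions(
    corpus: LabeledCorpus,
    flags: Mapping[str, Mapping[str, object]],
    path: str,
    dialect: CorpusDialect | None = None,
) -> None:
    """Write one row per record: id, gold label, narrative, one column per method.

    ``flags`` maps method name -> {record_id -> flag/score}.  Every method
    must cover every record; the output is round-trippable by
    :func:`read_corpus` with ``has_header=True, allow_extra_columns=True``.
    """
    dialect = dialect or CorpusDialect()
    all_ids = set(corpus.ids())
    for name, mapping in flags.items():
        missing = sorted(all_ids - set(mapping))
        if missing:
            preview = ", ".join(missing[:10])
            raise ValueError(
                f"method {name!r} is missing flags for {len(missing)} record(s): {preview}"
            )
    names = list(flags)
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter=dialect.delimiter)
        writer.writerow(["record_id", "activity_label", "narrative", *names])
        for r in corpus:
            writer.writerow(
                [r.record_id, _LABEL_OUT[r.activity_label], r.narrative]
                + [_fmt_flag(flags[name][r.record_id]) for name in names]
            )


def _fmt_flag(value: object) -> str:
    if isinstance(value, bool):
        return "1" if value else "0"
    return str(value)
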
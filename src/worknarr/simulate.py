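"""Synthetic triage-narrative corpora with realistic class structure.

The generator emulates the statistical skeleton of an ED injury
surveillance corpus: ~10.3% of presentations are work-related; the
word "work" appears in ~58% of work narratives and ~1% of other
narratives (via negation phrasing like "saw was not working properly");
work narratives without "work" often carry work-specific index terms
(job site, factory, forklift, ...); ambiguous terms (mine, farm,
truck, ...) appear in both classes; some narratives are scant or empty;
a handful of records lose their activity label.  A companion annotation
table records the planted terms of work-labelled, keyword-negative
records under their semantic headings, so the index builder can be run
end-to-end.

Because emission rates are planted by construction, classifier metrics
measured on this corpus validate the package's mechanics — not the
epidemiology of any real surveillance system.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, replace

from .corpus import MISSING, OTHER, WORK, LabeledCorpus, NarrativeRecord, MAX_NARRATIVE_LEN
from .index import AnnotationRow
from .normalize import porter_stem

# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class GeneratorParams:
    """Emission rates of the synthetic corpus.

    Defaults reproduce the marginal rates of the study corpus this
    package was designed around: 208,291 presentations, 10.3% work
    prevalence, "work" in 58.16% of work and 1.03% of other narratives,
    index-term emission in 52.2% of work narratives (the review-sample
    rate 522/1000) and 12.54% of other narratives, 10 missing labels.
    """

    n_records: int = 208_291
    work_prevalence: float = 0.103
    p_keyword_given_work: float = 0.5816
    p_keyword_given_other: float = 0.0103
    p_index_term_given_work_no_keyword: float = 0.522
    p_index_term_given_other: float = 0.1254
    negation_rate: float = 0.05
    empty_text_rate: float = 0.02
    misspelling_rate: float = 0.05
    missing_label_count: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 0:
            raise ValueError("n_records must be >= 0")
        if not 0 <= self.missing_label_count <= max(self.n_records, 0):
            raise ValueError("missing_label_count out of range")
        for name in (
            "work_prevalence", "p_keyword_given_work", "p_keyword_given_other",
            "p_index_term_given_work_no_keyword", "p_index_term_given_other",
            "negation_rate", "empty_text_rate", "misspelling_rate",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be a probability, got {value}")


@dataclass(frozen=True)
class TermSpec:
    """A plantable vocabulary term with its annotation heading and the
    phrase template it is realized through."""

    term: str
    heading: str
    phrase: str  # phrase used in work narratives
    other_phrase: str | None = None  # phrase used in other narratives (ambiguous terms)


@dataclass(frozen=True)
class VocabularyPools:
    """Term pools the generator assembles narratives from.

    ``work_terms`` are work-specific (emitted in other narratives only
    rarely, as false-positive noise); ``ambiguous_terms`` legitimately
    occur in both classes and carry most of the other-side index hits;
    ``shared_injury_terms`` (body parts, mechanisms, objects) appear in
    both classes; ``negation_phrases`` put "work" into narratives
    without implying work-relatedness.
    """

    work_terms: tuple[TermSpec, ...]
    ambiguous_terms: tuple[TermSpec, ...]
    other_activity_terms: tuple[str, ...]
    shared_injury_terms: dict[str, tuple[str, ...]]
    negation_phrases: tuple[str, ...]
    work_keyword_phrases: tuple[str, ...]
    work_context_fillers: tuple[str, ...]

    def __post_init__(self) -> None:
        work = {t.term for t in self.work_terms} | {t.term for t in self.ambiguous_terms}
        if work & set(self.other_activity_terms):
            raise ValueError("work/ambiguous terms must not collide with other-activity terms")
        for t in self.work_terms + self.ambiguous_terms:
            if "work" in t.term:
                raise ValueError("index vocabulary must not contain the keyword itself")

    def work_stems(self) -> frozenset[str]:
        """Stems of every work-specific term word (for recovery checks)."""
        out = set()
        for spec in self.work_terms:
            for word in spec.term.split():
                out.add(porter_stem(word))
        return frozenset(out)

    def guard_stems(self) -> frozenset[str]:
        """Stems misspellings must never create (all plantable vocabulary)."""
        out = set()
        for spec in self.work_terms + self.ambiguous_terms:
            for word in spec.term.split():
                out.add(porter_stem(word))
        return frozenset(out)


def default_vocabulary() -> VocabularyPools:
    return VocabularyPools(
        work_terms=(
            TermSpec("job site", "work location", "at the job site"),
            TermSpec("factory", "work location", "at the factory"),
            TermSpec("warehouse", "work location", "at the warehouse"),
            TermSpec("abattoir", "work location", "at the abattoir"),
            TermSpec("construction", "work location", "on the construction site"),
            TermSpec("forklift", "object involved", "hit by forklift"),
            TermSpec("crane", "object involved", "struck by crane load"),
            TermSpec("excavator", "object involved", "near the excavator"),
            TermSpec("scaffold", "object involved", "fell from scaffold"),
            TermSpec("welding", "activity task", "while welding"),
            TermSpec("labouring", "activity task", "while labouring"),
            TermSpec("client", "occupation", "while lifting client"),
            TermSpec("apprentice", "occupation", "apprentice"),
            TermSpec("tradesman", "occupation", "tradesman"),
            TermSpec("harness", "safety/preventative devices", "when harness failed"),
            TermSpec("hard hat", "safety/preventative devices", "not wearing hard hat"),
        ),
        ambiguous_terms=(
            TermSpec("mine", "work location", "at the mine", "dog of mine bit hand"),
            TermSpec("farm", "work location", "on the farm", "visiting a farm"),
            TermSpec("truck", "object involved", "loading the truck", "playing near truck"),
            TermSpec("ladder", "object involved", "fell from ladder", "fell from ladder at home"),
            TermSpec("kitchen", "work location", "in the commercial kitchen", "in the kitchen"),
            TermSpec("station", "work location", "at the station", "at the train station"),
            TermSpec("roof", "work location", "on the roof", "climbing on the roof"),
        ),
        other_activity_terms=(
            "at home", "playing football at the park", "at school", "during sport",
            "riding a bike", "in the garden", "at the beach", "at the playground",
            "swimming at the pool", "at the gym", "skateboarding on the street",
        ),
        shared_injury_terms={
            "body": (
                "hand", "arm", "leg", "back", "face", "foot", "knee", "finger",
                "shoulder", "ankle", "wrist", "eye", "head",
            ),
            "mechanism": (
                "cut", "fell and hurt", "burn to", "crush injury to",
                "twisted", "strained", "laceration to",
            ),
            "object": ("saw", "knife", "glass", "nail gun", "grinder", "door", "box"),
        },
        negation_phrases=(
            "saw was not working properly",
            "machine was not working properly",
        ),
        work_keyword_phrases=(
            "at work",
            "work related injury",
            "injured at work",
            "whilst at work",
            "co worker dropped box on foot",
        ),
        work_context_fillers=("during shift", "while on duty", "during night shift"),
    )


def disjoint_vocabulary() -> VocabularyPools:
    """Variant with no ambiguous pool: work vocabulary occurs only in
    work narratives (combine with ``p_index_term_given_other=0`` and
    ``p_keyword_given_other=0`` for fully separated class vocabularies).
    Used for parameter-recovery checks."""
    return replace(default_vocabulary(), ambiguous_terms=())


_SCANT_TEXTS = ("nil details", "unknown circumstances", "no details recorded", "pain")
_TEMPORALS = ("yesterday", "this morning", "last night", "today", "an hour ago")

_WORK_NEGATIONS = (
    "at work yesterday and did not work today",
    "at work on saw that was not working properly",
)


# ---------------------------------------------------------------------------
# generation


def _injury_phrase(rng: random.Random, vocab: VocabularyPools) -> str:
    shared = vocab.shared_injury_terms
    mech = rng.choice(shared["mechanism"])
    body = rng.choice(shared["body"])
    if rng.random() < 0.5:
        obj = rng.choice(shared["object"])
        return f"{mech} {body} on {obj}"
    return f"{mech} {body}"


def _misspell(rng: random.Random, token: str, guard: frozenset[str]) -> str:
    if len(token) < 3:
        return token
    i = rng.randrange(len(token))
    op = rng.random()
    if op < 0.4:  # substitute
        mutated = token[:i] + rng.choice("abcdefghijklmnopqrstuvwxyz") + token[i + 1 :]
    elif op < 0.7:  # delete
        mutated = token[:i] + token[i + 1 :]
    else:  # transpose
        if i == len(token) - 1:
            i -= 1
        mutated = token[:i] + token[i + 1] + token[i] + token[i + 2 :]
    if "work" in mutated or porter_stem(mutated) in guard:
        return token
    return mutated


def generate_corpus(
    params: GeneratorParams,
    vocab: VocabularyPools | None = None,
) -> tuple[LabeledCorpus, list[AnnotationRow]]:
    """Generate a labelled corpus and its companion annotation table.

    Deterministic per ``params.seed``: the same parameters always yield
    byte-identical output.  The annotation table covers the planted
    index terms of work-labelled, keyword-negative records — the
    population the manual review sample is drawn from.
    """
    vocab = vocab or default_vocabulary()
    rng = random.Random(params.seed)
    guard = vocab.guard_stems()
    width = max(6, len(str(max(params.n_records, 1))))

    records: list[NarrativeRecord] = []
    annotations: list[AnnotationRow] = []

    for i in range(params.n_records):
        rid = f"r{i + 1:0{width}d}"
        is_work = rng.random() < params.work_prevalence
        label = WORK if is_work else OTHER

        if is_work:
            has_kw = rng.random() < params.p_keyword_given_work
            has_idx = rng.random() < params.p_index_term_given_work_no_keyword
        else:
            has_kw = rng.random() < params.p_keyword_given_other
            has_idx = rng.random() < params.p_index_term_given_other

        if not has_kw and not has_idx and rng.random() < params.empty_text_rate:
            narrative = "" if rng.random() < 0.5 else rng.choice(_SCANT_TEXTS)
            records.append(NarrativeRecord(rid, narrative, label))
            continue

        protected: set[str] = set()
        parts: list[str] = []
        planted: TermSpec | None = None

        if has_idx:
            if is_work:
                pool = vocab.work_terms if (not vocab.ambiguous_terms or rng.random() < 0.8) else vocab.ambiguous_terms
            else:
                pool = vocab.ambiguous_terms if (vocab.ambiguous_terms and rng.random() < 0.8) else vocab.work_terms
            planted = rng.choice(pool)

        if planted is not None:
            phrase = planted.phrase
            if not is_work and planted.other_phrase is not None:
                phrase = planted.other_phrase
            if planted.heading == "occupation" and " " not in phrase:
                parts.append(phrase)  # occupation terms prefix the narrative
                parts.append(_injury_phrase(rng, vocab))
            else:
                parts.append(_injury_phrase(rng, vocab))
                parts.append(phrase)
            protected.update(planted.term.split())
            protected.update(phrase.split())
        else:
            parts.append(_injury_phrase(rng, vocab))

        if has_kw:
            if is_work:
                if rng.random() < params.negation_rate:
                    parts.append(rng.choice(_WORK_NEGATIONS))
                else:
                    parts.append(rng.choice(vocab.work_keyword_phrases))
            else:
                parts.append(rng.choice(vocab.negation_phrases))
            protected.update(parts[-1].split())
        elif not has_idx:
            # neutral context so the narrative still reads like triage text
            if is_work:
                if vocab.work_context_fillers and rng.random() < 0.3:
                    parts.append(rng.choice(vocab.work_context_fillers))
            else:
                parts.append(rng.choice(vocab.other_activity_terms))

        if rng.random() < 0.5:
            parts.append(rng.choice(_TEMPORALS))

        tokens = " ".join(parts).split()
        if params.misspelling_rate > 0:
            tokens = [
                _misspell(rng, t, guard)
                if t not in protected and "work" not in t and rng.random() < params.misspelling_rate
                else t
                for t in tokens
            ]
        narrative = " ".join(tokens)[:MAX_NARRATIVE_LEN]
        records.append(NarrativeRecord(rid, narrative, label))

        if is_work and not has_kw and planted is not None:
            annotations.append(AnnotationRow(rid, planted.heading, planted.term))

    if params.missing_label_count and records:
        for idx in rng.sample(range(len(records)), params.missing_label_count):
            r = records[idx]
            records[idx] = NarrativeRecord(r.record_id, r.narrative, MISSING)

    corpus = LabeledCorpus(records, provenance=f"synthetic(seed={params.seed},n={params.n_records})")
    return corpus, annotations


WORKED_EXAMPLE_ID = "worked-example"
WORKED_EXAMPLE_TEXT = (
    "Went home from work after getting piece of metal in eye; eye red and inflamed"
)


def plant_worked_example(corpus: LabeledCorpus) -> LabeledCorpus:
    """Append the canonical mixed-evidence narrative (home + work + metal
    + eye) as a work-labelled record, for end-to-end smoke tests of
    concept scoring.  Refuses to plant twice."""
    if WORKED_EXAMPLE_ID in set(corpus.ids()):
        raise ValueError(f"record {WORKED_EXAMPLE_ID!r} already present")
    return corpus.append(NarrativeRecord(WORKED_EXAMPLE_ID, WORKED_EXAMPLE_TEXT, WORK))
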
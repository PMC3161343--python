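"""Tag-supervised concept classifier for short injury narratives.

An open re-implementation of content-analytic concept scoring: frequent
stems seed *concepts*; each concept adopts a small thesaurus of its most
strongly co-occurring stems; each concept learns how strongly it is
associated with the gold activity groups (the "tags"); a record's Work
and Other relevance scores are sums of association weights over the
concepts its text evokes.  The scores are unnormalized relevance sums —
they may exceed 1 and their *difference* is the basis of the adjusted
classification cutoff.

The public surface follows the statsmodels convention: build a
:class:`ConceptTagModel` from a labelled corpus, call :meth:`fit`, and
work with the returned :class:`ConceptTagResults` (scoring,
classification, cutoff calibration, ``summary()``).

Model
-----
Let ``df(s)`` be the number of training narratives containing stem ``s``
after stop-listing.  Stems with ``df >= min_term_frequency`` seed
concepts in descending frequency order.  Concept ``C(s)`` adopts as
thesaurus members up to ``concept_generality`` stems ``t`` whose
occurrences predominantly accompany the seed — affinity
``df(s & t) / df(t) >= member_affinity_floor`` — ranked by that
affinity; each adopted member carries the co-occurrence weight
``w(t|s) = df(s & t) / df(s)``, and the seed itself is a member with
weight 1.  The affinity gate keeps concepts specific (a concept must
not fire on ubiquitous words that merely co-occur with everything) and
is what absorbs misspelt variants of a term into its concept.  With add-one smoothing over the two tags, the association of the
concept with tag ``c`` is::

    assoc_c = (n_c + k) / (n_work + n_other + 2k)

where ``n_c`` counts training records of label ``c`` containing the
seed and ``k`` is the smoothing constant, so assoc_work + assoc_other
= 1.  Concepts whose margin ``|assoc_work - assoc_other|`` falls below
``margin_floor`` do not discriminate the groups and are dropped; each
surviving concept is assigned to its dominant tag and contributes its
association weight (scaled by the best matched member weight) to that
tag's score only.  This keeps one-sided evidence genuinely one-sided:
a narrative evoking only Work concepts has score_other = 0.
"""

from __future__ import annotations

import enum
import logging
from collections import Counter, defaultdict
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .corpus import MISSING, OTHER, WORK, LabeledCorpus, NarrativeRecord
from .normalize import StopList, apply_stoplist, tokenize

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConceptModelParams:
    """Tunable knobs of the concept learner.

    concept_generality: thesaurus breadth — maximum number of
        co-occurring stems adopted per seed (default 10, narrow enough
        that concepts stay specific).
    max_seed_concepts: cap on the number of seeds; ``None`` = unlimited
        ("number of concepts to discover" turned off).
    min_term_frequency: a stem must appear in at least this many
        training narratives to seed a concept.
    margin_floor: minimum |assoc_work - assoc_other| for a concept to be
        kept (non-discriminating concepts carry no signal).
    member_affinity_floor: minimum share of a candidate member's
        occurrences that must fall alongside the seed for adoption.
    smoothing: add-k constant for the class associations.
    seed: recorded for provenance; the learner itself is deterministic.
    """

    concept_generality: int = 10
    max_seed_concepts: int | None = None
    min_term_frequency: int = 5
    margin_floor: float = 0.2
    member_affinity_floor: float = 0.5
    smoothing: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.concept_generality < 1:
            raise ValueError("concept_generality must be >= 1")
        if self.min_term_frequency < 1:
            raise ValueError("min_term_frequency must be >= 1")
        if not 0.0 <= self.margin_floor < 1.0:
            raise ValueError("margin_floor must be in [0, 1)")
        if not 0.0 < self.member_affinity_floor <= 1.0:
            raise ValueError("member_affinity_floor must be in (0, 1]")
        if self.smoothing <= 0:
            raise ValueError("smoothing must be positive")


@dataclass(frozen=True)
class Concept:
    """A seed stem, its co-occurrence thesaurus, and tag associations."""

    seed_stem: str
    members: Mapping[str, float]  # stem -> co-occurrence weight in (0, 1]
    assoc_work: float
    assoc_other: float
    n_train: int  # training records containing the seed

    def __post_init__(self) -> None:
        if self.members.get(self.seed_stem) != 1.0:
            raise ValueError("seed must be a member with weight 1")

    @property
    def tag(self) -> str:
        return WORK if self.assoc_work > self.assoc_other else OTHER

    @property
    def margin(self) -> float:
        return abs(self.assoc_work - self.assoc_other)


@dataclass(frozen=True)
class ClassScores:
    """Per-record Work/Other relevance scores; diff drives the cutoff."""

    score_work: float
    score_other: float

    def __post_init__(self) -> None:
        if self.score_work < 0 or self.score_other < 0:
            raise ValueError("relevance scores are non-negative")

    @property
    def diff(self) -> float:
        return self.score_work - self.score_other


class FourWayClass(enum.Enum):
    WORK_ACTIVITY = "WorkActivity"
    PROBABLE_WORK = "ProbableWorkActivity"
    PROBABLE_OTHER = "ProbableOtherActivity"
    OTHER_ACTIVITY = "OtherActivity"


class ConceptTagModel:
    """Concept-scoring model specification bound to a labelled corpus.

    >>> model = ConceptTagModel(corpus, ConceptModelParams())
    >>> results = model.fit()
    >>> results.score(record)
    """

    def __init__(
        self,
        corpus: LabeledCorpus,
        params: ConceptModelParams | None = None,
        stoplist: StopList | None = None,
    ) -> None:
        self.corpus = corpus
        self.params = params or ConceptModelParams()
        self.stoplist = stoplist if stoplist is not None else StopList.default()

    @classmethod
    def from_dataframe(
        cls,
        df,
        params: ConceptModelParams | None = None,
        stoplist: StopList | None = None,
        **columns: str,
    ) -> "ConceptTagModel":
        return cls(LabeledCorpus.from_dataframe(df, **columns), params, stoplist)

    # -- learning ----------------------------------------------------------

    def _stem_sets(self, records: Iterable[NarrativeRecord]) -> list[frozenset[str]]:
        return [
            apply_stoplist(tokenize(r.narrative), self.stoplist).stem_set()
            for r in records
        ]

    def fit(self) -> "ConceptTagResults":
        params = self.params
        labelled = [r for r in self.corpus if r.activity_label != MISSING]
        n_work = sum(1 for r in labelled if r.activity_label == WORK)
        n_other = len(labelled) - n_work
        if n_work == 0 or n_other == 0:
            raise ValueError(
                "corpus must contain both labels to learn tag associations "
                f"(work={n_work}, other={n_other})"
            )

        stem_sets = self._stem_sets(labelled)
        df_all: Counter[str] = Counter()
        df_work: Counter[str] = Counter()
        for record, stems in zip(labelled, stem_sets):
            df_all.update(stems)
            if record.activity_label == WORK:
                df_work.update(stems)

        seeds = sorted(
            (s for s, n in df_all.items() if n >= params.min_term_frequency),
            key=lambda s: (-df_all[s], s),
        )
        if not seeds:
            raise ValueError(
                f"no stem reaches min_term_frequency={params.min_term_frequency}"
            )
        if params.max_seed_concepts is not None:
            seeds = seeds[: params.max_seed_concepts]
        seed_set = set(seeds)

        joint: Counter[tuple[str, str]] = Counter()
        for stems in stem_sets:
            relevant = sorted(stems)
            for a, b in combinations(relevant, 2):
                if a in seed_set or b in seed_set:
                    joint[(a, b)] += 1

        # candidate member t of seed s: affinity = df(s&t)/df(t);
        # adopted weight = df(s&t)/df(s)
        cooc: dict[str, list[tuple[str, float, float]]] = defaultdict(list)
        for (a, b), n_ab in joint.items():
            if a in seed_set:
                cooc[a].append((b, n_ab / df_all[b], n_ab / df_all[a]))
            if b in seed_set:
                cooc[b].append((a, n_ab / df_all[a], n_ab / df_all[b]))

        k = params.smoothing
        concepts: list[Concept] = []
        for seed in seeds:
            partners = sorted(
                (
                    (t, affinity, w)
                    for t, affinity, w in cooc.get(seed, ())
                    if affinity >= params.member_affinity_floor
                ),
                key=lambda taw: (-taw[1], -taw[2], taw[0]),
            )
            members = {seed: 1.0}
            for t, _affinity, w in partners[: params.concept_generality]:
                members[t] = w
            nw = df_work[seed]
            no = df_all[seed] - nw
            assoc_w = (nw + k) / (nw + no + 2 * k)
            assoc_o = (no + k) / (nw + no + 2 * k)
            concept = Concept(seed, members, assoc_w, assoc_o, df_all[seed])
            if concept.margin >= params.margin_floor:
                concepts.append(concept)

        logger.info(
            "learned %d discriminating concepts from %d seeds (%d work / %d other records)",
            len(concepts), len(seeds), n_work, n_other,
        )
        summary = {
            "n_work": n_work,
            "n_other": n_other,
            "n_missing_ignored": len(self.corpus) - len(labelled),
            "n_seeds": len(seeds),
            "n_concepts": len(concepts),
        }
        return ConceptTagResults(self, tuple(concepts), summary)


class ConceptTagResults:
    """Fitted concept model: learned concepts plus scoring/classification."""

    def __init__(
        self,
        model: ConceptTagModel,
        concepts: tuple[Concept, ...],
        training_summary: dict[str, int],
    ) -> None:
        self.model = model
        self.params = model.params
        self.concepts = concepts
        self.training_summary = training_summary
        # inverted member index: stem -> [(concept position, weight)]
        inverted: dict[str, list[tuple[int, float]]] = defaultdict(list)
        for pos, concept in enumerate(concepts):
            for stem_, w in concept.members.items():
                inverted[stem_].append((pos, w))
        self._inverted = dict(inverted)

    # -- scoring -----------------------------------------------------------

    def score(self, record: NarrativeRecord) -> ClassScores:
        """Work/Other relevance of one record.

        A concept matches iff any member stem occurs in the stop-listed
        stem stream; it contributes assoc(tag) x (best matched member
        weight) to its dominant tag's score.  (0, 0) when nothing matches.
        """
        stems = apply_stoplist(tokenize(record.narrative), self.model.stoplist).stem_set()
        best: dict[int, float] = {}
        for stem_ in stems:
            for pos, w in self._inverted.get(stem_, ()):
                if w > best.get(pos, 0.0):
                    best[pos] = w
        score_work = 0.0
        score_other = 0.0
        for pos, w in best.items():
            concept = self.concepts[pos]
            if concept.tag == WORK:
                score_work += concept.assoc_work * w
            else:
                score_other += concept.assoc_other * w
        return ClassScores(score_work, score_other)

    def score_corpus(self, corpus: LabeledCorpus | None = None) -> dict[str, ClassScores]:
        corpus = corpus if corpus is not None else self.model.corpus
        return {r.record_id: self.score(r) for r in corpus}

    # -- classification ----------------------------------------------------

    def classify_binary(self, corpus: LabeledCorpus | None = None) -> dict[str, bool]:
        """Accept every record carrying any Work evidence (Work tag assigned)."""
        return {rid: classify_binary(s) for rid, s in self.score_corpus(corpus).items()}

    def classify_four_way(
        self, corpus: LabeledCorpus | None = None
    ) -> dict[str, FourWayClass]:
        return {rid: classify_four_way(s) for rid, s in self.score_corpus(corpus).items()}

    def calibrate_cutoff(
        self, corpus: LabeledCorpus | None = None
    ) -> "CutoffCalibration":
        corpus = corpus if corpus is not None else self.model.corpus
        scores = self.score_corpus(corpus)
        classes = {rid: classify_four_way(s) for rid, s in scores.items()}
        return calibrate_cutoff(scores, corpus.labels(), classes)

    def summary(self) -> str:
        """Human-readable fit summary (statsmodels-style text block)."""
        s = self.training_summary
        lines = [
            "Concept tag model".center(62),
            "=" * 62,
            f"Training records (work/other): {s['n_work']:>8} / {s['n_other']}",
            f"Missing-label records ignored: {s['n_missing_ignored']:>8}",
            f"Seed stems / kept concepts:    {s['n_seeds']:>8} / {s['n_concepts']}",
            f"concept_generality={self.params.concept_generality}  "
            f"min_term_frequency={self.params.min_term_frequency}  "
            f"margin_floor={self.params.margin_floor}",
            "-" * 62,
            f"{'concept':<16}{'tag':<8}{'assoc_work':>12}{'assoc_other':>12}{'n':>8}",
            "-" * 62,
        ]
        top = sorted(self.concepts, key=lambda c: (-c.margin, -c.n_train))[:15]
        for c in top:
            lines.append(
                f"{c.seed_stem:<16}{c.tag:<8}{c.assoc_work:>12.3f}{c.assoc_other:>12.3f}{c.n_train:>8}"
            )
        lines.append("=" * 62)
        return "\n".join(lines)

    def concepts_for_tag(self, tag: str) -> list[Concept]:
        return [c for c in self.concepts if c.tag == tag]


#: A fitted model *is* the concept model.
ConceptModel = ConceptTagResults


# ---------------------------------------------------------------------------
# spec-surface functions over the model objects

def learn_concept_model(
    corpus: LabeledCorpus,
    params: ConceptModelParams | None = None,
    stoplist: StopList | None = None,
) -> ConceptTagResults:
    """Fit a concept model (thin functional wrapper over ConceptTagModel)."""
    return ConceptTagModel(corpus, params, stoplist).fit()


def score_record(model: ConceptTagResults, record: NarrativeRecord) -> ClassScores:
    return model.score(record)


def classify_binary(scores: ClassScores) -> bool:
    """True iff the record carries any Work-tag evidence."""
    return scores.score_work > 0


def classify_four_way(scores: ClassScores) -> FourWayClass:
    """Four-way probability classification.

    work>0, other=0  -> WorkActivity;
    work>0, other>0, work>=other -> ProbableWorkActivity (ties are work);
    work>0, other>0, work<other  -> ProbableOtherActivity;
    work=0           -> OtherActivity (includes the no-evidence (0,0) case).
    """
    w, o = scores.score_work, scores.score_other
    if w > 0 and o == 0:
        return FourWayClass.WORK_ACTIVITY
    if w > 0 and o > 0:
        return FourWayClass.PROBABLE_WORK if w >= o else FourWayClass.PROBABLE_OTHER
    return FourWayClass.OTHER_ACTIVITY


@dataclass(frozen=True)
class CutoffCalibration:
    """Calibrated recoding cutoff with the per-label diff summaries."""

    cutoff: float
    by_label: Mapping[str, tuple[float, float, int]]  # label -> (mean, sd, n)


def calibrate_cutoff(
    scores: Mapping[str, ClassScores],
    labels: Mapping[str, str],
    classes: Mapping[str, FourWayClass],
    group: FourWayClass = FourWayClass.PROBABLE_OTHER,
) -> CutoffCalibration:
    """Cutoff = |mean(diff)| + sd(diff) over work-labelled records in ``group``.

    ``diff`` is score_work - score_other; sd is the sample (n-1) standard
    deviation.  Also reports the per-label (mean, sd, n) summary for the
    group, for the between-label comparison.
    """
    in_group: dict[str, list[float]] = defaultdict(list)
    for rid, cls in classes.items():
        if cls is group:
            in_group[labels[rid]].append(scores[rid].diff)
    work_diffs = in_group.get(WORK, [])
    if len(work_diffs) < 2:
        raise ValueError(
            f"need >=2 work-labelled records in {group.value}; found {len(work_diffs)}"
        )
    by_label = {
        label: (float(np.mean(d)), float(np.std(d, ddof=1)) if len(d) > 1 else 0.0, len(d))
        for label, d in sorted(in_group.items())
    }
    mean, sd, _ = by_label[WORK]
    return CutoffCalibration(cutoff=abs(mean) + sd, by_label=by_label)


def cutoff_from_summary(mean_diff: float, sd_diff: float) -> float:
    """Cutoff from reported summary statistics: |mean| + sd."""
    return abs(mean_diff) + sd_diff


@dataclass(frozen=True)
class AdjustedClassification:
    classes: Mapping[str, FourWayClass]
    flags: Mapping[str, bool]
    n_recoded: int


def apply_adjusted_classification(
    classes: Mapping[str, FourWayClass],
    scores: Mapping[str, ClassScores],
    cutoff: float,
) -> AdjustedClassification:
    """Recode ProbableOtherActivity records with |diff| < cutoff as
    ProbableWorkActivity; the final work flag is membership of
    {WorkActivity, ProbableWorkActivity}.  Only rule-3 records change.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    adjusted: dict[str, FourWayClass] = {}
    n_recoded = 0
    for rid, cls in classes.items():
        if cls is FourWayClass.PROBABLE_OTHER and abs(scores[rid].diff) < cutoff:
            adjusted[rid] = FourWayClass.PROBABLE_WORK
            n_recoded += 1
        else:
            adjusted[rid] = cls
    flags = {
        rid: cls in (FourWayClass.WORK_ACTIVITY, FourWayClass.PROBABLE_WORK)
        for rid, cls in adjusted.items()
    }
    logger.info("adjusted classification recoded %d records at cutoff %.4f", n_recoded, cutoff)
    return AdjustedClassification(adjusted, flags, n_recoded)


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: int
    pvalue: float


def compare_groups_ttest(
    diffs_group_a: Sequence[float], diffs_group_b: Sequence[float]
) -> TTestResult:
    """Pooled-variance two-sample t-test (df = nA + nB - 2)."""
    a = np.asarray(diffs_group_a, dtype=float)
    b = np.asarray(diffs_group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("zero pooled variance: t statistic undefined")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(float(t), int(a.size + b.size - 2), float(p))
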
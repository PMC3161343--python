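"""Concept learning, scoring, classification and calibration."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import brute_force_scores
from worknarr import (
    ClassScores,
    ConceptModelParams,
    ConceptTagModel,
    FourWayClass,
    LabeledCorpus,
    NarrativeRecord,
    apply_adjusted_classification,
    calibrate_cutoff,
    classify_binary,
    classify_four_way,
    compare_groups_ttest,
    cutoff_from_summary,
    learn_concept_model,
)
from worknarr.model_io import load_model, save_model

# ---------------------------------------------------------------------------
# learning


def test_toy_association_hand_computed(toy_model):
    # "factori" occurs in 2 records, both work-labelled:
    # add-one smoothing over two tags gives (2+1)/(2+2)
    concept = next(c for c in toy_model.concepts if c.seed_stem == "factori")
    assert concept.assoc_work == pytest.approx(0.75)
    assert concept.assoc_other == pytest.approx(0.25)
    assert concept.tag == "work"
    assert concept.members["factori"] == 1.0


def test_associations_sum_to_one(toy_model):
    for c in toy_model.concepts:
        assert c.assoc_work + c.assoc_other == pytest.approx(1.0)


def test_duplicating_corpus_preserves_associations(toy_corpus):
    params = ConceptModelParams(min_term_frequency=1, margin_floor=0.0, smoothing=1e-9)
    base = ConceptTagModel(toy_corpus, params).fit()
    doubled = LabeledCorpus(
        toy_corpus.records
        + [
            NarrativeRecord(r.record_id + "-copy", r.narrative, r.activity_label)
            for r in toy_corpus
        ]
    )
    twice = ConceptTagModel(doubled, params).fit()
    base_assoc = {c.seed_stem: c.assoc_work for c in base.concepts}
    twice_assoc = {c.seed_stem: c.assoc_work for c in twice.concepts}
    assert set(base_assoc) == set(twice_assoc)
    for stem, assoc in base_assoc.items():
        assert twice_assoc[stem] == pytest.approx(assoc, abs=1e-6)


def test_single_label_corpus_rejected():
    corpus = LabeledCorpus([NarrativeRecord("1", "fell at factory", "work")])
    with pytest.raises(ValueError, match="both labels"):
        learn_concept_model(corpus, ConceptModelParams(min_term_frequency=1))


def test_unreachable_term_frequency_rejected(toy_corpus):
    with pytest.raises(ValueError, match="min_term_frequency"):
        learn_concept_model(toy_corpus, ConceptModelParams(min_term_frequency=100))


def test_fit_is_deterministic(toy_corpus):
    params = ConceptModelParams(min_term_frequency=1)
    a = ConceptTagModel(toy_corpus, params).fit()
    b = ConceptTagModel(toy_corpus, params).fit()
    assert a.concepts == b.concepts


def test_summary_reports_training_counts(toy_model):
    text = toy_model.summary()
    assert "3 / 3" in text
    assert "factori" in text


# ---------------------------------------------------------------------------
# scoring


def test_empty_narrative_scores_zero(toy_model):
    scores = toy_model.score(NarrativeRecord("x", "", "other"))
    assert (scores.score_work, scores.score_other) == (0.0, 0.0)


def test_one_sided_evidence(toy_model):
    scores = toy_model.score(NarrativeRecord("x", "forklift", "other"))
    assert scores.score_work > 0
    assert scores.score_other == 0.0


def test_mixed_evidence_worked_example():
    """A narrative mixing work concepts (work, metal, eye) with one home
    concept gets a high Work score and a small positive Other score."""
    rows = [
        ("1", "metal in eye at work", "work"),
        ("2", "work with metal sheet", "work"),
        ("3", "eye injury from metal at work", "work"),
        ("4", "fell at home", "other"),
        ("5", "tripped at home", "other"),
        ("6", "slipped at home on stairs", "other"),
    ]
    corpus = LabeledCorpus([NarrativeRecord(i, t, l) for i, t, l in rows])
    model = ConceptTagModel(
        corpus, ConceptModelParams(min_term_frequency=2, margin_floor=0.0)
    ).fit()
    record = NarrativeRecord(
        "q",
        "Went home from work after getting piece of metal in eye; eye red and inflamed",
        "work",
    )
    scores = model.score(record)
    assert scores.score_work > scores.score_other > 0


def _random_small_corpus(rng: random.Random) -> LabeledCorpus:
    vocab = [
        "saw", "nail", "hammer", "drill", "brick", "glass", "rope", "pipe",
        "tile", "wire", "pump", "belt", "clamp", "winch", "crate",
    ]
    n = rng.randint(2, 10)
    records = []
    for i in range(n):
        words = rng.sample(vocab, rng.randint(0, 6))
        label = "work" if (i == 0 or rng.random() < 0.5) else "other"
        if i == 1:
            label = "other"  # guarantee both labels
        records.append(NarrativeRecord(str(i), " ".join(words), label))
    return LabeledCorpus(records)


def test_scoring_agrees_with_brute_force_enumeration():
    """Inverted-index scoring is exactly the brute-force concept walk."""
    rng = random.Random(20_260_1)
    checked = 0
    for _ in range(60):
        corpus = _random_small_corpus(rng)
        params = ConceptModelParams(
            min_term_frequency=1,
            margin_floor=0.0,
            concept_generality=rng.choice([1, 3, 10]),
        )
        results = ConceptTagModel(corpus, params).fit()
        for record in corpus:
            fast = results.score(record)
            slow = brute_force_scores(results, record)
            assert fast.score_work == pytest.approx(slow.score_work, abs=1e-12)
            assert fast.score_other == pytest.approx(slow.score_other, abs=1e-12)
            checked += 1
    assert checked >= 300


# ---------------------------------------------------------------------------
# classification rules


@pytest.mark.parametrize(
    "work,other,expected",
    [
        (0.5, 0.0, FourWayClass.WORK_ACTIVITY),
        (0.4, 0.4, FourWayClass.PROBABLE_WORK),  # ties side with work
        (0.2, 0.5, FourWayClass.PROBABLE_OTHER),
        (0.0, 0.3, FourWayClass.OTHER_ACTIVITY),
        (0.0, 0.0, FourWayClass.OTHER_ACTIVITY),  # no evidence
        (0.9, 0.4, FourWayClass.PROBABLE_WORK),
    ],
)
def test_classify_four_way_rules(work, other, expected):
    assert classify_four_way(ClassScores(work, other)) is expected


@pytest.mark.parametrize(
    "work,other,expected", [(0.4, 0.9, True), (0.0, 0.3, False), (0.0, 0.0, False)]
)
def test_classify_binary(work, other, expected):
    assert classify_binary(ClassScores(work, other)) is expected


_scores = st.one_of(st.just(0.0), st.floats(0.0, 10.0, allow_nan=False))


@given(_scores, _scores)
@settings(derandomize=True, max_examples=500)
def test_four_way_total_and_single_valued(work, other):
    value = classify_four_way(ClassScores(work, other))
    # re-derive from first principles: exactly one rule fires
    rules = [
        work > 0 and other == 0,
        work > 0 and other > 0 and work >= other,
        work > 0 and other > 0 and work < other,
        work == 0,
    ]
    assert sum(rules) == 1
    expected = [
        FourWayClass.WORK_ACTIVITY,
        FourWayClass.PROBABLE_WORK,
        FourWayClass.PROBABLE_OTHER,
        FourWayClass.OTHER_ACTIVITY,
    ][rules.index(True)]
    assert value is expected
    assert classify_binary(ClassScores(work, other)) == (work > 0)


# ---------------------------------------------------------------------------
# calibration and adjusted classification


def _po_scores(diffs):
    """ProbableOtherActivity scores with the requested (negative) diffs."""
    scores = {}
    for i, d in enumerate(diffs):
        assert d < 0
        scores[str(i)] = ClassScores(0.5, 0.5 - d)
    return scores


def test_calibrate_cutoff_fixture():
    scores = _po_scores([-0.5, -1.0, -1.5])
    labels = {rid: "work" for rid in scores}
    classes = {rid: classify_four_way(s) for rid, s in scores.items()}
    calibration = calibrate_cutoff(scores, labels, classes)
    assert calibration.cutoff == pytest.approx(1.5)
    mean, sd, n = calibration.by_label["work"]
    assert (mean, sd, n) == (pytest.approx(-1.0), pytest.approx(0.5), 3)


def test_calibrate_cutoff_degenerate_sd_zero():
    scores = _po_scores([-0.7, -0.7])
    labels = {rid: "work" for rid in scores}
    classes = {rid: classify_four_way(s) for rid, s in scores.items()}
    assert calibrate_cutoff(scores, labels, classes).cutoff == pytest.approx(0.7)


def test_calibrate_cutoff_needs_two_work_records():
    scores = _po_scores([-0.5])
    classes = {rid: classify_four_way(s) for rid, s in scores.items()}
    with pytest.raises(ValueError, match=">=2 work-labelled"):
        calibrate_cutoff(scores, {"0": "work"}, classes)


def test_cutoff_from_reported_summary():
    # |mean| + sd construction on the reported group statistics
    assert cutoff_from_summary(-0.83, 0.63) == pytest.approx(1.46)


def test_adjusted_recoding_rules():
    scores = {
        "a": ClassScores(0.5, 1.4),   # diff -0.9: recoded at cutoff 1.47
        "b": ClassScores(0.5, 2.5),   # diff -2.0: stays ProbableOther
        "c": ClassScores(0.5, 0.0),   # WorkActivity untouched
        "d": ClassScores(0.0, 0.4),   # OtherActivity untouched
    }
    classes = {rid: classify_four_way(s) for rid, s in scores.items()}
    adjusted = apply_adjusted_classification(classes, scores, cutoff=1.47)
    assert adjusted.classes["a"] is FourWayClass.PROBABLE_WORK
    assert adjusted.classes["b"] is FourWayClass.PROBABLE_OTHER
    assert adjusted.classes["c"] is FourWayClass.WORK_ACTIVITY
    assert adjusted.classes["d"] is FourWayClass.OTHER_ACTIVITY
    assert adjusted.flags == {"a": True, "b": False, "c": True, "d": False}
    assert adjusted.n_recoded == 1


def test_adjusted_monotone_in_cutoff_and_touches_only_rule3():
    rng = random.Random(17)
    scores = {}
    for i in range(400):
        w = rng.choice([0.0, rng.uniform(0, 3)])
        o = rng.choice([0.0, rng.uniform(0, 3)])
        scores[str(i)] = ClassScores(w, o)
    classes = {rid: classify_four_way(s) for rid, s in scores.items()}
    previous: set[str] = set()
    for cutoff in (0.1, 0.5, 1.0, 2.0, 5.0):
        adjusted = apply_adjusted_classification(classes, scores, cutoff)
        flagged = {rid for rid, f in adjusted.flags.items() if f}
        assert previous <= flagged  # raising cutoff never unflags
        previous = flagged
        for rid, cls in classes.items():
            if cls is not FourWayClass.PROBABLE_OTHER:
                assert adjusted.classes[rid] is cls


def test_adjusted_requires_positive_cutoff():
    with pytest.raises(ValueError):
        apply_adjusted_classification({}, {}, cutoff=0.0)


# ---------------------------------------------------------------------------
# group comparison


def test_ttest_identical_groups_is_zero():
    result = compare_groups_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert result.statistic == pytest.approx(0.0)
    assert result.df == 4


def test_ttest_pooled_hand_computed():
    result = compare_groups_ttest([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
    assert result.statistic == pytest.approx(-3.674, abs=1e-3)
    assert result.df == 4


def test_ttest_zero_variance_rejected():
    with pytest.raises(ValueError, match="pooled variance"):
        compare_groups_ttest([1.0, 1.0], [1.0, 1.0])


def _exact_moment_sample(mean: float, sd: float, n: int) -> np.ndarray:
    x = np.concatenate([np.ones(n // 2), -np.ones(n - n // 2)])
    x = x - x.mean()
    x = x / x.std(ddof=1)
    return mean + sd * x


def test_ttest_reconstructed_group_summaries():
    # groups rebuilt to the reported moments: other n=11662 mean -1.47 sd 0.92,
    # work n=5609 mean -0.83 sd 0.63; pooled t lands near -47
    other = _exact_moment_sample(-1.47, 0.92, 11_662)
    work = _exact_moment_sample(-0.83, 0.63, 5_609)
    result = compare_groups_ttest(other, work)
    assert result.df == 17_269
    assert result.statistic == pytest.approx(-47.1, abs=1.0)
    assert result.pvalue < 0.01


# ---------------------------------------------------------------------------
# persistence


def test_model_roundtrip(tmp_path, toy_model, toy_corpus):
    path = str(tmp_path / "model.json")
    save_model(toy_model, path)
    loaded = load_model(path)
    assert loaded.concepts == toy_model.concepts
    for record in toy_corpus:
        a, b = toy_model.score(record), loaded.score(record)
        assert (a.score_work, a.score_other) == (b.score_work, b.score_other)
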
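"""Index construction and flagging: merging, thresholding, union."""

import random

import pytest

from worknarr import (
    AnnotationRow,
    GeneratorParams,
    NarrativeRecord,
    TermIndex,
    build_index,
    default_index,
    generate_corpus,
    index_flag,
    index_flag_corpus,
    keyword_flag_corpus,
    select_review_sample,
    tokenize,
    union_flag,
)
from worknarr.index import IndexEntry, read_index, write_index


def _ann(heading, keyword, n, start=0):
    return [AnnotationRow(str(start + i), heading, keyword) for i in range(n)]


def test_merge_then_threshold_weld():
    # "weld" (activity) and "welder" (occupation) collapse to one stem whose
    # pooled frequency passes the threshold neither reaches alone
    annotations = _ann("activity task", "weld", 3) + _ann("occupation", "welder", 4, start=10)
    index = build_index(annotations, min_frequency=5)
    assert len(index) == 1
    entry = index.entries[0]
    assert entry.stem == "weld"
    assert entry.frequency == 7
    assert entry.headings == {"activity task", "occupation"}


def test_min_frequency_one_keeps_every_stem():
    annotations = _ann("occupation", "welder", 1) + _ann("work location", "factory", 1, start=5)
    index = build_index(annotations, min_frequency=1)
    assert sorted(index.stems()) == ["factori", "welder"]


def test_all_below_threshold_errors():
    annotations = _ann("activity task", "weld", 2) + _ann("occupation", "welder", 2, start=10)
    with pytest.raises(ValueError, match="min_frequency"):
        build_index(annotations, min_frequency=5)


def test_headings_outside_selection_ignored():
    annotations = _ann("body site", "hand", 10) + _ann("work location", "factory", 6, start=20)
    index = build_index(annotations, min_frequency=5)
    assert index.stems() == ("factori",)


def test_permutation_invariance():
    annotations = (
        _ann("work location", "factory", 6)
        + _ann("object involved", "forklift", 7, start=10)
        + _ann("activity task", "welding", 5, start=20)
    )
    rng = random.Random(3)
    shuffled = annotations[:]
    rng.shuffle(shuffled)
    assert build_index(annotations) == build_index(shuffled)


def test_unknown_heading_rejected():
    with pytest.raises(ValueError):
        AnnotationRow("1", "favourite colour", "blue")


def test_minimal_stem_invariant_enforced():
    with pytest.raises(ValueError, match="prefix"):
        TermIndex(
            (IndexEntry("weld", 9, frozenset()), IndexEntry("welder", 5, frozenset())),
            min_frequency=5,
        )


def _rec(text):
    return NarrativeRecord("x", text, "other")


def test_index_flag_published_terms():
    index = default_index()
    assert index_flag(_rec("fell from forklift at job site"), index)
    assert not index_flag(_rec(""), index)
    assert not index_flag(_rec("fell at home playing football"), index)


def test_index_flag_matches_stem_variants():
    index = default_index()
    # surface forms whose stems the index stores: factory -> factori
    assert index_flag(_rec("crushed finger at the factory"), index)
    assert index_flag(_rec("injured at two factories"), index)
    assert index_flag(_rec("welding burn to arm"), index)


def test_multiword_phrase_matches_across_spaces():
    index = default_index()
    assert index_flag(_rec("fell over at the job   site this morning"), index)
    assert not index_flag(_rec("lost his job yesterday"), index)


def test_index_flag_agrees_with_substring_oracle():
    corpus, _ = generate_corpus(GeneratorParams(n_records=1000, seed=9))
    index = default_index()
    flags = index_flag_corpus(corpus, index)
    for record in corpus:
        hay = tokenize(record.narrative).stemmed_text
        oracle = any(stem in hay for stem in index.stems())
        assert flags[record.record_id] == oracle
    assert 0 < sum(flags.values()) < len(flags)


def test_index_roundtrip(tmp_path):
    annotations = _ann("work location", "factory", 6) + _ann("object involved", "forklift", 7, start=10)
    index = build_index(annotations)
    path = str(tmp_path / "index.tsv")
    write_index(index, path)
    assert read_index(path, min_frequency=index.min_frequency) == index


def test_union_flag_truth_table_and_counts():
    kw = {"1": True, "2": False, "3": False}
    ix = {"1": False, "2": True, "3": False}
    union = union_flag(kw, ix)
    assert union == {"1": True, "2": True, "3": False}
    assert sum(union.values()) == len({k for k, v in kw.items() if v} | {k for k, v in ix.items() if v})


def test_union_flag_domain_mismatch():
    with pytest.raises(ValueError, match="3"):
        union_flag({"1": True, "3": False}, {"1": True, "2": False})


def test_review_sample_contract(synthetic_20k):
    corpus, _ = synthetic_20k
    kw = keyword_flag_corpus(corpus)
    sample = select_review_sample(corpus, kw, 500, seed=4)
    assert len(sample) == 500
    assert all(r.activity_label == "work" for r in sample)
    assert all("work" not in r.narrative.casefold() for r in sample)
    again = select_review_sample(corpus, kw, 500, seed=4)
    assert sample.ids() == again.ids()
    assert select_review_sample(corpus, kw, 0, seed=4).ids() == []
    with pytest.raises(ValueError, match="work-labelled keyword-negative"):
        select_review_sample(corpus, kw, len(corpus), seed=4)
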
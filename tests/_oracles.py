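"""Independent brute-force oracles used by the concept-scoring tests."""

from worknarr import ClassScores, StopList, apply_stoplist, tokenize
from worknarr.corpus import WORK


def brute_force_scores(results, record) -> ClassScores:
    """Enumerate every concept and sum association x best member weight.

    Deliberately naive (no inverted index): walks all concepts and all
    members for each record.
    """
    stems = set(
        apply_stoplist(tokenize(record.narrative), results.model.stoplist).stems
    )
    work = 0.0
    other = 0.0
    for concept in results.concepts:
        matched = [w for member, w in concept.members.items() if member in stems]
        if not matched:
            continue
        if concept.assoc_work > concept.assoc_other:
            work += concept.assoc_work * max(matched)
        else:
            other += concept.assoc_other * max(matched)
    return ClassScores(work, other)
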
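"""Structured-text (JSON) serialization of fitted concept models.

The file carries everything scoring needs — concepts with their member
weights and tag associations, the learning parameters, and the resolved
stop list — so a saved model can be inspected with any text tools and
reloaded without the training corpus.
"""

from __future__ import annotations

import json

from .concepts import Concept, ConceptModelParams, ConceptTagModel, ConceptTagResults
from .corpus import LabeledCorpus
from .normalize import StopList

FORMAT_VERSION = 1


def save_model(results: ConceptTagResults, path: str) -> None:
    payload = {
        "format_version": FORMAT_VERSION,
        "params": {
            "concept_generality": results.params.concept_generality,
            "max_seed_concepts": results.params.max_seed_concepts,
            "min_term_frequency": results.params.min_term_frequency,
            "margin_floor": results.params.margin_floor,
            "member_affinity_floor": results.params.member_affinity_floor,
            "smoothing": results.params.smoothing,
            "seed": results.params.seed,
        },
        "training_summary": results.training_summary,
        "stoplist": {
            "excluded": sorted(results.model.stoplist.excluded),
            "retained_overrides": sorted(results.model.stoplist.retained_overrides),
        },
        "concepts": [
            {
                "seed_stem": c.seed_stem,
                "members": dict(sorted(c.members.items())),
                "assoc_work": c.assoc_work,
                "assoc_other": c.assoc_other,
                "n_train": c.n_train,
            }
            for c in results.concepts
        ],
    }
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(payload, handle, indent=1)
        handle.write("\n")


def load_model(path: str) -> ConceptTagResults:
    with open(path, encoding="utf-8") as handle:
        payload = json.load(handle)
    if payload.get("format_version") != FORMAT_VERSION:
        raise ValueError(f"unsupported model file version: {payload.get('format_version')}")
    params = ConceptModelParams(**payload["params"])
    stoplist = StopList(
        frozenset(payload["stoplist"]["excluded"]),
        frozenset(payload["stoplist"]["retained_overrides"]),
    )
    shell = ConceptTagModel(LabeledCorpus([], provenance=path), params, stoplist)
    concepts = tuple(
        Concept(
            c["seed_stem"],
            {k: float(v) for k, v in c["members"].items()},
            float(c["assoc_work"]),
            float(c["assoc_other"]),
            int(c["n_train"]),
        )
        for c in payload["concepts"]
    )
    return ConceptTagResults(shell, concepts, dict(payload["training_summary"]))
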
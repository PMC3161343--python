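"""Sensitivity / specificity / PPV of method flags against the gold label.

The coded activity label is the measurement standard: sensitivity is the
proportion of gold work cases flagged, specificity the proportion of
gold non-work cases not flagged, and PPV the proportion of flagged
cases that are gold work cases.  Records with a missing label are
excluded here (and counted), never at load time.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Mapping
from dataclasses import dataclass

from .corpus import MISSING, WORK, LabeledCorpus

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvalResult:
    """Confusion counts and the derived screening metrics."""

    tp: int
    fp: int
    fn: int
    tn: int
    n_excluded_missing: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_evaluated(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity(self) -> float:
        return _ratio(self.tp, self.tp + self.fn, "sensitivity")

    @property
    def specificity(self) -> float:
        return _ratio(self.tn, self.tn + self.fp, "specificity")

    @property
    def ppv(self) -> float:
        return _ratio(self.tp, self.tp + self.fp, "ppv")


def _ratio(num: int, denom: int, name: str) -> float:
    if denom == 0:
        logger.warning("%s undefined: zero denominator", name)
        return math.nan
    return num / denom


def metrics_from_counts(tp: int, fp: int, fn: int, tn: int) -> tuple[float, float, float]:
    """(sensitivity, specificity, ppv) from confusion counts.

    Undefined ratios are returned as NaN, never silently zero.  This is
    the closed form used to recompute published contingency tables.
    """
    result = EvalResult(tp, fp, fn, tn)
    return result.sensitivity, result.specificity, result.ppv


def evaluate(flags: Mapping[str, bool], corpus: LabeledCorpus) -> EvalResult:
    """Cross-tabulate flags against gold labels (missing labels excluded)."""
    missing_ids = [r.record_id for r in corpus if r.record_id not in flags]
    if missing_ids:
        preview = ", ".join(missing_ids[:10])
        raise ValueError(f"flags missing {len(missing_ids)} record(s): {preview}")
    tp = fp = fn = tn = excluded = 0
    for record in corpus:
        if record.activity_label == MISSING:
            excluded += 1
            continue
        flagged = bool(flags[record.record_id])
        is_work = record.activity_label == WORK
        if flagged and is_work:
            tp += 1
        elif flagged:
            fp += 1
        elif is_work:
            fn += 1
        else:
            tn += 1
    if excluded:
        logger.info("excluded %d records with missing activity label", excluded)
    return EvalResult(tp, fp, fn, tn, excluded)


def overlap_counts(
    flag_sets: Mapping[str, Mapping[str, bool]],
    corpus: LabeledCorpus,
    gold_name: str = "gold",
) -> dict[str, int]:
    """Region counts of the Venn partition of the flag sets plus the gold
    work set.

    Keys are '&'-joined sorted member names for every non-empty
    combination (zero counts included); values sum to the size of the
    union of all sets.  Missing-label records cannot join the gold set
    but may join flag sets.
    """
    if len(flag_sets) < 2:
        raise ValueError("need at least two flag sets")
    if gold_name in flag_sets:
        raise ValueError(f"flag set name {gold_name!r} collides with the gold set")
    domain = set(corpus.ids())
    for name, flags in flag_sets.items():
        if set(flags) != domain:
            raise ValueError(f"flag set {name!r} does not cover the corpus id domain")

    sets: dict[str, set[str]] = {
        name: {rid for rid, v in flags.items() if v} for name, flags in flag_sets.items()
    }
    sets[gold_name] = {r.record_id for r in corpus if r.activity_label == WORK}

    names = sorted(sets)
    regions: dict[str, int] = {}
    from itertools import combinations

    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            regions["&".join(combo)] = 0
    membership: dict[str, list[str]] = {}
    for name, members in sets.items():
        for rid in members:
            membership.setdefault(rid, []).append(name)
    for rid, members in membership.items():
        regions["&".join(sorted(members))] += 1
    return regions
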
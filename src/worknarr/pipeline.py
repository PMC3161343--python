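"""End-to-end pipeline: simulate -> build/train -> flag/classify -> evaluate.

One call wires the whole comparison: generate (or load) a labelled
corpus, flag it with the keyword rule, draw the review sample and build
the term index, fit the concept model, calibrate the recoding cutoff,
and evaluate all five methods (keyword, index, keyword-or-index, binary
concept, adjusted concept) against the gold activity label.  Reports
are plain delimited text plus a run log that records every seed and
parameter needed to reproduce the outputs byte-identically.
"""

from __future__ import annotations

import configparser
import csv
import dataclasses
import logging
import math
import os
from dataclasses import dataclass, field

from . import __version__
from .concepts import (
    ConceptModelParams,
    ConceptTagModel,
    CutoffCalibration,
    apply_adjusted_classification,
    classify_binary,
    classify_four_way,
    compare_groups_ttest,
)
from .corpus import MISSING, OTHER, WORK, LabeledCorpus, read_corpus, write_corpus, write_predictions
from .evaluate import EvalResult, evaluate, overlap_counts
from .index import (
    DEFAULT_INDEX_HEADINGS,
    DEFAULT_MIN_FREQUENCY,
    build_index,
    index_flag_corpus,
    read_annotations,
    select_review_sample,
    union_flag,
    write_annotations,
    write_index,
)
from .keyword import KeywordRule, keyword_flag_corpus
from .simulate import GeneratorParams, generate_corpus
from .evaluate import metrics_from_counts  # noqa: F401  (re-export convenience)

logger = logging.getLogger(__name__)

METHODS = ("keyword", "index", "keyword_or_index", "concept_binary", "concept_adjusted")


@dataclass
class RunConfig:
    """Flat configuration for one full pipeline run."""

    out_dir: str = "worknarr_out"
    corpus_path: str | None = None  # None -> simulate
    annotations_path: str | None = None
    seed: int = 0
    # simulate
    n_records: int = 208_291
    # keyword
    keyword_pattern: str = "work"
    # index
    review_sample_n: int = 1000
    index_min_frequency: int = DEFAULT_MIN_FREQUENCY
    # concepts
    concept_generality: int = 10
    concept_min_term_frequency: int = 5
    concept_margin_floor: float = 0.2
    concept_smoothing: float = 1.0
    # classification
    cutoff: str = "auto"  # "auto" or a positive number as text
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        parser = configparser.ConfigParser()
        with open(path, encoding="utf-8") as handle:
            parser.read_string("[run]\n" + handle.read())
        merged: dict[str, str] = {}
        for section in parser.sections():
            merged.update(parser[section])
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in merged:
                raw = merged[f.name]
                if f.type in ("int", int):
                    kwargs[f.name] = int(raw)
                elif f.type in ("float", float):
                    kwargs[f.name] = float(raw)
                elif f.name in ("corpus_path", "annotations_path"):
                    kwargs[f.name] = raw or None
                else:
                    kwargs[f.name] = raw
        return cls(**kwargs)

    def generator_params(self) -> GeneratorParams:
        return GeneratorParams(n_records=self.n_records, seed=self.seed)

    def concept_params(self) -> ConceptModelParams:
        return ConceptModelParams(
            concept_generality=self.concept_generality,
            min_term_frequency=self.concept_min_term_frequency,
            margin_floor=self.concept_margin_floor,
            smoothing=self.concept_smoothing,
            seed=self.seed,
        )


@dataclass
class PipelineReport:
    """In-memory result of a run: per-method evaluation plus extras."""

    results: dict[str, EvalResult]
    flags: dict[str, dict[str, bool]]
    cutoff: float | None
    calibration: CutoffCalibration | None
    overlap: dict[str, int]
    out_dir: str
    ttest: object | None = None


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
                raise PipelineStageError(name, exc) from exc
        return inner
    return wrap


def run_pipeline(config: RunConfig) -> PipelineReport:
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    os.makedirs(config.out_dir, exist_ok=True)
    log_lines: list[str] = [
        f"worknarr {__version__} pipeline run",
        f"seed = {config.seed}",
    ]

    # -- corpus ------------------------------------------------------------
    if config.corpus_path is None:
        params = config.generator_params()
        corpus, annotations = _stage("simulate")(generate_corpus)(params)
        write_corpus(corpus, os.path.join(config.out_dir, "corpus.csv"))
        write_annotations(annotations, os.path.join(config.out_dir, "annotations.csv"))
        log_lines.append(f"simulated corpus: {dataclasses.asdict(params)}")
    else:
        corpus = _stage("load-corpus")(read_corpus)(config.corpus_path)
        annotations = (
            _stage("load-annotations")(read_annotations)(config.annotations_path)
            if config.annotations_path
            else []
        )
        log_lines.append(f"loaded corpus from {config.corpus_path}")
    counts = corpus.label_counts()
    log_lines.append(
        f"records = {len(corpus)} (work={counts[WORK]}, other={counts[OTHER]}, "
        f"missing={counts[MISSING]})"
    )

    # -- keyword -----------------------------------------------------------
    rule = KeywordRule(pattern=config.keyword_pattern)
    kw_flags = _stage("keyword")(keyword_flag_corpus)(corpus, rule)

    # -- index -------------------------------------------------------------
    def _index_stage():
        eligible = sum(
            1 for r in corpus
            if r.activity_label == WORK and not kw_flags[r.record_id]
        )
        n = min(config.review_sample_n, eligible)
        if n < config.review_sample_n:
            logger.warning(
                "only %d eligible records for review sample (requested %d)",
                eligible, config.review_sample_n,
            )
        sample = select_review_sample(corpus, kw_flags, n, config.seed)
        sample_ids = set(sample.ids())
        sample_annotations = [a for a in annotations if a.record_id in sample_ids]
        index = build_index(
            sample_annotations, DEFAULT_INDEX_HEADINGS, config.index_min_frequency
        )
        return sample, index

    sample, index = _stage("build-index")(_index_stage)()
    write_index(index, os.path.join(config.out_dir, "index.tsv"))
    log_lines.append(
        f"review sample n = {len(sample)}; index terms = {len(index)} "
        f"(min_frequency={config.index_min_frequency})"
    )
    idx_flags = _stage("index-flag")(index_flag_corpus)(corpus, index)
    union = _stage("union-flag")(union_flag)(kw_flags, idx_flags)

    # -- concepts ----------------------------------------------------------
    fitted = _stage("concept-train")(
        lambda: ConceptTagModel(corpus, config.concept_params()).fit()
    )()
    log_lines.append(
        f"concept model: {fitted.training_summary['n_concepts']} concepts "
        f"from {fitted.training_summary['n_seeds']} seeds"
    )
    scores = _stage("concept-score")(fitted.score_corpus)(corpus)
    binary = {rid: classify_binary(s) for rid, s in scores.items()}
    classes = {rid: classify_four_way(s) for rid, s in scores.items()}

    calibration: CutoffCalibration | None = None
    cutoff: float | None = None
    ttest = None
    if config.cutoff == "auto":
        try:
            from .concepts import calibrate_cutoff

            calibration = calibrate_cutoff(scores, corpus.labels(), classes)
            cutoff = calibration.cutoff
            log_lines.append(
                "cutoff calibration (ProbableOtherActivity group): "
                + "; ".join(
                    f"{label}: mean={m:.4f} sd={s:.4f} n={n}"
                    for label, (m, s, n) in calibration.by_label.items()
                )
                + f"; cutoff = {cutoff:.4f}"
            )
            if OTHER in calibration.by_label and calibration.by_label[OTHER][2] >= 2:
                group_w = [
                    scores[rid].diff for rid, c in classes.items()
                    if c.value == "ProbableOtherActivity" and corpus.labels()[rid] == WORK
                ]
                group_o = [
                    scores[rid].diff for rid, c in classes.items()
                    if c.value == "ProbableOtherActivity" and corpus.labels()[rid] == OTHER
                ]
                ttest = compare_groups_ttest(group_o, group_w)
                log_lines.append(
                    f"probability-difference comparison: t = {ttest.statistic:.2f}, "
                    f"df = {ttest.df}, p = {ttest.pvalue:.3g}"
                )
        except ValueError as exc:
            logger.warning("cutoff calibration skipped: %s", exc)
            log_lines.append(f"cutoff calibration skipped: {exc}")
    else:
        cutoff = float(config.cutoff)
        log_lines.append(f"cutoff fixed by configuration: {cutoff}")

    if cutoff is not None:
        adjusted = apply_adjusted_classification(classes, scores, cutoff)
        adj_flags = dict(adjusted.flags)
        log_lines.append(f"adjusted classification recoded {adjusted.n_recoded} records")
    else:
        adj_flags = {
            rid: c.value in ("WorkActivity", "ProbableWorkActivity")
            for rid, c in classes.items()
        }

    # -- evaluation --------------------------------------------------------
    flags = {
        "keyword": kw_flags,
        "index": idx_flags,
        "keyword_or_index": union,
        "concept_binary": binary,
        "concept_adjusted": adj_flags,
    }
    results = {name: _stage("evaluate")(evaluate)(f, corpus) for name, f in flags.items()}
    overlap = _stage("overlap")(overlap_counts)(
        {"keyword": kw_flags, "concept_adjusted": adj_flags}, corpus
    )

    # -- reports -----------------------------------------------------------
    write_predictions(corpus, flags, os.path.join(config.out_dir, "flags.csv"))
    report_path = os.path.join(config.out_dir, "report.csv")
    with open(report_path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(
            ["method", "tp", "fp", "fn", "tn", "sensitivity", "specificity", "ppv"]
        )
        for name in METHODS:
            r = results[name]
            writer.writerow(
                [name, r.tp, r.fp, r.fn, r.tn]
                + [_fmt(v) for v in (r.sensitivity, r.specificity, r.ppv)]
            )
    with open(os.path.join(config.out_dir, "overlap.csv"), "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["region", "count"])
        for region, count in sorted(overlap.items()):
            writer.writerow([region, count])
    n_excluded = next(iter(results.values())).n_excluded_missing
    log_lines.append(f"records excluded from evaluation (missing label) = {n_excluded}")
    for name in METHODS:
        r = results[name]
        log_lines.append(
            f"{name}: tp={r.tp} fp={r.fp} sens={_fmt(r.sensitivity)} "
            f"spec={_fmt(r.specificity)} ppv={_fmt(r.ppv)}"
        )
    with open(os.path.join(config.out_dir, "run_log.txt"), "w", encoding="utf-8") as handle:
        handle.write("\n".join(log_lines) + "\n")

    return PipelineReport(results, flags, cutoff, calibration, overlap, config.out_dir, ttest)


def _fmt(value: float) -> str:
    return "NA" if math.isnan(value) else f"{value:.4f}"
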
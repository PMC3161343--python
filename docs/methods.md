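# Methods

This note documents the models and procedures implemented in
`worknarr`, the assumptions behind them, the parameters that matter, and
the choices made where the design was genuinely open.

## Problem setting

Injury surveillance systems built on emergency-department presentations
record a short free-text injury description (at most 255 characters of
triage shorthand) and, in some systems, a coded *activity* field whose
"working for an income" category marks occupational injuries. Where the
code is absent, case ascertainment must come from the text. The package
compares three interrogation families against the coded label treated
as the measurement standard: keyword search, index-term search, and
tag-supervised concept classification. All three are deliberately
*high-recall first-pass screens*: the presence of target words, phrases
or concepts is sufficient to flag a case as potentially work-related,
and negation phrases ("not working properly") never rule a case out,
because such wording occurs inside genuinely work-related narratives.

## Text normalization

Narratives are case-folded and split on any run of non-alphanumeric
characters, so hyphenated compounds contribute their parts; numerals
are kept (ages and dates can discriminate, and dropping them loses
information). Each narrative is one undivided context block — there is
no sentence segmentation, because triage text is rarely grammatical
prose. Stemming is the classic Porter suffix-stripping algorithm,
implemented in-package and pinned by a golden test against the
algorithm's published example vectors, so grammatical variants collapse
onto one term (work/works/working → `work`). The shipped stop list is a
generic English function-word list from which words that can name body
parts (back, face, feet), injury mechanisms (cut) or injurious objects
(saw) are rescued by an override list; both files are user-replaceable,
and the override list is a design artifact of this package — no
canonical modified stop list exists for this domain.

## Keyword search

A record flags if the pattern (default `work`) occurs case-insensitively
as a **substring of the raw narrative**. Substring rather than token
matching is intentional: it covers `worker`, `work-related` and
compounds without a morphology model, at the accepted cost of
incidental matches (`woodworking`). Matching runs on the raw casefolded
text, not the token stream, so punctuation cannot block a match.

## Index search

The index is built the way a surveillance unit would: draw a seeded
random sample (default n = 1000) of work-labelled, keyword-negative
records; consume a manual annotation table assigning each extracted
word or phrase to one of 16 fixed headings; pool the five work-specific
headings (activity task, object involved, work location, occupation,
safety/preventative devices); stem each keyword; reduce to minimal
stems by folding any entry that another entry prefixes into that
shorter root (frequencies summed — `weld` absorbs `welder` and
`welding`); and drop stems with pooled frequency below `min_frequency`
(default 5), which keeps the index compact enough for general use.
Merging runs **before** the threshold, so fragmented variants of one
stem can jointly clear it; this ordering is a design choice the
builder documents rather than an externally fixed rule. The builder is
permutation-invariant and the resulting index satisfies a minimal-stem
invariant (no entry is a prefix of another).

Flagging matches each index stem as a substring of the narrative's
*stemmed token stream* (stems joined by single spaces). This is
deliberate: Porter stems such as `factori` are not substrings of the
surface word "factory", so raw-text matching could never match the
stems the builder itself produces; matching in stem space makes
`factori` cover factory/factories and `weld` cover welding/welder,
and multi-word phrases ("job site") match across any whitespace or
punctuation. The manual annotation step itself is out of scope: the
package consumes annotation files and ships a synthetic annotation
table produced by the generator. The shipped default index contains
the handful of published work-specific terms plus clearly marked
synthetic vocabulary; real analyses should build their own.

## Concept classification

The concept classifier is an open algorithm with the behavioural
contract of tag-supervised content-analytic text mining: concepts are
discovered from term frequency and within-narrative co-occurrence,
associations are learned from the coded groups ("tags"), and a record
may carry positive relevance for both tags at once.

With `df(s)` the number of training narratives containing stem `s`
after stop-listing (missing-label records are ignored for learning):

* **Seeds.** Stems with `df(s) ≥ min_term_frequency` (default 5) seed
  concepts, most frequent first; the number of concepts is otherwise
  uncapped.
* **Thesaurus.** Concept `C(s)` adopts up to `concept_generality`
  (default 10, keeping concepts narrow) member stems `t` ranked by
  affinity `df(s∧t)/df(t)`, admitted only if that affinity is at least
  `member_affinity_floor` (default 0.5, i.e. the member predominantly
  accompanies the seed). The adopted weight is the co-occurrence ratio
  `w(t|s) = df(s∧t)/df(s)`; the seed itself has weight 1. The affinity
  gate is essential: without it, concepts adopt ubiquitous words that
  merely co-occur with everything and then fire on nearly every record,
  destroying specificity. It is also the mechanism that absorbs
  misspelt variants of a term (which co-occur almost exclusively with
  their correctly spelt neighbours) into the concept.
* **Associations.** `assoc_c = (n_c + k)/(n_work + n_other + 2k)` with
  add-one smoothing (`k = 1`), counting records containing the *seed*.
  Seed-presence counting (rather than any-member) keeps the association
  an estimate of P(class | concept's defining term), which is the
  quantity the smoothed ratio is meant to be. Concepts with margin
  `|assoc_Work − assoc_Other| < margin_floor` (default 0.2) are
  non-discriminating and dropped.
* **Scoring.** A concept matches a record if any member stem occurs in
  its stop-listed stem stream; it contributes `assoc × best matched
  member weight` **to its dominant tag only**. Summing each concept
  into both tags was considered and rejected: with smoothing, both
  associations are strictly positive, so both scores would be positive
  for every non-empty narrative, the one-sided classification rules
  (exactly one score zero) could never fire, and the binary technique
  (any Work evidence) would flag everything. Assigning each concept to
  the group it discriminates matches the discriminating-concept
  discovery the approach is built on. Scores are unnormalized relevance
  sums and routinely exceed 1; only their comparison and difference
  matter.
* **Classification.** Binary: flag iff `score_Work > 0`. Four-way:
  Work > 0 ∧ Other = 0 → WorkActivity; both > 0 ∧ Work ≥ Other →
  ProbableWork (ties side with Work by rule); both > 0 ∧ Work < Other →
  ProbableOther; Work = 0 → OtherActivity. A no-evidence (0, 0) record
  is OtherActivity: with no information in the text, no interrogation
  method can identify the case, and defaulting to the majority class is
  the honest outcome.
* **Adjusted cutoff.** Over gold-work records classified ProbableOther,
  the cutoff is `|mean(d)| + sd(d)` where `d = score_Work − score_Other`
  and sd is the sample (n−1) standard deviation; ProbableOther records
  with `|d|` below the cutoff are recoded ProbableWork, and the final
  flag is membership of {WorkActivity, ProbableWork}. Only rule-3
  records can change, and raising the cutoff can only add flags. On the
  reported group summary mean −0.83, sd 0.63 this construction gives
  1.46; analyses of this design have applied 1.47 (the group-mean
  magnitude of the other class coincides with it), so the calibrator
  computes the stated formula and any fixed override can be supplied
  instead — the package does not guess between the two.
* **Group comparison.** The Work-vs-Other comparison of score
  differences in the ProbableOther stratum is a pooled-variance
  two-sample t-test with df = nA + nB − 2 (the df convention used when
  such comparisons are reported for this design).

Training and application run on the same corpus by default, matching
how such screens are calibrated in practice; scoring a held-out corpus
is a one-argument option (`score_corpus(other_corpus)`) for honest
out-of-sample use. The model is deterministic given corpus and
parameters; all tie-breaks (equal frequencies, equal affinities) fall
back to lexicographic stem order.

## Evaluation

Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), PPV = TP/(TP+FP),
computed against the coded label; records with a missing label are
excluded *here*, counted and logged — never at load time, so loaders
never drop rows. Undefined ratios (zero denominators) are reported as
NaN with a logged reason, never silently as zero. Overlap analysis
returns the count of every region of the Venn partition of the supplied
flag sets plus the gold work set; region counts sum exactly to the size
of the union. No confidence intervals are attached to the metrics: at
surveillance-corpus sizes their binomial uncertainty is negligible
relative to the design differences between methods.

## Synthetic data generator

The generator emulates the class-conditional *structure* of an ED
surveillance corpus, not clinical language. Defaults are the study
conditions the package was designed around: 208,291 records; work
prevalence 0.103; P(keyword | work) = 0.5816 and
P(keyword | other) = 0.0103 (other-class keyword hits realized through
negation phrasing such as "saw was not working properly"); index-term
emission at 0.522 among work cases — the rate observed when 522 of a
1000-case keyword-negative review sample carried index terms — and
0.1254 among other cases; 10 records with a missing activity label.
Where no value was externally fixed, realistic rates were chosen once:
negation phrasing inside 5% of keyword-positive work narratives, 2%
scant/empty descriptions, 5% per-token misspelling probability.

Three generator choices deserve explanation. First, index terms are
planted in *all* work records at the 0.522 rate, not only
keyword-negative ones: narratives that mention "work" also mention
worksites and machinery, and restricting emission to keyword-negative
cases would make the work-side index rate implausibly low. Second, the
vocabulary distinguishes work-specific terms (factory, forklift,
scaffold, …) from *ambiguous* terms (mine, farm, truck, ladder, …)
that legitimately occur in both classes; other-class index emission
draws 80% from the ambiguous pool, so per-term work-specificity is
high for specific terms and low for ambiguous ones — the pattern real
index vocabularies show. Third, misspellings are single-character edits
applied only to non-planted tokens, and an edit is discarded if it
would create the keyword or any plantable vocabulary stem, so the
configured detection rates are never perturbed.

The companion annotation table lists the planted terms of work-labelled
keyword-negative records under their semantic headings — exactly the
population the review sample draws from — so the index builder runs
end-to-end. A `plant_worked_example` helper appends one fixed
mixed-evidence narrative (home + work + metal + eye) for smoke tests.

**What passing tests on synthetic data show.** Because emission rates
are planted by construction, recovering them (e.g. keyword sensitivity
0.58, specificity 0.99 on the default corpus) validates the flag →
evaluate mechanics, determinism and bookkeeping of the package. It says
nothing about how these methods perform on any real surveillance
system: real triage text has abbreviation conventions, formulaic
phrases, regional vocabulary and label noise the generator does not
model, and the generator's template grammar makes concept learning
easier than reality would.

## Problem sizes and numerical checks

The test suite exercises the generator at up to 200,000 records (the
keyword calibration check) and the concept learner at 20,000; the
acceptance script runs the full five-method comparison at the default
208,291. Scoring uses an inverted member-stem index and is verified
against a naive concept-by-concept enumeration on hundreds of small
random corpora; keyword and index flags are verified against naive
substring scans. Property tests cover stemmer idempotence, stop-list
order preservation, four-way rule exhaustiveness/exclusivity (including
zeros and exact ties), cutoff monotonicity, and index
permutation-invariance.

## Known limitations

* The concept engine is an open re-implementation of a behavioural
  contract; it does not reproduce any proprietary software's numeric
  output, and its "probabilities" are explicitly unnormalized relevance
  scores.
* The shipped default index and stop-list override are package
  artifacts; only a handful of published index terms exist, so real
  deployments must build their own index from an annotated sample.
* Substring keyword matching accepts incidental matches by design;
  whether that trade-off suits a given corpus must be checked there.
* Duplicate presentations are not detected; every row is treated as a
  distinct case.
* No spelling correction or abbreviation expansion is attempted — term
  matching tolerates misspellings only insofar as the concept thesaurus
  absorbs frequent variants.
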
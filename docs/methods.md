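# Methods

## The screening problem

Title/abstract screening is the first pass of a systematic review: every
record retrieved by the database searches is included or excluded from the
review on the strength of its title and abstract alone, judged against the
review's PICOS eligibility criteria (Population, Intervention, Comparison,
Outcome, Study design). Screening corpora are extremely imbalanced — for
treatment meta-analyses the fraction of truly includable records typically
lies between about 0.2% and 4% — and missing an eligible study (a false
negative) is far costlier than carrying an ineligible one into full-text
review (a false positive). Those two facts shape every statistical choice in
this package.

## The three-role adjudication model

`triscreen` models screening as a collaboration of three language-model
roles, mirroring how human review teams work:

1. **Reviewer** — makes the initial include/exclude call on every record
   against the PICOS criteria, with a stated reason.
2. **Critic** — re-evaluates every record against the same criteria,
   knowing the reviewer's verdict (and, by default, its reasoning), and
   gives an independent verdict.
3. **Arbitrator** — re-analyzes *only* the records on which the reviewer
   and critic disagree and makes the final determination.

The final verdict is the shared verdict when the first two roles agree and
the arbitrator's verdict otherwise. Two structural invariants follow and
are enforced: every record receives exactly one final verdict, and
arbitrator token usage is exactly zero on a run without disagreements.

PICOS elements left empty are legitimate (a review may genuinely not
restrict the comparator); they are flagged as *unspecified* and rendered in
the prompts as "not restricted — do not exclude on this element", so an
unstated element widens the effective scope rather than silently narrowing
it. A task with **all five** elements empty is rejected outright.

### Prompts and the response contract

All roles share one prompt layout: a role preamble, the PICOS block, one
delimited block per record (stable id, title, abstract, and the prior
verdict(s) where the role calls for them), and an instruction to answer
with a JSON array of `{id, verdict, reason}` objects. Parsing tries the
structured JSON form first and falls back to a lenient per-line pattern;
a batch whose response still lacks a usable verdict for some record is
retried (2 retries by default) and then surfaced as an error carrying
partial progress. Records are batched (default batch size 10) and results
are always emitted in corpus order.

The critic sees the reviewer's verdict and reasoning; the arbitrator sees
the two conflicting verdicts but not the reasonings, which keeps
arbitrator prompts short on the conflicted subset. Both choices are
configuration toggles, not hard-wired behaviour.

### Backends

The completion backend is pluggable behind a one-method contract
(`complete(profile, prompt) -> (text, usage)`):

* **MockBackend** — fully deterministic and offline. It reads the PICOS
  block and the record blocks back out of the prompt and votes *include*
  when at least `threshold` distinct criteria keywords (word tokens of 4+
  characters from the specified PICOS elements) occur in the record's
  title+abstract. It is monotone by construction: adding a criteria keyword
  present in a record's text can only raise the match count.
* **ScriptedBackend** — answers from precomputed per-role verdict tables;
  the bridge between the error-model simulator and the real pipeline.
* **OpenAIChatBackend** — a generic chat-completion HTTP adapter
  (OpenAI-compatible wire shape) with an injectable transport so it can be
  tested without a network. Vendor-specific endpoints are out of scope.

Default hyperparameters bind temperature 0 so reruns with a deterministic
backend are byte-reproducible.

## Bibliographic input, identifiers, deduplication

RIS and NBIB/MEDLINE are line-tagged plain-text formats; the parsers map
the conventional tags (TI/T1, AB/N2, AU, PY/Y1/DP, DO, LID/AID `[doi]`,
FAU, JT …), join continuation lines with single spaces, accept both the
two-space and one-space RIS separator dialects, and keep every tag seen in
`raw_fields` so a parsed corpus writes back out without loss. A record
missing its `ER` terminator at end of file is emitted with a warning rather
than dropped; undecodable bytes are replaced with a warning by default
(strict mode raises, naming the byte offset). Year extraction takes the
first 4-digit group of the date field and records no year otherwise.

Record identifiers are deterministic and **source-qualified**:
`db:DOI`, else `db:pmidNNN`, else `db:ordinal`. Qualifying by source
database is deliberate — the package's central use case is merging exports
of the *same* publication from several databases before deduplication, and
an id derived from the DOI alone would collide at exactly that point. The
DOI itself remains a record field and drives the strongest dedup rule.

Deduplication unions three signals into a transitive duplicate relation:
case-insensitive DOI equality; exact normalized-title equality (casefold,
punctuation and dashes replaced by spaces, whitespace collapsed) gated on
co-matching first-author surname and year; and, when enabled, a token-set
title similarity at a configurable threshold in (0.5, 1.0], gated the same
way. Fuzzy matching is off by default: the exact rules already absorb
case, punctuation and spacing noise, and a fuzzy threshold is a corpus
policy decision the user should make explicitly. Each duplicate group keeps
one representative — the first member with a non-empty abstract, else the
earliest in input order — so collapsing duplicates never discards an
abstract that one database supplied and another omitted.

Blank-abstract records (empty or whitespace-only) are filtered before
screening by default, since title-only records cannot be judged on
abstract content; the filter is a switch, and the removed partition is
preserved for audit.

## The evaluation panel

All metrics derive from the 2×2 table of final verdicts vs gold labels
(TP/FP/FN/TN, positive class configurable, *include* by default):

* accuracy `p_o = (TP+TN)/n`; precision `TP/(TP+FP)`; recall `TP/(TP+FN)`;
  `F1 = 2PR/(P+R)`; each computed for both orientations of the positive
  class, because screening studies report exclusion-oriented and
  inclusion-oriented panels separately;
* `F_β = (1+β²)PR/(β²P+R)` with β = 2 by default, weighting recall over
  precision — the cost asymmetry of screening;
* balanced accuracy = mean of the two class recalls; Matthews correlation
  coefficient `(TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN))`;
* Cohen's `κ = (p_o − p_e)/(1 − p_e)` with marginal chance agreement
  `p_e = [(TP+FP)(TP+FN) + (FN+TN)(FP+TN)]/n²`, and
  `PABAK = 2·p_o − 1`, the prevalence-adjusted bias-adjusted κ, which fixes
  the chance term at 1/2. Under extreme imbalance both marginals
  concentrate on *exclude*, `p_e → p_o`, and κ collapses toward zero even
  at near-perfect raw agreement; PABAK does not, which is why it is the
  agreement summary of record for screening corpora. PABAK ≡ 2·accuracy − 1
  is an exact identity and is property-tested as such.

Degenerate tables follow documented conventions rather than raising:
precision with zero predicted positives is 0 with a warning (conservative);
recall with zero actual positives is undefined and reported as missing,
propagating to F-scores and balanced accuracy; MCC with a zero factor is 0;
κ at `p_e = 1` is 1 when `p_o = 1` and 0 otherwise. Values are kept at full
precision internally; display rounding is 2 d.p.

Cross-dataset summaries weight each dataset's metric by its record count
(`Σwᵢxᵢ/Σwᵢ`); the pooled accuracy `Σ correct/Σ n` coincides with the
weighted mean accuracy. The SD is the unweighted sample SD across datasets
(0 for a single dataset) and the range is the min–max pair, matching the
mean/SD/range triplet convention of screening reports. The paired
κ-vs-PABAK comparison tests whether imbalance systematically depresses κ:
the per-dataset differences are checked for normality (Shapiro–Wilk,
α = .05), then a paired two-tailed t test (df = n−1) or a Wilcoxon
signed-rank test is applied; all-zero (or constant) differences are a
flagged degenerate case with no statistic. `scipy.stats` provides the three
underlying tests; the 2×2 panel itself is authored here and cross-checked
against scikit-learn in the test suite.

## Cost and runtime accounting

Every backend call is logged with stage, model, start/end timestamps and
token usage. Cost is the ledger × price-table product:
`Σ (prompt·input_price + completion·output_price)/10⁶` per model, summed to
a run total and normalized per 1000 records. Prices are per-million-token
numbers in an opaque currency (no conversion logic); the shipped
`examples/prices.yaml` is explicitly illustrative. Token counts reported by
a backend pass through untouched; only when a backend omits usage does the
crude `ceil(chars/4)` heuristic apply (the mock always reports usage, so no
test depends on the heuristic's accuracy). Runtime summaries aggregate
elapsed seconds per stage and per dataset with mean, SD and a per-1000-record
rate; an end timestamp before its start is an error.

## The synthetic corpus generator

`synthgen` emulates the *statistical* shape of screening corpora, not their
language: titles and abstracts are template-generated token sequences drawn
from disjoint vocabularies. Gold-included records plant keywords from the
configured PICOS lexicons; excluded records draw from decoy and filler
pools that share no word with any lexicon, so a keyword screen can separate
the classes and pipeline tests have a known answer. Defaults: 1000 unique
records, prevalence 1% (inside the sub-4% regime of real treatment
meta-analysis corpora), two databases (`pubmed` emitting NBIB, others
RIS), 10% planted cross-database duplicates, 5% blank abstracts.
`round(n × prevalence)` records are gold-included, with a floor of one
(warned). Duplicate copies live in a different database and perturb only
case, punctuation and whitespace — exactly the noise the default dedup
policy normalizes away — with half keeping the (case-mangled) DOI and half
dropping it to exercise the title+author+year rule. Duplicates are drawn
from non-blank records so the blank count stays exact after deduplication.
Everything flows from one `numpy` generator seed: the same seed yields
byte-identical files.

`simulate_role_decisions` converts a gold table into per-role verdict
tables under a sensitivity/specificity error model (independent across
records and roles, seeded per role), and `ScriptedBackend` feeds those
verdicts through the real pipeline, so end-to-end tests measure what the
orchestration actually emits.

What passing these tests shows — and does not. The generator validates the
plumbing (parsing, dedup, batching, adjudication, accounting) and the
statistics (metric panel, imbalance behaviour, error-model recovery)
against constructions with known ground truth. It says nothing about how
well any real language model reads clinical abstracts: the mock's keyword
rule is a caricature of relevance judgment, real corpora contain near-miss
titles and malformed exports beyond the perturbations planted here, and
real verdict errors are correlated with record difficulty, not independent
coin flips.

## Problem sizes and numerical choices

The test suite and the acceptance script choose sizes that make their
claims sharp rather than large: the mock-pipeline study uses the generator
defaults (1000 records → 1100 parsed entries with duplicates); the
operating-parameter recovery study uses 10,000 records at prevalence 0.5 so
that sensitivity and specificity are each estimated from ~5,000 records
(binomial SE ≈ 0.004, several standard errors inside the ±0.02 assertion
band); the imbalance demonstration uses five corpora of 3,000 records at
prevalence 0.4% with specificity 0.99, where κ < PABAK on every dataset.
Floating-point comparisons in tests use relative tolerance except where a
printed-precision check is the point, in which case the value is rounded
exactly as displayed (2 d.p., or 1 d.p. for prevalence percentages).

## Known limitations

* No EndNote XML, BibTeX or vendor CSV dialects; no live database fetching.
* Dedup merges nothing beyond representative selection; abstract-level
  near-duplicate detection is out of scope.
* The HTTP adapter targets the generic chat-completion shape only.
* The κ-vs-PABAK test treats datasets as exchangeable paired observations;
  with fewer than three datasets it refuses to run.
* Simulated decision errors are independent Bernoulli draws; real model
  errors cluster on hard records, so recovered operating parameters from
  simulation are a best case.
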
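# triscreen

Three-role LLM adjudication for systematic-review title/abstract screening.

Systematic reviews begin by screening every record a database search
returns — often thousands — against the review's PICOS criteria
(Population, Intervention, Comparison, Outcome, Study design), keeping the
handful that belong. `triscreen` implements that first pass as an automated
pipeline for methodologists and evidence-synthesis teams: it parses RIS and
NBIB (MEDLINE) citation exports, collapses cross-database duplicates, runs
each record through a **reviewer → critic → arbitrator** chain of language
model roles, and scores the final verdicts with the statistics screening
studies report.

The adjudication model: a *reviewer* makes the initial include/exclude call
on every record, a *critic* re-evaluates each record knowing the reviewer's
verdict, and an *arbitrator* re-analyzes only the records where the two
disagree. The final verdict is the shared verdict on agreement and the
arbitrator's determination on conflict. Backends are pluggable — a generic
OpenAI-compatible HTTP adapter for real models, and a deterministic
keyword-matching mock so the entire pipeline runs offline and reproducibly.

Because inclusion prevalence in screening corpora is tiny (well under 5%),
the evaluation panel goes beyond accuracy: class-conditional
precision/recall/F1 for both orientations, F-β (β = 2, recall-weighted),
balanced accuracy, the Matthews correlation coefficient, Cohen's
κ = (p_o − p_e)/(1 − p_e), and PABAK = 2·p_o − 1 — the prevalence-adjusted
bias-adjusted κ that stays informative when class imbalance drives κ toward
zero. Cross-dataset summaries are record-count weighted, and a paired
t/Wilcoxon test quantifies the κ-vs-PABAK gap. A cost module converts the
run's token ledger into money via a per-model price table.

See `docs/methods.md` for the full model, conventions and limitations.

## Worked example

Generate a synthetic two-database corpus (1000 unique records at 1%
inclusion prevalence, 10% planted cross-database duplicates, 5% blank
abstracts), then run the whole pipeline with the offline mock backend:

```bash
triscreen synth -o corpus --seed 11
# wrote 2 citation file(s) + gold.csv (1100 records, 12 gold-included) -> corpus

triscreen parse --format nbib --source-db pubmed   corpus/pubmed.nbib   -o pubmed.csv
triscreen parse --format ris  --source-db cochrane corpus/cochrane.ris -o cochrane.csv
# parsed 556 records from 1 file(s) -> pubmed.csv
# parsed 544 records from 1 file(s) -> cochrane.csv

python -c "
from triscreen import records
m = records.merge_corpora(records.read_records_table('pubmed.csv'),
                          records.read_records_table('cochrane.csv'))
records.write_records_table(m, 'all.csv')"

triscreen dedup all.csv -o unique.csv --report groups.json
# deduplicated 1100 -> 1000 records

triscreen screen --config examples/config.yaml --records unique.csv \
                 --backend mock -o verdicts.csv --log run.jsonl
# screened 950 records: 10 include, 940 exclude, 0 conflict(s)

triscreen evaluate --verdicts verdicts.csv --gold corpus/gold.csv --beta 2 -o report.json
triscreen cost --log run.jsonl --prices examples/prices.yaml -o cost.json
# total cost 0.0296 USD
```

Reading the numbers: the two exports overlap in 100 planted duplicates, so
1100 parsed entries deduplicate to exactly 1000; 50 blank-abstract records
are filtered before screening, leaving 950. The mock backend votes from
PICOS keyword matches, and on this corpus it recovers every gold-included
record with no false positives, so `report.json` shows accuracy, recall,
precision, κ and PABAK all at 1.00 with zero reviewer/critic conflicts (a
real model backend would not be this clean — the mock is a determinism and
plumbing oracle, not a relevance model). The cost estimate prices the
logged ~222k tokens at the illustrative rates in `examples/prices.yaml`,
about $0.03 per 1000 records.

The same machinery is available as a library (`triscreen.screen_corpus`,
`triscreen.class_metrics`, …) — see the test suite for idiomatic usage.

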
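# tglisten

A social-media-listening analysis pipeline for hypertriglyceridemia
consultation corpora: Boolean keyword retrieval, rule-based contamination
filtering, patient-attribute extraction, severity/demand classification, and
descriptive aggregation — together with a synthetic consultation-corpus
generator that emits full ground-truth labels so every pipeline stage can be
verified end to end without any external data.

## Layout

| Module | Role |
| --- | --- |
| `tglisten.corpus_model` | Domain types (posts, responses, lexicons), JSONL corpus I/O, text normalization |
| `tglisten.synthgen` | Synthetic corpus + ground-truth generator, recovery reporting |
| `tglisten.retrieval` | Single/pairwise keyword-category search clauses over query text |
| `tglisten.filtering` | Duplicate/advertisement/popular-science/non-topic exclusion rules, stand-in n-gram classifier |
| `tglisten.extraction` | Gender/proxy, age, TG values (mmol/L, mg/dL converted), pregnancy, symptoms, interventions, response suggestions |
| `tglisten.classification` | TG severity bands (1.7 / 2.3 / 5.6 mmol/L, configurable), TG-only vs TG+cholesterol typing, ten-label demand taxonomy |
| `tglisten.report` | Frequency tables, time series, response statistics, published-count consistency checks |
| `tglisten.pipeline` / `tglisten.cli` | Orchestration and the `tglisten` command-line interface |

Two lexicons (English and Chinese) plus the default search strategy, filter
marker lists, and the published summary counts used by the consistency
checks are bundled under `src/tglisten/data/`.

## CLI

```bash
# generate a synthetic corpus with its ground-truth sidecar
tglisten generate --n-posts 5000 --seed 1 --out corpus.jsonl --truth truth.jsonl

# run retrieval -> filtering -> extraction -> classification -> report tables
tglisten run --corpus corpus.jsonl --out report/

# aggregate an existing records sidecar
tglisten report --records report/records.jsonl --out tables/

# recompute published-count arithmetic and report pass/fail
tglisten verify
```

`tglisten run` writes `records.jsonl`, `responses.jsonl`, `decisions.csv`,
one CSV per report table, and `summary.json` into the output directory.

## Notes

- Corpus interchange format: JSONL, one post per line with keys
  `post_id`, `platform`, `platform_type` (`qa_search` |
  `online_consultation`), `year` (2004–2020), `query_text`, `responses`.
- All matching is substring containment on normalized text (no tokenizer),
  applied uniformly to both lexicon languages; synthetic templates are
  English-only while the Chinese lexicon/markers are bundled for matching.
- Response word counts use whitespace tokens for English and characters for
  Chinese.
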
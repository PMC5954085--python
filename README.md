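# fctmap

Automated mapping of free-text food-diary items onto food composition
tables (FCTs).

Linking each diary record to its FCT entry is traditionally a manual,
expert-driven step in nutritional studies. `fctmap` automates it with two
complementary approaches:

- **Fuzzy name matching** — names are upper-cased, stripped of
  punctuation, token-sorted, and compared with a partial-ratio similarity
  built on recursive longest-common-substring decomposition (an integer
  score in 0–100).
- **A boosted entropy-tree classifier** — trees split on gain ratio over
  two features, the fuzzy score and the percent energy difference between
  query and candidate (per 100 g, denominated by the query), and emit the
  probability that a match is plausible. Missing energies are routed
  fractionally, so the model tolerates incomplete records.

Threshold choice is driven by a precision–recall framework over annotated
match pairs, stratified into "directly mappable" items (those whose food
identifier code exists in the FCT) and the difficult "other" items. A
synthetic-data module generates multi-country FCTs, perturbed diary
queries (typos, token shuffles, qualifier noise, pseudo-translation,
energy noise) and ground-truth labels, so the whole pipeline is testable
offline.

## Library quick start

```python
from fctmap import partial_token_sort_ratio, map_items
from fctmap.synthetic import GeneratorConfig, generate_fct, generate_queries

partial_token_sort_ratio("hake raw", "hare raw")   # 88

cfg = GeneratorConfig(seed=1, n_fct_items=300, n_queries=100)
fct = generate_fct(cfg)
queries, truth = generate_queries(fct, cfg)
for result in map_items(queries, fct, metric="fuzzy", threshold=63,
                        name_variant="english"):
    print(result.query_id, result.decision, result.best.candidate_id)
```

## CLI

All tables are delimited text (TSV default; comma/semicolon selectable),
models are JSON, generator configs are YAML. Exit codes: 0 success, 1
validation error, 2 usage error.

```sh
# similarity of two names
fctmap score "hake raw" "hare raw"                  # -> 88

# synthetic fixture: writes fct.tsv, queries.tsv, truth.tsv
fctmap simulate --seed 1 --n-fct-items 300 --n-queries 100 --out-dir sim/

# map queries onto an FCT with the fuzzy score
fctmap map --queries sim/queries.tsv --fct sim/fct.tsv \
    --name-variant english --metric fuzzy --threshold 63 --out mapped.tsv

# train the boosted-tree classifier on annotated pairs, then use it
fctmap train --annotated annotated.tsv --trials 10 --out model.json
fctmap predict --model model.json --fuzzy 88 --ediff 25
fctmap map --queries sim/queries.tsv --fct sim/fct.tsv \
    --metric c5 --model model.json --threshold 50 --out mapped_c5.tsv

# precision-recall analysis and threshold selection
fctmap evaluate --annotated annotated.tsv --target-precision 75 \
    --out pr.tsv --plot pr.png
```

Item tables need columns `item_id`, `name_original`, `energy_kcal_100g`
(empty energy = missing, never zero); optional `name_english`,
`portion_g`, `country`, `food_group`. Energies declared in kJ are
converted only via the explicit `--energy-unit kJ` flag.

## Layout

| module | contents |
| --- | --- |
| `fctmap.text` | normalization, Levenshtein, matching blocks, partial token sort ratio |
| `fctmap.features` | `FoodItem`, 100 g scaling, percent energy difference |
| `fctmap.classifier` | entropy/gain-ratio trees, pessimistic pruning, boosting, JSON models |
| `fctmap.pipeline` | pair scoring, best match, id cross-matching, training-pair filter, thresholded mapping |
| `fctmap.evaluation` | confusion counts, precision/recall, PR curves, threshold selection |
| `fctmap.synthetic` | seeded generator for FCTs, queries, truth tables, annotations |
| `fctmap.benchmark` | self-contained synthetic benchmarks (remap rate, recall gain, rule recovery) |
| `fctmap.io` / `fctmap.cli` | table/model/config I/O and the `fctmap` command |
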
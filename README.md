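# fcdblink

Cross-country food-composition-database (FCDB) harmonization for
dish-level ingredient metadata, plus the statistical battery to compare
the nutrient content a dish gets under two different databases.

The package takes cafeteria-dish metadata in the ragged-wide "one row per
dish" CSV dialect (dish totals followed by repeated 7-field ingredient
blocks), links every distinct ingredient to a target FCDB through a
five-strategy matching cascade (exact name map, nutrient-profile
similarity, generic-group mean, recipe composition, borrowed source-DB
item), applies expert curation tables (plate-only removal, missing-name
recovery, order-of-magnitude mass corrections), resolves trace flags and
missing cells through an ordered imputation plan, aggregates per-100 g
compositions to dish totals, and then compares the two resulting per-dish
nutrient tables with:

- Pearson correlation with hypothesis test,
- quintile cross-classification (per-source cutoffs), percent perfect
  agreement and unweighted Cohen's kappa,
- Bland–Altman bias and 95% limits of agreement,
- raw-difference summaries, KS normality and paired Wilcoxon signed-rank
  tests, and top-k extreme-difference rankings,
- a robust MM regression (fast-S scale stage + 95%-efficiency bisquare
  M-step) of the per-dish differences on mass, ingredient count,
  raw/cooked discrepancies and recreated-recipe flags, with robust Wald /
  ANOVA-style joint tests.

A synthetic-data generator (`fcdblink.synthdata`) produces paired FCDBs
that share items but differ by the fiber-in-carbohydrate definitional
offset, dish files in the exact input dialect, all curation tables, and
an independently computed ground truth — so the entire pipeline is
testable offline.

## CLI

```sh
# generate a synthetic bundle (FCDBs, dish file, curation tables, truth)
fcdblink simulate --seed 42 --out bundle/

# curation -> matching -> imputation -> aggregation
fcdblink harmonize \
    --dishes bundle/dish_metadata_cafe1.csv \
    --fcdb-a bundle/fcdb_a.csv --fcdb-b bundle/fcdb_b.csv \
    --registry bundle/registry.csv --tables bundle/tables \
    --out run/

# full agreement battery between the two per-dish totals tables
fcdblink compare --totals-a run/totals_a.csv --totals-b run/totals_b.csv \
    --top-k 25 --out cmp/

# compact text rendering of a compare run
fcdblink report --agreement cmp/agreement.json
```

Every command writes a `manifest.json` (inputs, config hash, versions).
`harmonize` additionally emits `audit.json` with per-strategy match
counts and per-strategy imputation counts.

## Layout

| module                  | role |
|-------------------------|------|
| `fcdblink.n5k_io`       | ragged-wide dish metadata parsing, wide↔long reshaping, ingredient catalogue |
| `fcdblink.fcdb`         | component registry, value states, trace rule, definitional harmonization formulas, FCDB file I/O |
| `fcdblink.matching`     | five-strategy cascade, recipes, match audit |
| `fcdblink.curation`     | plate-only/mass/name curation and the five missing-value imputation strategies |
| `fcdblink.aggregation`  | per-mass scaling, dish totals, corpus summaries |
| `fcdblink.concordance`  | the paired-comparison battery |
| `fcdblink.robust`       | MM estimator, robust Wald/ANOVA tests, model frame |
| `fcdblink.synthdata`    | seeded synthetic worlds with ground truth |
| `fcdblink.pipeline`     | end-to-end harmonization runs |
| `fcdblink.cli`          | `fcdblink` command-line entry points |

Notes on conventions: differences are always reported as target-minus-
source (A − B); quintile ties go to the lower class; Bland–Altman limits
use the sample SD (ddof = 1); the KS normality check plugs in estimated
parameters without a Lilliefors correction; recipes carry no
yield/retention factors.
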
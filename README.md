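# slforest

Infer candidate synthetic-lethal (SL) gene pairs from CRISPR knockout
dependency screens. For every target gene, the per-cell-line dependency
score is modeled from binary pathogenic-mutation status and expression
(log2(TPM+1)) predictors with an all-relevant random-forest feature
selection loop (shadow features, shadowMax hit counting, binomial
confirm/reject decisions with Bonferroni control). Confirmed predictors
become directed candidate pairs (deficient gene → dependent gene), which
are then:

1. self-pair filtered,
2. sign-filtered on their Pearson correlation with the dependency
   (positive for mutation pairs, negative for expression pairs; can be
   bypassed),
3. min–max scaled within each (importance method, feature cohort) group,
4. thresholded by head/tail-breaks clustering of the scaled-importance
   distribution (last break = high-confidence cutoff, with configurable
   absolute fallbacks),
5. filtered for pan-essential targets (coefficient of variation of the
   dependency distribution < 0.3), and
6. exported as a directed network (edges/nodes CSV + GraphML).

Three importance metrics are supported: impurity (`gini`), bias-corrected
impurity (`gini_corrected`, permuted-copy debiasing) and out-of-bag
permutation (`permutation_raw`).

A first-class synthetic-data module generates download-free cohorts with
planted mutation/expression effects, collinear feature blocks, pure-noise
features and constructed essential genes, plus precision/recall scoring of
planted-pair recovery.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py`, which implements the
acceptance criteria (exact binomial-decision oracle, head/tail-breaks
brute-force oracle, 200-seed null control, 10-seed planted-pair recovery,
determinism/round-trip checks, direction/scaling invariants). The full run
takes roughly 15–20 minutes on one CPU; the non-acceptance tests alone run
in about a minute.

## CLI

```sh
# generate a synthetic cohort
slforest simulate --config sim.yaml --out data/

# end-to-end pair inference (writes pairs.csv, nodes.csv, thresholds.json,
# effective_config.yaml into output_dir)
slforest run --config run.yaml

# build / filter / export the directed network
slforest network --pairs out/pairs.csv --nodes out/nodes.csv \
    --min-expression 0.4 --min-mutation 0.5 --out-prefix out/net

# cross-method agreement and interaction-table summaries
slforest concordance --pairs out/pairs.csv --method-a gini --method-b permutation_raw
slforest enrich --pairs out/pairs.csv --scores string_scores.tsv
```

A minimal `run.yaml`:

```yaml
dependency_path: data/dependency.csv
expression_path: data/expression.csv
mutation_calls_path: data/mutation_calls.csv
dialect: {gene_col: gene_id, damaging_col: damaging_flag, hotspot_col: hotspot_flag}
methods: [permutation_raw]
forest: {n_trees: 500}
boruta: {max_iter: 500, alpha: 0.01}
master_seed: 1
output_dir: out
```

Matrix CSVs are cell-line × gene with the sample id in the first column;
gene headers may carry a `"SYMBOL (ENTREZID)"` suffix, which is stripped.
Mutation calls are long-format CSV with per-call coding score, damaging
flag and hotspot flag; a call is pathogenic when its coding score exceeds
0.7 or either flag is set.

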
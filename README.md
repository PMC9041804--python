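# sdbe — smallest-relevant-gene-set selection for binary phenotypes

`sdbe` selects the smallest stable set of genes that classifies a binary
phenotype (e.g. tumor vs. normal tissue in bulk or single-cell
transcriptomes) at near-best performance. It targets the common situation
in cancer transcriptomics where thousands of genes are differentially
expressed, many of them mutually redundant, and a diagnostic panel needs a
handful of genes — not a signature of hundreds.

The pipeline narrows a labeled expression matrix in four stages:

1. **DEG screen** — per-gene two-sided Mann–Whitney U test between
   phenotypes with Benjamini–Hochberg FDR control; keep genes with
   |log2FC| > 1 and FDR < 0.05, then min–max normalize survivors.
2. **Importance filter** — rank genes by random-forest variable importance
   and keep the top *K*.
3. **Enrichment filter** (optional) — rank genes by a signal-to-noise
   contrast, compute the weighted Kolmogorov–Smirnov enrichment score of
   gene sets from a GMT collection, and keep the *core enrichment*
   (leading-edge) genes of explicitly chosen sets.
4. **Sort Difference Backward Elimination (SDBE)** — the core algorithm.

## The SDBE algorithm

SDBE reorders a gene list G(g_k), 0 ≤ k ≤ n, so that relevant genes collect
on the left and redundant genes on the right; it never discards a gene.
Under backward elimination over the current order, cross-validated metric
values m_i of the nested prefixes {g_0..g_i} are recorded, and the
metric differences

    dm_i = m_i − m_{i−1},   0 < i ≤ n

measure what gene g_i adds on top of the genes to its left — a near-zero
or negative dm_i marks g_i as redundant given its left context. Each
iteration advances a split index ST to the first negative difference at or
after the current ST, splits the difference list into part1 (before ST) and
part2 (ST and after), sorts each part by difference in descending order,
maps differences back to their genes, and rebuilds the list with the anchor
gene g_0 — the most important gene, fixed from the initial
importance-driven elimination — at position 0. Re-tracing the new order
with the chosen classifier closes the loop. After the configured number of
iterations, the smallest prefix whose metric is within a tolerance of the
best prefix metric, and whose gene set is unchanged over the last few
iterations, is the selected panel.

The *metric object* driving the sort is either the Matthews correlation
coefficient (MCC) or the ROC AUC — both usable on strongly imbalanced
cohorts — and the trace classifier is pluggable (random forest, SVM, k-NN,
gradient-boosted trees, extremely randomized trees).

## Worked example

The built-in generator plants known signal so recovery can be scored: the
`S-redundant` preset emulates an imbalanced cohort (20 normal vs. 200
tumor samples) with 3 relevant genes, 2 correlated redundant copies of
each (ρ = 0.9), and 51 null genes.

```python
from sdbe import SDBE, ClassifierSpec, generate_preset, truth_eval

ds, truth = generate_preset("S-redundant", seed=4)
model = SDBE(ds, metric_object="mcc",
             model=ClassifierSpec("rf", {"n_estimators": 40}),
             n_iterations=3, k=5)
res = model.fit(seed=4)
print(res.summary())
```

```
Sort Difference Backward Elimination
====================================================
genes in play:        60
metric object:        mcc
classifier:           rf (k=5-fold CV)
iterations:           3
seed:                 4
anchor gene g0:       REL2
ST path:              [2, 2, 2]
----------------------------------------------------
selected genes (3, stable): REL2, RED1_0, RED0_1
mcc at selection: 0.9450
----------------------------------------------------
final ordering (left = most relevant):
    0  REL2                 mcc[prefix]=0.7515
    1  RED1_0               mcc[prefix]=0.8658
    2  RED0_1               mcc[prefix]=0.9450
    ...
```

The three selected genes cover all three planted families (one original,
two redundant copies — statistically exchangeable with their parents at
ρ = 0.9), no null gene is selected, and the 3-gene panel reaches a
cross-validated MCC of 0.945:

```python
>>> truth_eval(list(res.selection().genes), truth)
RecoveryCounts(n_relevant_recovered=3, n_redundant_selected=2,
               n_null_selected=0, n_families=3)
```

The per-prefix metric column is the polyline users plot per iteration
(`res.plot_traces()`); `res.to_dir("run/")` writes per-iteration orderings,
traces and a JSON manifest for exact re-runs.

## Command line

```bash
gsea-sdbe simulate  --preset S-redundant --seed 7 --out sim/
gsea-sdbe degscreen --matrix sim/matrix.tsv --labels sim/labels.tsv --out degs.tsv
gsea-sdbe rank      --matrix sim/matrix.tsv --labels sim/labels.tsv --top 50 --out rank.tsv
gsea-sdbe gsea      --matrix sim/matrix.tsv --labels sim/labels.tsv --gmt sets.gmt --out enrich.tsv
gsea-sdbe sdbe      --matrix sim/matrix.tsv --labels sim/labels.tsv --metric mcc \
                    --model rf --iters 6 --out run/
gsea-sdbe run       --matrix expr.tsv --labels labels.tsv --config cfg.yaml --out run/
```

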
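# grnimpute

Predicting the **genetic component of gene expression** through gene
regulatory networks (GRNs), for transcriptome-wide association studies
(TWAS) and anyone who needs to impute expression from genotypes.

Traditional transcriptome-imputation models use only variants local to a
gene: X_g = E_g α_g + ξ_g, with E_g the gene's cis-eQTL dosages. Under the
omnigenic view, much of the heritable expression signal instead arrives in
*trans*, propagated through the regulatory network. `grnimpute` implements
a network-aware predictor:

1. reconstruct a causal GRN (a DAG over genes) from paired genotype and
   expression data, using eQTL-anchored pairwise likelihood-ratio tests
   whose posteriors P(A→B) are combined into edge scores and assembled
   greedily into a maximal DAG;
2. for each gene, fit the cis model X̂ᶜⁱˢ_i = E_i α̂_i, then model the
   residual ξ̂_i = X_i − X̂ᶜⁱˢ_i with network-derived inputs — parent
   cis-eQTLs (Eᵖ), parent+grandparent cis-eQTLs (Eᵍᵖ), or parent
   expression (Xᵖ);
3. predict the genetic component as the sum X̂_i = X̂ᶜⁱˢ_i + X̂ᵗʳᵃⁿˢ_i;
   root genes are cis-only. Recursive prediction (Xᵖᵖ) reuses the
   Xᵖ models, substituting recursively predicted parent expression, so
   imputation needs genotypes alone.

A linear-Gaussian systems-genetics simulator with exported ground truth
(random DAG, one biallelic cis-variant per gene, structural-equation
expression) makes the whole pipeline testable offline.

## Worked example

```python
from grnimpute import (
    PipelineConfig, combine_posteriors, estimate_posteriors, evaluate_models,
    fit_mode_sets, greedy_dag, llr_statistics, network_summary,
    simulate_dataset, split_samples, threshold_edges,
)

# 1. simulate a systems-genetics dataset (100 genes, one cis-eQTL each)
geno, expr, catalog, truth = simulate_dataset(n_genes=100, n_samples=1000, seed=7)
split = split_samples(geno.sample_ids, fraction=0.8, seed=7)
gtr, gte = geno.restrict_samples(split.train_ids), geno.restrict_samples(split.test_ids)
etr, ete = expr.restrict_samples(split.train_ids), expr.restrict_samples(split.test_ids)

# 2. reconstruct a causal GRN from the training data
pp = estimate_posteriors(llr_statistics(etr, gtr, catalog))
scores = combine_posteriors(pp, "HALF_P2P5_PLUS_P4")
grn = threshold_edges(greedy_dag(scores), 0.5)
s = network_summary(grn)
print(f"network: {s.n_edges} edges, global FDR {s.global_fdr:.3f}")

# 3. fit all input modes and evaluate on held-out samples
config = PipelineConfig(backend="ridge", seed=7)
sets = fit_mode_sets(etr, gtr, catalog, grn, config)
report = evaluate_models(sets, gte, ete, threshold=0.05)
print(f"{report.n_predictable} predictable intermediate/leaf genes")
print(report.summary().round(3))
```

Output:

```
network: 599 edges, global FDR 0.334
74 predictable intermediate/leaf genes
E        0.071
E+Ep     0.157
E+Egp    0.144
E+Xpp    0.168
E+Xp     0.573
```

Reading the numbers: `E` is the mean held-out R² of the cis-only baseline
over predictable intermediate/leaf genes; adding parent-eQTL information
through the reconstructed network (`E+Ep`) roughly doubles it, and the
observed-parent benchmark (`E+Xp`) — an upper bound that assumes parent
expression is available — shows how much trans signal the network carries.
The global FDR is one minus the mean posterior of the retained edges.

The same pipeline is scriptable from the shell via the `grnimpute` CLI
(`simulate`, `pairtests`, `network`, `fit`, `predict`, `evaluate`,
`compare` subcommands); model sets serialize to JSON and reproduce their
predictions bit-exactly.

Statsmodels-style model objects are available too: fitting
`GrnImputation(expr, geno, catalog, grn, mode="Ep").fit()` returns a
results object with `predict()` and a per-gene `summary()` table.

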
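# Methods

## Model

`grnimpute` predicts the *genetic component* of gene expression — the part
of expression variance attributable to genotype — by propagating cis-eQTL
effects through a gene regulatory network (GRN), in the spirit of the
omnigenic view that much of a gene's heritable expression variation arrives
in trans through the regulatory network rather than from local variants
alone.

The GRN is a DAG G over genes; an edge A → B means A regulates B. For gene
*i* with cis-eQTL dosage matrix E_i, prediction is a two-stage regression,
and the two stages *define* the cis/trans decomposition:

1. **cis stage.** X_i = E_i α_i + ξ_i is fitted on training samples,
   giving X̂_i^cis = E_i α̂_i and the residual ξ̂_i = X_i − X̂_i^cis.
2. **trans stage.** ξ̂_i = P_i β_i + σ_i is fitted on the same samples,
   where P_i is one of three network-derived inputs:
   - **Ep** — top cis-eQTL dosages of the parents of *i*;
   - **Egp** — top cis-eQTL dosages of parents ∪ grandparents;
   - **Xp** — expression levels of the parents, standardized with
     training-set mean and SD.

The genetic-component prediction is the exact sum
X̂_i = X̂_i^cis + X̂_i^trans. Root genes have no trans stage; their genetic
component is the cis prediction. A fourth evaluation mode, **Xpp**, reuses
the Xp-fitted models but replaces observed parent expression with
*recursively predicted* expression at inference time: roots are predicted
cis-only, children consume their parents' predictions in topological
order. Xp is an upper benchmark (it assumes parent expression is observed,
which defeats the purpose of imputation); Xpp is the deployable recursive
predictor.

A deliberate reading: the trans stage is fitted on the cis residual, never
jointly with the cis stage, and the trans design does not re-include the
gene's own eQTLs. Genotype features are never standardized; only
expression features (mode Xp) are, using training statistics stored in the
model and re-applied at prediction time. Two-stage fitting leaves an
O(n^−1/2) gap to the joint least-squares fit, because the cis coefficient
absorbs sampling correlation between the gene's eQTL and its parents'
contributions; in the noise-free limit recovery is therefore near-perfect
(per-gene R² > 0.99) rather than exact.

## Regression backends

Four per-gene backends share one hyper-parameter policy: `ridge` and
`lasso` choose their penalty from 50 log-spaced values on [0.001, 10] by
five-fold cross-validation; `elastic_net` crosses the same grid with L1
ratios {0.01, 0.5, 1.0}; `bayesian_ridge` uses default priors with the
iteration cap at 10 000. Lasso and elastic net use scikit-learn's
path-based CV estimators. Ridge uses `GridRidgeCV`, which evaluates the
whole grid from one SVD per fold (coefficients
V diag(s/(s²+α)) Uᵀy); scikit-learn's `RidgeCV` with an explicit `cv`
falls back to a generic grid search whose per-candidate overhead dominates
when thousands of small models are fitted. `GridRidgeCV` is tested for
exact agreement with `sklearn.linear_model.Ridge` at fixed penalty. Ties
in CV error go to the smaller penalty. CV folds are seeded per gene from
the master seed (CRC32 of the gene id mixed with the seed), so refits are
bit-identical.

## Network reconstruction

For every ordered pair (A, B) of catalog genes, with E_A the strongest
cis-eQTL of A entering as a categorical regressor (K genotype classes),
five nested Gaussian likelihood-ratio tests are computed (the primary-
linkage test is fixed at posterior 1, since only genes with a significant
cis-eQTL enter the catalog):

| test | alternative | null    | dof  | probes                          |
|------|-------------|---------|------|---------------------------------|
| 0    | B ~ A       | B ~ 1   | 1    | correlation                     |
| 2    | B ~ E_A     | B ~ 1   | K−1  | secondary linkage               |
| 3    | B ~ E_A + A | B ~ A   | K−1  | B ⟂ E_A given A (independence)  |
| 4    | B ~ E_A + A | B ~ 1   | K    | relevance                       |
| 5    | B ~ E_A + A | B ~ E_A | 1    | B depends on A given E_A        |

LLR = (n/2)·log(RSS₀/RSS₁), computed vectorized per regulator row via
within-genotype-class centering, clipped to [0, 10⁶] (degenerate,
perfectly collinear pairs would otherwise be infinite). The diagonal and
pairs sharing the identical eQTL variant are excluded; regulators with a
monomorphic eQTL are skipped with a warning and their rows receive the
null posterior.

**Posteriors.** Each statistic becomes a p-value under its chi-squared
asymptotic null, and P = 1 − lfdr with the local false discovery rate
estimated as a density ratio on a logarithmic p-value histogram (the null
is uniform, so each bin's expected null mass is its width; log bins give
resolution in the far tail where signals live; bin count ≈ √n). The null
proportion π₀ is estimated from the upper-half p-value mass (2·P(p>0.5),
clipped to [0.05, 1]). The per-bin lfdr is clipped to [0, 1] and
monotonized by count-weighted isotonic regression, so posteriors never
decrease with the LLR. Test 3 reports the probability of its *null*
(conditional independence), so it is large when the statistic is small.
Curves are estimated per regulator row ("regulator-specific background");
rows with fewer than 100 scored pairs share a pooled all-rows curve.
Exact numerical agreement with any external implementation of these tests
is not a goal; the estimator is validated by calibration (≤5% of null
pairs may score above 0.5; observed ≤0.12%) and discrimination (a strong
causal pair reaches P2·P5 > 0.9) properties.

**Recipes.** Posterior matrices combine elementwise into edge scores
P(A→B): correlation `P0`, mediation `P2·P3`, instrumental-variable
`P2·P5`, and the hidden-confounder compromise `0.5·(P2·P5 + P4)`
(the default). All are asymmetric.

**DAG construction.** Edges are inserted in strictly decreasing score
order — ties broken by (source id, target id) for determinism — skipping
any edge that would close a cycle. Cycle checking maintains the transitive
closure as a boolean reachability matrix: rejections are O(1) lookups and
each insertion is one vectorized outer-product update. Memory and update
cost are O(n²), which is the right trade for the few-hundred-gene panels
this package targets; the contract (equality with a naive
DFS-after-every-edge oracle) is enforced by test. The DAG is built on all
scored edges and thresholded afterwards (strictly greater than the
threshold, keeping all nodes); `PipelineConfig.threshold_before_dag`
exposes the opposite order. Thresholds are user-supplied — the intended
use is to pick, per recipe, a threshold equalizing network characteristics
via the `threshold_grid` report. The global FDR of a network is one minus
the mean posterior of its retained edges (undefined for edgeless graphs).

**Randomization.** The null reference for network comparisons relabels
nodes by a shuffled topological order, preserving the unlabeled edge
structure exactly (acyclicity, degree multisets, node-class counts);
degree-preserving rewiring is deliberately not offered, as it can break
acyclicity. Five replicates by default.

## Synthetic data generator

The generator emulates a cross-style systems-genetics study: a random DAG
(uniform node order; edge i→j for i before j with probability
2·m/(n−1), giving mean in-degree m), one biallelic cis-variant per gene
with MAF ~ U[0.1, 0.5], haploid Bernoulli(maf) dosages by default
(Binomial(2, maf) for diploids), and linear-Gaussian structural equations

    X_i = α_i E_i + Σ_p β_{p→i} X_p + ε_i,   ε_i ~ N(0, σ_i²).

Defaults: α uniform on ±[0.5, 1.5], β uniform on ±[0.3, 1.0], σ = 1,
mean in-degree 1.5, 250 genes, 1000 samples. These put the cis-only test
R² of a typical gene near 0.05–0.1 — the regime where network information
has headroom to help — and are used unchanged throughout the tests and
the acceptance script. One master seed expands into independent
per-stage substreams (DAG, effects, genotypes, noise); the noise matrix
is drawn up front in fixed gene order, so generation is invariant to the
topological order used and identical seeds give byte-identical output.

The generator is linear-Gaussian by design (the predictor is linear, so
linear truth yields analytic recovery targets); it does **not** simulate
linkage disequilibrium between variants, epistasis, hidden confounders,
cyclic regulation, library-size/count noise, or kinetic nonlinearity.
Passing tests therefore demonstrate correctness of the machinery and the
qualitative behavior of the method in its own model class — not
performance on real transcriptomes, where all of the above are present.

## Evaluation protocol

Samples are split 80/20 uniformly at random (seeded); networks, models,
scalers and CV folds see training samples only. Per-gene test
R² = 1 − SS_res/SS_tot is computed on raw (unstandardized) expression —
R² is invariant to the affine scale choice for identical predictions — and
may be negative; it is undefined (NaN) for zero-variance targets. Reports
are restricted to intermediate and leaf nodes, and summary means are taken
over *predictable* genes: test R² ≥ 0.05 (inclusive, per "at least") with
the combined cis + observed-parent input (E+Xp). Genes with a degenerate
(monomorphic-eQTL) cis model are kept, scored against their intercept-only
prediction, rather than silently dropped.

`compare_networks` deliberately drops the node-class restriction and the
predictability filter: node classes differ between networks (and their
randomizations), so filtering would change the gene set per network and
contaminate the comparison. Averaging over all modelled genes keeps the
gene set identical, making the cis-only column exactly network-invariant
and the random-network entry (mean over five relabelings) directly
comparable.

## Numerical choices and degenerate inputs

- LLR cap 10⁶; p-values floored at 10⁻³⁰⁰.
- Greedy-DAG tie-break: (−score, source id, target id) lexicographic.
- Threshold semantics: strictly greater ("exceeding").
- Monomorphic cis variant: cis model degenerates to the training mean with
  zero coefficients (logged).
- Constant parent expression in mode Xp: scaler SD is replaced by 1, so
  the centered feature is exactly zero rather than NaN.
- Missing values are rejected at load time, never imputed; dosages must be
  integers in the configured alphabet ({0,1} haploid, {0,1,2} diploid).
- Serialization is JSON with full-precision float round-trip, so saved
  models reproduce predictions bit-exactly.

## Problem sizes

The test suite and acceptance script run the full pipeline at 250 genes ×
1000 samples (800 training) over five master seeds for recovery and
mode-ordering checks, 50 genes × 1000 samples × 20 seeds for test
calibration, and 100 genes for the noise-free recursive limit — sizes
chosen to match the default study conditions above while keeping a full
run on a single CPU in the order of a minute.

## Known limitations

- The DAG abstraction discards feedback loops; with cyclic truth the
  greedy construction keeps the strongest-supported direction per cycle.
- The lfdr estimator is intentionally simple (histogram + isotonic); with
  very few pairs per regulator it falls back to a pooled curve, and its
  posteriors are calibrated in rank more than in value — recipe products
  should be read as scores, not exact probabilities.
- CV-minimum penalty selection (no 1-SE rule) occasionally keeps a small
  nonzero lasso coefficient on pure-noise features.
- The transitive-closure DAG builder is quadratic in memory; panels beyond
  a few thousand genes would need a different incremental cycle detector.
- Recursive prediction compounds upstream errors on imperfect networks;
  this is a property of the method, visible in the E+Xpp column.
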
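# Methods

## The question

Tree-ensemble variable importance is widely used to rank predictors in
settings — genetic association, microarray and other -omics studies — where
predictors are strongly correlated (e.g. markers in linkage disequilibrium).
`corrvim` implements a controlled Monte Carlo study of how predictor
correlation shapes the permutation-based variable importance measures (VIMs)
of a regression random forest, together with the linear-model analytics that
explain the observed behaviour.

## Generating model

Twelve predictors are jointly standard normal with correlation matrix V:
the leading 4×4 block is equi-correlated at ρ = 0.9 and everything else is
independent. The response is linear with no intercept,

    y = X b + ε,   ε ~ N(0, σ_ε²) i.i.d.,

with b = (5, 5, 2, 0, −5, −5, −2, 0, 0, 0, 0, 0) under the alternative H_A
and b = 0 under the null H_0 (same V). So x1–x4 form the correlated block
(x4 with a zero coefficient — the "proxy"), x5–x7 are uncorrelated but
influential, and x8–x12 are pure noise.

### The noise-scale convention

The noise term is specified as "N(0, 0.5)", which is ambiguous between
variance 0.5 and standard deviation 0.5. The two readings are not
interchangeable at two-decimal precision: the analytic marginal correlation
of the proxy x4 is r = (V b)₄ / σ_y = 10.8/√(189 + σ_ε²), which rounds to
0.78 under the variance reading (σ_ε² = 0.5) and to 0.79 under the SD
reading (σ_ε = 0.5). The package therefore exposes `noise_sd` as an explicit
parameter everywhere. The simulator's default is `noise_sd = 0.5` (the SD
reading, the convention of the R-style generators used in this literature);
the closed-form truth table is reported under either reading by passing the
corresponding `noise_sd`. Note σ_ε only sets the absolute scale of
null-hypothesis VIMs and has no visible effect on any of the ordinal
findings or the OLS bias results (the bivariate slopes do not involve σ_ε).

## Analytic truths

With unit predictor variances the population bivariate slope of y on x_i is
(V b)_i, its marginal correlation is (V b)_i / σ_y with
σ_y² = bᵀVb + σ_ε², and the population multiple-regression coefficient
vector is b itself. These closed forms (`analytic_truth`) are the yardstick
for the Monte Carlo regressions and the explanation of the forest's
first-split preferences: at the root, a tree split is a bivariate screen, so
the proxy x4 (marginal r ≈ 0.78) out-competes the uncorrelated influential
predictors x5/x6 (r ≈ −0.36).

## Bias and coverage of OLS

For each replicate (n = 2000; 500 replicates by default) the package fits
the full 12-predictor OLS model and the twelve single-predictor models,
with and without an intercept (the generating model has none; the two
variants agree closely). Bias is the mean difference between the estimate
and the *generating* coefficient, and coverage is the percentage of t-based
95% confidence intervals containing that generating value. This definition
makes the bivariate results informative by construction: the expected
bivariate bias of a correlated predictor is (V b)_i − b_i (6.30 for x1,
10.80 for x4) and its coverage collapses to 0, while the full model is
unbiased with ≈95% coverage. Confidence intervals use the t distribution;
at n = 2000 the difference from the normal quantile is negligible but the
choice is fixed for reproducibility.

## The instrumented forest

Regression trees are CART-style: at each node `mtry` candidate predictors
are drawn uniformly without replacement and the split minimising the pooled
within-child sum of squares over midpoint thresholds is chosen. Tree
induction is delegated to scikit-learn's `DecisionTreeRegressor`
(`criterion="squared_error"`, `max_features=mtry`,
`min_samples_split=min_node_size`); the package owns the subsampling, seed
derivation and instrumentation. Study settings: minimum node size 20
(a node with fewer in-bag observations is never split; children may be
smaller), subsampling 63.2% of the observations WITHOUT replacement (so OOB
is exactly 36.8% per tree), mtry ∈ {1, 3, 8}. One caveat of the wrapped
learner: when none of the drawn candidates admits an improving split it
inspects further predictors rather than making the node a leaf; with
continuous predictors and responses this is essentially never triggered.
The test suite cross-checks the forest and its unconditional importance
against R's `randomForest` with the matching settings (`nodesize=20`,
`replace=FALSE`, `sampsize=0.632·n`, unscaled importance) on a shared
replicate, requiring agreement to Monte Carlo accuracy and an identical
ranking of the influential predictors.

Every tree records its split list (node id, depth, feature, threshold), its
in-bag/OOB partition and the set of features it used; split-selection
frequencies (`selection_freq`) are exact integer counts over these records,
separated into root-split counts and all-split counts.

## Variable importance measures

For tree t and predictor j the raw importance is
Δ_{tj} = MSE_oob(x_j permuted) − MSE_oob(original), permuting only among
that tree's OOB rows, one fresh permutation per (tree, predictor)
(an `nperm` averaging knob exists, default 1). Then

* unconditional VIM_j = mean_t Δ_{tj};
* scaled VIM_j = mean_t Δ_{tj} / (sd_t Δ_{tj} / √ntree) — a t-statistic, so
  it grows like √ntree for a genuinely important predictor and is reported
  as undefined for a single tree;
* conditional VIM_j = mean_t Δ'_{tj}, where the permutation of x_j is
  applied independently within strata of the conditioning set
  {k ≠ j : |cor(x_j, x_k)| ≥ threshold} (default threshold 0.2; with this
  design any threshold in (0, 0.9) yields identical sets). Strata are the
  cells of the partition induced by the tree's own split thresholds on the
  conditioning variables; a conditioning variable the tree never split on
  contributes no refinement, and a quantile-bin stratification is available
  as an alternative (`strata_source="quantile_bins"`). Singleton strata are
  left fixed by the permutation.

Sign convention: positive = important (permuting an informative predictor
increases OOB error). A predictor a tree never used has Δ_{tj} = 0 exactly,
which the implementation exploits and the tests assert. Permutation
randomness is seeded per (tree, predictor) from a stream independent of
forest growing, so forest structure is invariant to VIM settings and a
predictor with an empty conditioning set has *bitwise identical*
conditional and unconditional importances.

Conditional importances are computed on a random 500-observation subset of
each replicate with 500 trees at full scale (they are far more expensive
than the unconditional ones), mirrored by separate configuration knobs.

### Null-hypothesis selection frequencies

With mtry = 1 the root feature is exactly the uniform candidate draw, so
under H_0 first-split shares are uniform at 1/12 (verified by chi-square).
With mtry > 1 the null first-split distribution is *not* exactly uniform:
when two or more members of the correlated block land in the same candidate
set their split criteria are positively dependent, so the block's best
candidate wins less often than four independent predictors would — a
competition effect that depresses the correlated shares (to ≈ 0.06 at
mtry = 8 versus 1/12 ≈ 0.083) and never inflates them. The acceptance
checks therefore test exact uniformity only at mtry = 1 and the absence of
any correlated-block preference at mtry 3 and 8.

## Study orchestration and scale

`experiment.run_vim_condition` runs one (scenario, mtry) cell: simulate a
replicate, grow a forest, compute the VIMs, accumulate selection counts,
discard the forest. `run_study` covers the grid
{H_A, H_0} × mtry {1, 3, 8} and writes the bias/coverage tables, analytic
truth table, per-cell VIM summaries (median and quartiles per predictor)
and selection counts, plus a manifest with every seed; two runs with the
same master seed produce identical files.

Full scale is n = 2000, 500 replicates, 5000 trees. The package's desk
scale — the default, used by the test suite and the acceptance script — is
50 replicates and 250 trees at the same n (conditional VIMs: 500
observations, 250 trees). The per-replicate VIM mean is unbiased in ntree,
so desk scale changes Monte Carlo noise, not the quantities being
estimated; all ordinal findings (VIM rankings, the conditional reversal,
selection-frequency patterns) are stable at this scale. Desk scale never
reduces n below 200, since tree depth — and with it the null inflation
discussed next — depends on n through the node-size rule.

## Seeds

All randomness descends from one master seed via
`derive_seed(master, *path)` (a `SeedSequence` over the master seed plus a
counter path): per-replicate data seeds, per-tree subsample and growth
seeds, per-(tree, predictor) permutation seeds, and the conditional-VIM
subset seeds occupy disjoint paths, so every draw is attributable, streams
are independent, and any replicate can be re-run in isolation.

## Group-gap summary and known limitations

The null-inflation summary is the median unconditional VIM pooled over
replicates and predictors of the correlated block minus the same median for
the uncorrelated group. Under H_0 this gap measures how much the correlated
block's noise-fitting splits inflate importance (σ_ε = 0.5 ⇒ var(y) = 0.25
sets its absolute scale); the acceptance script recomputes it at every
mtry. Because the per-replicate VIM mean is unbiased in the number of
trees, the gap is a property of the design conditions (n, node size, ρ),
not of the forest size.

Other limitations: the generator covers only Gaussian predictors, a single
equi-correlated block and a linear response — none of the heavy tails,
discrete genotypes or interaction structure of real -omics data — so
passing tests demonstrate correctness of the machinery under the stated
model, not robustness on real data. The conditional-inference-forest
algorithm (p-value-based splitting) is out of scope; the conditional
permutation scheme is applied to the CART-style forest only. Classification
forests and impurity-based importances are not implemented.
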
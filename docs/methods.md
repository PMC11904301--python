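# Methods

This note documents the scoring model, its parameters and defaults,
the synthetic benchmark, and the numerical and design choices that were
genuinely open, in enough detail to reimplement the package.

## Scoring model

For each gene g and enabled feature i the pipeline computes

    x_i(g)  →  rescale  →  impute  →  curve  →  weight

in that fixed order, and the final score

    score(g) = Σ_i w_i · curve(x̃_i(g), c_i) / Σ_i |w_i| ,

a normalized weighted average. Imputation runs after rescaling so that
fill constants (0, 0.5, column min/median) live on the common [0, 1]
scale regardless of the feature's original units. Scores lie in
[−1, 1] (in [0, 1] when all weights are nonnegative), are invariant to
feature ordering and to multiplying all weights by any k > 0, and
features with weight 0 are provably inert.

**Rescaling.** `rank_percentile` maps the r-th of n non-missing values
to (r−1)/(n−1) with average ranks for ties; `minmax` maps linearly to
[0, 1]. Constant (or single-valued) columns map to 0.5: they carry no
information and should neither reward nor penalize. Percentiles
everywhere in the package — rescaling and the restricted
normal-expression filter — use linear interpolation between closest
ranks (numpy's default definition).

**Curving.** `curve(v, c) = v^exp(c)`. The exponential ensures a
positive exponent for any real c, so the transform is strictly
increasing, fixes 0 and 1, and is the identity at c = 0; c > 0 gives a
convex transform that spreads the top of the feature distribution,
c < 0 a concave one that spreads the bottom. This particular functional
form is this package's choice; any one-parameter family with those
qualitative properties would serve. Because curving is monotone, a
single-feature ranking is unchanged by any curve value — curves matter
only through the relative geometry of several features.

**Direction handling.** "Lower is better" features (normal-tissue
expression) get default weight −1 rather than being pre-inverted. Both
the weight sign and the curve sign remain free parameters for the
optimizer, which can therefore also discover direction.

**Ties.** Equal scores are ranked by ascending gene symbol. This is
documented because MAP depends on the ranking of tied genes;
determinism makes reports and objective values exactly reproducible.

## Default feature catalog

Twelve features spanning five categories (the user-dataset tumor
summaries plus the four enrichment categories). The catalog is a
representative, schema-compatible set, not a replication of any
specific production catalog; users add features by extending the
catalog and supplying matching snapshot columns.

| feature | category | direction | rescale | impute |
|---|---|---|---|---|
| expr_mean, expr_median, expr_max, expr_q75 | tumor_expression | higher | rank_percentile | min |
| expr_frac_expressed | tumor_expression | higher | minmax | min |
| normal_expr_max | normal_expression | lower | rank_percentile | neutral |
| normal_expr_pctile | normal_expression | lower | minmax | neutral |
| surface_evidence | localization | higher | minmax | zero |
| dependency_mean | annotation | higher | rank_percentile | neutral |
| has_drug, has_adc | therapeutic | higher | minmax | zero |
| pmtl_flag | therapeutic | higher | minmax | zero |

Impute defaults encode the meaning of absence: an unassayed surface
protein contributes nothing (zero), an unknown normal-tissue profile is
neutral (0.5), a gene missing from the tumor data entirely is treated
as minimally expressed (min). Multi-column sources are collapsed by
documented derivations: `normal_expr_max` is the per-gene maximum
across tissue columns (the most conservative single number for
off-tumor toxicity), `normal_expr_pctile` its percentile among all
snapshot genes, `dependency_mean` the mean across phenotype-matched
cell-line columns (matched by the `<phenotype>.` column-name prefix,
falling back to all lines).

## Labels and evaluation

Known positives for a phenotype are genes with at least one approved or
clinical-stage therapy record matching the phenotype (case-folded exact
match; ontology mapping is out of scope). Known negatives are genes
whose phenotype-matched records are all discontinued; a gene with both
active and discontinued records counts positive. The two sets are
disjoint by construction.

Average precision is the mean over positives of precision at each
positive's rank. Two modes are provided because the right treatment of
negatives is a genuine modeling choice: `full` evaluates over the whole
ranking (unlabeled genes count as non-relevant) and is the default when
no negatives exist; `labeled_only` first restricts the ranking to
positives ∪ negatives, so a positive is penalized only by labeled genes
above it, and is the default when negatives exist. Every result records
its mode. The project-level objective is the unweighted mean of
per-project MAP.

## Optimization

**Stage 1 — SFS + Brent.** The baseline objective is the MAP of the
full enabled catalog with default parameters. Greedy forward selection
then evaluates every unselected feature together with the current
selection (newcomers at default weight/curve), keeps the best candidate
only if it improves the current objective by at least the relative
threshold (default 10⁻⁴, i.e. 0.01%), and after inclusion refines the
newcomer's weight and then its curve by bounded Brent search, one
coordinate at a time (weight first — an arbitrary but fixed order).
Candidate ties break by catalog order, so the stage is fully
deterministic. Starting the comparison from the full-catalog baseline
(rather than from zero) makes the threshold meaningful at the first
step: with a relative threshold of 100% nothing is ever selected and
the default-parameter result is returned, whereas any threshold applied
to a zero baseline would be vacuous.

**Stage 2 — GA + Nelder-Mead.** A real-coded genetic algorithm over
the concatenated (weights, curves) vector of the selected features,
seeded with the SFS result: tournament selection (size 3), uniform
crossover (rate 0.9), per-gene Gaussian mutation (probability 0.15,
s.d. 10% of the bound width) clipped to bounds, elitism of one. Half
the initial population is a Gaussian cloud around the SFS vector, half
is uniform in the bounds. Every 10 generations the best individual is
refined by Nelder-Mead (simplex ascent, bounds-clipped) and replaces
itself only if the relative improvement is at least 10⁻³ (0.1%). These
budget-scale hyper-parameters (population 40, 60 generations) are
package defaults chosen for desk-scale problems and are all
configurable. Elitism makes the best-so-far trace non-decreasing; a
single `numpy` Generator seeded from the project seed makes runs
bit-reproducible.

Bounds default to weights ∈ [−10, 10] and curves ∈ [−3, 3] (curve
exponents between e⁻³ ≈ 0.05 and e³ ≈ 20). An all-zero weight vector is
scored −1 (strictly worse than any attainable MAP) rather than raised
as an error inside the optimizer, so stochastic search cannot crash on
a degenerate proposal.

**Performance.** Rescaling and imputation are weight-independent, so
each project's transformed matrix is computed once; an objective
evaluation is then one matrix power, one mat-vec, one sort, and an AP —
about a millisecond at 1000 genes × 12 features. Evaluations are
memoized by exact parameter bytes; caching changes speed only, never
results.

## Synthetic benchmark

The generator emulates the inputs of a real prioritization study at
desk scale. Per-gene log2 baselines are Normal(5, 2); tumor samples add
Normal(0, noise_sd) noise (lognormal intensities on the linear scale,
matching proteomics-like inputs). Planted genes — disjoint sets per
phenotype — receive the ideal-target profile: a tumor shift of
`tumor_effect_sd` × noise_sd (default 2 s.d.), normal-tissue values
divided by `normal_suppression` (default 4×), surface evidence 5/5 with
probability 0.9, a dependency increment of 0.5 over the |Normal(0,
0.3)| background in phenotype-matched cell lines, and active drug
records with full coverage; 30% as many background genes get
discontinued-only records and become known negatives. About 5% of
background genes are absent from the surface snapshot to exercise the
missing-data path. Ground truth lives only in the manifest so
enrichment cannot leak it; equal configurations produce byte-identical
directories.

What the generator does **not** emulate: realistic marginal
distributions of any public database, correlated tissue profiles,
batch effects, sample sparsity, or gene-gene correlation. Passing the
recovery benchmark therefore shows that the pipeline's mechanics —
enrichment, transformation, ranking, optimization — recover a planted
multi-feature signal; it says nothing about performance on real tumor
data.

## Guard against label leakage

On an effect-free fixture (tumor shift 0, suppression 1×, surface and
dependency boosts off) with the therapeutic features disabled, the
optimized MAP is compared two-sided (α = 0.01) against 1000
random-ranking AP draws. The therapeutic features must be excluded from
this check because labels are derived from the drug table: `has_drug`
equals the labeling by construction, so leaving it enabled would test
nothing. The check tolerates the optimizer's inherent selection
optimism (maximizing over many parameter vectors inflates MAP above the
null mean even on pure noise) because the random-ranking null is
fat-tailed at 10 positives among 400 genes; a systematic leak of truth
through the biological features would clear the tail and fail.

## Known limitations

- Gene symbols are the only join key; no alias or ortholog resolution.
- Phenotype matching is exact string comparison after case-folding.
- The negative-aware MAP is one of two documented conventions, not a
  canonical formula; results record which mode produced them.
- SFS is greedy: features that help only jointly (complementary pairs)
  can leave it below the exhaustive-subset optimum; the GA stage
  mitigates but does not eliminate this.
- The multi-cancer objective weights phenotypes equally regardless of
  their number of labeled targets.
- No per-sample normalization is applied; inputs are assumed already
  normalized.
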
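# Methods

## Study design and what the generator emulates

The pipeline targets the following design: one reference cell line, 19
arrays — 3 vehicle controls and 11 drug-treated samples spread over three
independently manufactured product batches (4 + 4 + 3), plus 5 comparator
agents with one array each, hybridized in their own run. The signature
contrast uses the 14 vehicle+treated arrays; the consistency map compares
the 16 treated+comparator arrays.

`phytosig.simulate.generate_expression` draws, per probe *i* and sample *j*,

    a_ij = mu_i + beta_i * treat_j + kappa_{agent(j),i} + gamma_{batch(j),i}
           + delta_{batch(j),i} * eps_ij

with baseline mu_i ~ N(8, 2²) log2 units, residual eps_ij ~ N(0, noise_sd²),
additive per-batch-per-probe shifts gamma ~ N(0, batch_shift_sd²), and
multiplicative per-batch scales delta drawn log-normal with E[delta] = 1 and
log-sd `batch_scale_shape` (a unit-mean family chosen so batch-adjustment
tests know the true scale factors; no specific prior family is implied).
Each comparator agent carries its own planted signature kappa so that
comparators are mutually and jointly distinct.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| `n_probes` | 5,000 | desk-scale stand-in for a 54,675-probe array; all rates scale per probe |
| `frac_de` | 0.10 | ~2% of probes reached significance in typical single-agent treatments at full scale; 10% of 5k probes keeps absolute DE counts (~500 probes / ~170 genes) in the realistic few-hundreds range |
| `effect_log2` | 1.0 | a 2-fold treatment effect, the conventional "clear" effect size |
| `noise_sd` | 0.5 log2 | typical residual spread of replicate arrays after normalization |
| `batch_shift_sd` | 1.0 log2 | batch effects comparable to or larger than the biology — the regime batch adjustment exists for |
| `batch_scale_shape` | 0.25 | mild (±25%) scale heterogeneity between runs |
| `probes_per_gene` | 3 | HG-U133-Plus-2-like redundancy (54,675 probe sets over ~20k genes) |
| `frac_unmapped` / `frac_multi` | 0.04 / 0.02 | small tails exercising the no-symbol / multi-symbol exclusion rules |

Differential expression is planted gene-coherently: whole genes (all of
their uniquely mapped probes) are flipped up or down until exactly
`round(frac_de * n_probes)` probes carry an effect, so gene-level recovery
is well defined. The truth sidecar records DE probe and gene sets, all batch
parameters, comparator signatures, planted cliques, and the label of the
constructed connected reference instance; recovery tests consume only this
record.

What the generator does **not** emulate: probe-level intensity physics (GC
bias, cross-hybridization), correlated gene modules (probes are independent
given their gene), heavy-tailed noise, and dye/scanner drift. Passing
recovery tests therefore demonstrate that the *analysis chain* is correct
and calibrated under its own model, not that real arrays will reach the same
sensitivity.

## Relative expression and batch adjustment

`relative_expression` rescales each probe row to [0, 1] by its own min and
max. Rows with zero range are moved to a `dropped_probes` list rather than
producing NaNs. The transform is idempotent and invariant to per-row affine
rescaling with positive slope.

`batch_adjust` implements the parametric empirical-Bayes location/scale
model: per-probe standardization against a design of batch indicators plus
(optionally, default on) the biological group indicator; per-batch-per-probe
location gamma and scale delta² estimates; Normal prior on gamma and
Inverse-Gamma prior on delta², both fit by method of moments across probes;
the coupled posterior-mean equations iterated to relative tolerance 1e-4
(cap 100 iterations); adjusted values back-transformed. Only the parametric
variant is provided — it is the canonical small-sample choice and the only
one this design (2–5 arrays per batch) can support. Constant probes are
passed through unchanged. A single-batch matrix is returned unchanged with a
warning; a batch of one sample is rejected (its scale is not estimable).
The implementation agrees with the Bioconductor reference implementation to
~1e-8 on shared fixtures (cross-checked in the test suite), which is also
why the group covariate is exposed as a flag: whether to protect the
treatment contrast during adjustment is a design choice, defaulted to on
because the signature stage follows.

Comparator samples live in a batch that contains only comparators, so batch
and group are confounded there and the design matrix would be singular;
`adjust_treatment_arm` therefore adjusts the vehicle+treated arm in place
and leaves comparator columns untouched. Their shared run effect is real
technical signal, and it is what makes the comparators cluster together —
as a group distinct from the treated block — in the consistency map.

## Degrees of freedom after adjustment

Testing a batch-adjusted matrix with the naive two-sample df (n₁+n₂−2) is
anticonservative: removing one fitted mean per batch per probe deflates the
pooled variance (~2.8% empirical rejection at a nominal 1%). Both tests
accept a `df_loss` argument, and the signature stage discounts
(n_batches − 1) degrees of freedom automatically when the input carries
multiple batch labels (empirical null rate ~1.4% after the discount; the
remainder stems from the partially shrunk location estimates and per-batch
scale rescaling, which no single-df correction can remove). On unadjusted
single-batch data the tests are exactly calibrated.

## Moderated t

Hyperparameters (d₀, s₀²) are estimated by matching the mean and variance of
log sample variances to their theoretical digamma/trigamma expressions, with
Newton inversion of the trigamma function; when the observed spread of log
variances does not exceed the chi-square expectation, d₀ = ∞ and the
limiting equal-variance statistic (normal reference) is used. The moderated
statistic is referred to t on d₀ + d_g df. The implementation reproduces the
Bioconductor reference estimator to ~1e-10 on shared fixtures (cross-checked
in the test suite).

## Signature stage composition

The printed pipeline applies a significance test, a symbol-exclusion rule,
a 1.3-fold criterion, and a clique analysis, but not the exact order in
which significance and fold change combine. The stage here selects probes at
P < 0.01 (moderated t by default; the ordinary pooled t is a switch),
collapses them to uniquely mapped genes (no-symbol and multi-symbol probes
excluded and counted; selected probes of one gene disagreeing in sign drop
the gene), and then applies the fold criterion to the **gene-level mean
log2 fold change over all of the gene's probes**. The order is a power
consideration made at design time: with 11 vs 3 samples and sd 0.5, a
per-probe fold filter is vacuous for significant probes (any probe passing
P < 0.01 already exceeds 1.3-fold), whereas the across-probe mean fold
change (sd ≈ 0.19 under the null) separates noise-selected genes from real
effects — per-probe power ~0.69 compounds to ~0.97 gene sensitivity with
3 probes/gene, while the gene fold filter holds the false discovery rate
near 0.1. Sensitivity and FDR are expectations, so the recovery check
evaluates their means over five replicate simulations.

The enriched signature is the union of fold-change genes and clique-member
genes with per-gene provenance tags; direction conflicts between the two
sources resolve by the sign of the gene-level fold change.

## Seriation and leaf ordering

R2E seriation iterates R ← corr(R) (rows as observations) until
|λ₃|/|λ₁| < 1e-9 (cap 100 iterations, warn and proceed on non-convergence),
takes the two leading eigenvectors (each sign-fixed so its largest-magnitude
entry is positive), orders objects by θ_i = atan2(v₂ᵢ, v₁ᵢ), and cuts the
circular order at the largest angular gap. Equal angles tie-break by
original index; a fully degenerate map (all off-diagonal correlations equal,
or a constant row) returns the stable input order with a warning. Objects
with identical correlation patterns are exchangeable, so their relative
order is necessarily index-based.

HCT_R2E builds the average-linkage tree on distance 1 − r and then chooses,
for every internal node, which child block comes first so as to minimize the
total L1 displacement between leaf positions and R2E ranks. Under a fixed
subtree membership the optimal flip of each binary node given its leaf
offset is independent of choices elsewhere, so a top-down dynamic programme
(memoized on node × offset) attains the exact optimum. Flipping permutes
leaves only; merge heights are untouched.

Correlation PCA eigendecomposes the sample correlation matrix; coordinates
are eigenvector × √eigenvalue with the same sign convention.

## Clique enumeration

"k-clique" means every complete subgraph of exactly k nodes, not only the
maximal ones — the member-gene union over all 3- and 4-cliques is the
quantity of interest, and maximal-only enumeration would undercount it.
Vertices are ordered by degeneracy (repeated minimum-degree removal, ties by
name) and each candidate clique is extended only into higher-ordered common
neighbors, so each clique is emitted exactly once and the search stays
near-linear on sparse PPI-like graphs (2,000 nodes at mean degree 6
enumerate in well under a minute). Every emitted set is independently
verifiable by an all-pairs adjacency check, and the suite cross-checks
against exhaustive subset enumeration on small random graphs.

## Enrichment

Over-representation is the exact upper-tail hypergeometric probability
P(X ≥ k); q-values are Benjamini–Hochberg; a set is retained when p < 0.05,
q < 0.05 and the overlap has ≥ 4 genes. The background universe is the set
of measured, uniquely mapped genes (configurable) — a database-internal
background is not available offline and the measured-gene background is the
defensible default. Only enrichment (not depletion) is scored. Because the
statistic is discrete, null p-values are super-uniform with a deficit that
shrinks as overlap variance grows; the calibration test uses large sets
(500–1,500 of 5,000) where the deficit is well inside sampling noise.

## Connectivity scoring

For ordered tags at ascending ranks V(1..t) in a universe of n,
a = max_j [j/t − V(j)/n], b = max_j [V(j)/n − (j−1)/t], ks = a if a > b else
−b. A query scores raw = ks_up − ks_down when the two disagree in sign and 0
otherwise; raw scores are scaled sign-specifically to [−1, 1]. Reversing a
profile swaps the maxima exactly (a′ = b − 1/n, b′ = a + 1/n), so the
statistic is antisymmetric up to one rank unit except where the a-vs-b
decision is itself within 2/n of a tie.

Permutation p-values use random tag sets of the same sizes:
p = (1 + #{null ≥ observed})/(n_perm + 1). Because the sign-disagreement
rule puts an atom of probability ≈ ½ at raw = 0, the permutation null is not
continuous and p-values under random queries cannot be uniform (the atom
maps to a point mass near p ≈ 0.75); they are, as for any valid permutation
test with ties, super-uniform — P(p ≤ t) ≤ t — which is what the suite
asserts.

The robustness analysis draws, for each query size (default 100–500, 1,000
replicates each), a random probe set split evenly into up/down tags, scores
every instance, and records each agent's occupancy of the top k (default 5)
by scaled score. The published description of the "drug ratio" is not
operational; top-k occupancy fraction is the interpretation implemented, and
k is exposed. Ties — above all the zero-score atom — are broken by a fresh
seeded permutation per query so that no agent is favored by its label; under
exchangeable (uniformly random) profiles every agent's ratio is top_k/n_agents.

## Synergy

q = D12/(D1 + D2 − D1·D2) on *fractions affected* (dead-cell proportion),
undefined when both single-agent effects are 0. The fraction-affected
reading is forced by arithmetic: only it reproduces the published example
indices (1.48, 1.64 at two decimals) from the published arm percentages —
the source text calls the same 30.63% both "viability" and "cell death",
and the viability reading is inconsistent with its own reported q.
Classification is synergistic above 1.15, antagonistic below 0.85, additive
on the closed interval between. Reporting rounds half-even to two decimals;
full precision is retained.

## Determinism and problem sizes

One master seed drives every stochastic stage through fixed offsets
(simulate +0, PPI +101, gene sets +211, profiles +307, robustness +401,
permutation +503); reruns are bit-identical for all non-image outputs, and
raster maps are one-pixel-per-cell images written without axes or metadata
so identical inputs yield identical bytes on one platform. The test suite
and the analysis scripts run at the generator's defaults (5,000 probes, the
19-array design, 20 reference instances); the robustness analysis in the
drivers uses the full 5 × 1,000 random queries, while unit tests use
smaller replicate counts chosen so that binomial/KS tolerances stated in
each test are meaningful.

## Known limitations

- The empirical-Bayes adjustment assumes Normal/Inverse-Gamma priors; with
  2-sample batches the scale posterior is prior-dominated.
- The residual mild anticonservatism of testing adjusted data (~1.4% at
  nominal 1%) is documented rather than hidden; analyses that need exact
  error control should test unadjusted data with batch covariates.
- Gene collapsing discards multi-mapped probes entirely; no attempt is made
  to apportion their signal.
- Connectivity scoring assumes all reference profiles share one probe
  universe; cross-platform collapsing is out of scope.
- The synthetic comparator agents are mutually independent; real comparator
  panels may share pathway responses with the drug, which would loosen the
  consistency-map separation.
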
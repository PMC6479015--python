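# Methods

This note documents the statistical procedures `dyadcomm` implements, the
choices made where the procedures admit more than one reading, and what the
synthetic-data generator does and does not emulate.

## Data model and preprocessing

The raw input is a samples × genera matrix of non-negative integer read
counts plus per-sample metadata (cohort, dyad id, niche ∈ {milk, feces}).
Genus names are opaque strings; composite labels such as
"Escherichia/Shigella" or "Clostridium sensu stricto 1" are single tokens.
A dyad may contribute at most one milk and one feces sample; samples
without a dyad id are allowed and simply skipped by dyad operations.

Preprocessing runs in a fixed order: (1) samples with fewer than
`min_reads` (default 1,000) total reads are dropped, with an inclusive
boundary; (2) counts become per-sample proportions; (3) proportions are
rounded half-to-even to `rounding_digits` decimals (default 10) and genera
whose rounded abundance is zero in every sample are pruned; (4) remaining
zeros are replaced by `zero_fill` (default 1e-6).

Two choices deserve comment.

* *Rounding granularity.* "Round to the tenth decimal place" can be read
  as one decimal on the percent scale or ten decimals on the proportion
  scale. The default is ten proportion decimals: one percent-decimal
  rounding would zero out everything the subsequent 1e-6 fill is meant to
  rescue, making the fill meaningless. The digit count is configurable for
  anyone preferring the other reading.
* *Scope of zero replacement.* The filled table exists solely for
  proportion-scale statistics (the beta likelihood and the logit
  transform, which are undefined at 0). Diversity is computed from raw
  counts; presence/absence quantities (prevalence, binary Jaccard) must
  also use unfilled data — after filling, every genus is "present"
  everywhere and binary Jaccard degenerates to zero. The library logs a
  warning if binary Jaccard is requested on a zero-replaced table.

## Core, unique, and aggregated taxa

A genus is **core** within a scope (whole dataset or one cohort) when its
prevalence (fraction of samples with raw count > 0) is ≥ 90% and its
scope-mean relative abundance is ≥ 0.1%; both boundaries are inclusive, so
a genus at exactly 90.0% prevalence qualifies. The abundance screen is
implemented as mean per-sample relative abundance (matching how the
summary tables report abundance); a reads-share basis is available via
`CoreCriteria(abundance_basis="reads")`. A genus is **unique** to a cohort
when it is detected in no other cohort and in ≥ 10% (inclusive) of that
cohort's samples. The **aggregate set** is the union over cohorts of each
cohort's top-10 genera by within-cohort mean relative abundance (ties
broken by genus name); all remaining genera are summed into an `other`
column, so aggregated rows preserve their original sums exactly.

## Diversity

All four indices are computed on counts rarefied to a common depth
(default 1,000 reads), one draw per sample, drawn without replacement via
the multivariate hypergeometric distribution; the seed is recorded in the
output so runs are reproducible. Richness is the count of genera with a
positive rarefied count; Shannon uses natural log; inverse Simpson is
1/Σp². The widely used verbal gloss of inverse Simpson ("inverse of the
probability that two randomly chosen reads belong to *different* genera")
literally describes 1/(1−Σp²); the implementation uses the standard
1/Σp² and notes the discrepancy here rather than guessing intent.

Fisher's α solves S = α ln(1 + N/α) by Brent root-finding on a bracket
that covers the root's growth like N²/(2(N−S)) near S → N; the returned
residual is below 1e-8 everywhere on a broad (S, N) grid. A finite
positive root exists precisely when 1 ≤ S < N, so α is reported missing
(NaN, with a warning) only for S = N. α is strictly increasing in S and
decreasing in N.

## Community comparison

Bray-Curtis (Σ|x−y|/Σ(x+y)) and Jaccard (binary 1 − |A∩B|/|A∪B|;
quantitative Ruzicka 1 − Σmin/Σmax behind a flag) are computed on
abundance vectors. Hierarchical clustering is unweighted average linkage
(UPGMA): the inter-cluster distance is the unweighted mean over all
cross pairs of leaves, merges with tied distances are broken by the
smallest cluster-index pair, and heights are monotone non-decreasing.
Dendrograms export to Newick with branch lengths equal to merge-height
differences. The implementation is cross-checked against scipy's
`linkage(method="average")` in the test suite.

ANOSIM ranks all n(n−1)/2 distances with mid-rank ties and forms
R = (mean between-group rank − mean within-group rank)/(n(n−1)/4). The
permutation P-value uses the convention that the observed labelling counts
as one permutation, P = (1 + #{R\* ≥ R})/(1 + n_perm), so the smallest
achievable value at 999 permutations is 1/1000 — consistent with reporting
"P < 0.001" at that permutation count. An exact mode enumerates all
distinct label assignments for small n (the perfectly separated 2+2 toy
gives exactly P = 1/3).

## Abundance and diversity models

Relative abundances (zero-replaced, strictly inside (0, 1)) are modelled
per genus as y ~ Beta(μ_k φ, (1−μ_k) φ) with a logit link on the group
means μ_k and a **common precision** φ across groups (a per-group-φ
generalization was considered and left out: the study-sized groups of
12–43 samples do not support stable group-specific precisions). Fitting is
maximum likelihood: a method-of-moments start, L-BFGS-B with analytic
gradient, then damped Newton polish until the score norm is below 1e-8.
Standard errors come from the observed information (central differences of
the analytic score). The overall cohort effect is a likelihood-ratio test
against the intercept-only model (χ², K−1 df); pairwise contrasts are Wald
z-tests on the link scale with Bonferroni multiplier m = K(K−1)/2 (m = 55
for 11 cohorts). Letter displays use the insert-and-absorb algorithm;
after absorption, two groups share a letter exactly when their adjusted P
exceeds α, a property the tests verify by reconstruction on random
significance patterns.

Diversity indices use an ordinary one-way ANOVA, by default on ln(y) with
back-transformed (geometric-mean) group estimates; Shannon is analysed
untransformed, following the convention that its values are already
approximately normal.

## Dyad association

Only matched dyads enter these analyses. The Spearman screen computes
mid-rank rs between every (milk genus, feces genus) pair over dyads, with
t-approximation P-values, flagged at P < 0.01 and |rs| > 0.3. Constant
variables yield missing rs with a warning.

Canonical correlation runs on logit-transformed, per-variable standardized
blocks (entries at or above 1 are clipped to 1 − 1e-6). The canonical
correlations are the singular values of the whitened cross-covariance;
rank-deficient blocks raise an error naming the collinear variables unless
a ridge term is enabled. Loadings are reported as Spearman correlations of
each original variable with its side's first variate, and the overall
significance of the canonical set uses Bartlett's chi-square
approximation, −(n − 1 − (p+q+1)/2) Σ ln(1−r_i²) on pq degrees of
freedom. The first canonical correlation is affine-invariant per variable
and dominates every single-pair correlation; both properties are tested.

The matched-dyad similarity test computes d(milk_i, feces_i) for every
dyad and d(milk_i, feces_j) for all i ≠ j on a shared genus universe, then
compares the two sets with a two-sample rank-sum test (mid-rank tie
correction, normal approximation, two-sided), reporting the signed median
difference so direction is explicit. **Caveat:** the two sets share the
same underlying samples, so they are not independent; the rank-sum normal
approximation is therefore conservative under no coupling (its null
rejection rate is far below nominal — simulation places sd(z) near 0.43).
The test is nevertheless implemented in this classical form because that
is how such dyad comparisons are conventionally reported. For a calibrated
null, `dyad_similarity_test(..., permutation=n)` additionally shuffles the
dyad pairing and recomputes the mean matched distance; under no coupling
that permutation null is exact, and the test suite verifies its
calibration alongside the rank-sum version's conservatism.

Diversity correlations are per-index Spearman r and P across dyads,
overall or per cohort; scopes with fewer than 5 dyads are skipped with a
warning.

## Synthetic paired-dyad generator

Per dyad in cohort k: the mother's milk composition is drawn as
p_milk ~ Dirichlet(c_milk · m_milk[k]); the infant's fecal composition as
p_feces ~ Dirichlet(c_feces · ((1−λ) m_feces[k] + λ p_milk)); read counts
are multinomial at log-normal depths floored at the rarefaction depth.
Coupling acts on the Dirichlet *mean*, not by mixing counts, so λ has a
clean population interpretation: at λ = 0 matched and non-matched dyads
are exchangeable (the pairing-permutation null is exact), and at λ = 1
each infant's expected composition equals its own mother's realized milk
composition.

Default parameters, chosen once as study-shaped conditions:

| parameter | default | rationale |
|---|---|---|
| cohorts × dyads | 11 × 33 | ≈ the study's 360 dyads across 11 cohorts |
| genera G | 50 | typical genus-table width after pruning |
| base composition | power-law rank profile (exponent 1.1) with per-cohort log-normal perturbation (σ = 1) | few-dominant / long-tail shape of real genus tables |
| c_milk, c_feces | 15, 50 | milk communities vary more across mothers, consistent with the study's much larger milk depth/composition spread |
| coupling λ | 0.3 | modest vertical-transfer signal, matching the weak-but-detectable dyad effect such studies report |
| depths | log-normal, feces mean 11,444 sd 6,198; milk 17,029 sd 16,783; floor 1,000 | the study's printed read-depth spread |

Planted structure is enforced, not merely probable: planted-core genera
are guaranteed a read in every sample (one read is moved from the sample's
most abundant genus if the multinomial draw missed them), and
planted-unique genera carry mass in exactly one cohort. Five frozen
scenarios (`null_no_structure`, `cohort_structure`, `dyad_coupling`,
`core_recovery`, `unique_recovery`) fix all parameters and seeds for the
acceptance suite; `core_recovery` uses a flat jittered background at
concentration 5 so that background genera fail the 90% prevalence screen
while passing the abundance screen, isolating the prevalence criterion.

What the generator does **not** emulate: sequencing error, chimeras and
taxonomic misassignment; compositional correlations between specific
genera (beyond what the Dirichlet induces); longitudinal structure; and
zero inflation beyond Dirichlet-multinomial sparsity. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated model, not robustness to those real-data features.

## Numerical conventions

Rounding is half-to-even throughout so results are bit-reproducible.
All stochastic routines take a seed (an integer or numpy Generator) and
record it in their output. Problem sizes in the test and acceptance runs
(e.g. 100–500 simulation replicates, 2,000 rarefaction draws, 999
permutations) were chosen so each check resolves its target within
Monte-Carlo error while the whole suite stays fast on a single CPU.

## Known limitations

* The rank-sum dyad test is conservative (see above); its nominal-rate
  calibration holds only for the permutation variant.
* Bartlett's CCA P assumes multivariate normality of the logit-transformed
  blocks; with strongly non-normal blocks it is approximate.
* The beta model assumes a common precision; strong group-wise dispersion
  differences would be absorbed into the means.
* Cohort-level clustering of printed means treats the published
  cohort-mean vectors as compositions over the aggregate genus set only
  (the printed tables do not sum to 100%); an `other` remainder column can
  be appended by the caller if desired.
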
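# Methods

## Estimation model

Expression levels are treated as standardized quantitative traits on a
single cohort of nominally unrelated individuals. For one transcript,
`y = μ + g + e` with `g ~ N(0, σ²_g A)` and `e ~ N(0, σ²_e I)`; the GRM
`A` is built from sample-standardized allele counts,
`A_jk = (1/M) Σ_i (x_ij − 2p_i)(x_ik − 2p_i) / (2p_i(1−p_i))`, after a
minor-allele-frequency filter (default 0.01), with monomorphic SNPs
excluded and missing genotypes mean-imputed. Heritability is
`h² = σ²_g/(σ²_g+σ²_e)`.

For a transcript pair the two traits share the GRM, and the stacked
covariance has genetic blocks `A σ²_g·` / `A σ_gi,gj` and residual
blocks `I σ²_e·` / `I σ_eij`. The residual covariance block is **on by
default**: both traits are measured on the same individuals, so a model
without it is misspecified whenever the phenotypic correlation differs
from the genetic one. A switch (`include_residual_cov=False`) reproduces
the stricter two-independent-samples form; the grid-search oracle tests
exercise both.

Fixed effects are intercepts only — expression values are assumed
already normalized and residualized for covariates and batch structure,
which is how such matrices are distributed.

## REML implementation

All pair fits reuse one eigendecomposition `A = U diag(d) U'`. In the
rotated basis the bivariate covariance splits into n independent 2×2
blocks `S_k = d_k G + E`, so the restricted likelihood, its gradient and
the average-information (AI) matrix are O(n) per evaluation; the
eigendecomposition is the only O(n³) step and is shared across all
pairs. The rotated implementation is checked against a literal
dense-matrix REML evaluation to ~1e-10.

Updates are AI-REML with:

- an EM-style first step (robust far from the optimum);
- projection into the feasible region after every step: variances
  floored at ε = 1e-6 × the phenotypic variance, covariances clamped so
  implied |correlations| ≤ 1 − 1e-6;
- an active-set rule — a parameter pinned at its floor/clamp with an
  outward gradient is dropped from the AI solve;
- step halving, then a projected-gradient step, then an EM-REML step as
  successive fallbacks when an update fails to increase the likelihood;
- convergence at |ΔlogL| < 1e-4, at most 100 iterations (GCTA-like
  defaults). Non-convergence is a flagged result, never an exception.

Near the variance floor the AI matrix is a poor curvature model (the
likelihood is extremely anisotropic: gradients of order 10 against
curvatures of order 1e12), and the loop can stall short of the optimum.
A final quasi-Newton polish over the smooth parameterization
(log-variances, atanh-scaled correlations; L-BFGS-B) is therefore run
after the loop and adopted only when it improves the restricted
likelihood. With it, random multi-start probes find no better point on
small instances, and the optimum dominates exhaustive grid search.

`r̂_G = σ̂_gi,gj / √(σ̂²_gi σ̂²_gj)`, clamped to ±1 with a boundary flag;
undefined (NaN, flagged) when a genetic variance sits at its floor. The
SE comes from the first-order delta method using the 3×3 block of the
inverse-AI covariance for (σ_gi,gj, σ²_gi, σ²_gj); the Wald statistic
`(r̂_G/SE)²` is referred to χ²₁. At a boundary the curvature is
one-sided and the SE is unreliable — flagged, not suppressed.

## Null model and multiplicity

Under `r_G = 0`, `var(r̂_G) ≈ 1/(h̄²_gi h̄²_gj N² var(A_ij))` with
`var(A_ij)` the population variance of the GRM's strictly-lower-triangle
entries. Its square root σ gives the 2/3/4σ thresholds used for network
edges, and `m × (two-sided tail mass)` the expected exceedance count per
transcript. By default the tail masses use the conventionally rounded
central masses (0.9545 at 2σ, 0.9973 at 3σ) so printed reference numbers
are reproduced exactly; exact Gaussian masses are available via
`conventional=False`. Ceilings are reported alongside expectations for
integer summaries. Bonferroni is `α/n_tests`; the FDR procedure is
Benjamini–Hochberg (statsmodels implementation behind the module
surface, verified against the literal step-up definition).

## Downstream analyses

**Shared eSNPs.** The top eSNP of a transcript is its smallest-p
association below 1e-6 (ties: larger |β|, then smaller chromosome and
position). Each pair contributes up to two cross-lookups (eSNP_i on
transcript j, eSNP_j on transcript i), both counted in the Bonferroni
denominator. A pair is evaluable only when both cross rows exist; a
missing row is data absence, not an error. "Cis" means same chromosome
and within 1 Mb (configurable window). Significant shared eSNPs are
classified by sign concordance of the two cross betas against the sign
of r̂_G (categories i–iv), summarized with an equal-occupancy
goodness-of-fit χ² (df = 3). The r_G binning uses half-open bins of
width 0.1 over [−1, 1] with the top bin closed.

**Chromatin contacts.** Contacts are BEDPE on disk (0-based half-open),
1-based inclusive internally. Intrachromosomal contacts with anchor
midpoints closer than 20 kb are removed as self-ligation artifacts
(strict <). A pair overlaps a contact when one transcript position is
within the window of one anchor interval (distance to the nearest
interval point, i.e. interval edges) and the partner within the window
of the other anchor, under either assignment; intrachromosomal pairs
separated by less than the window are excluded from evaluation to
remove trivial cis proximity. The permutation null shuffles the j-side
loci (both marginal locus multisets preserved) and recomputes the count
under identical exclusions; the two-tailed p is
`min(1, 2·min(P_up, P_low))` with the add-one correction, so the
attainable minimum with B permutations is 2/(B+1) (≈0.002 at the
default B = 1000). Transcripts are anchored at their single annotated
position.

**Networks and TF enrichment.** Edges are pairs with |r̂_G| above a σ
threshold; connection counts accrue to both endpoints; hubs are ranked
by count with probe-id tie-breaks. TF enrichment is the hypergeometric
upper tail P(X ≥ k) over unique gene symbols: background = expressed
gene universe, successes = expressed TFs, sample = hub genes.

## Synthetic cohort generator

Genotypes are i.i.d. Binomial(2, p) per SNP with p uniform on the MAF
range — no linkage disequilibrium, so `var(A_ij) ≈ 1/M` exactly by
construction, and every null-model check uses the synthetic GRM's own
off-diagonal variance rather than any external constant. For a pair,
effects on a common causal set are `β_i = √h²_i · a` and
`β_j = √h²_j · (r_G a + √(1−r²_G) b)` with a, b i.i.d. N(0, 1/n_causal)
on standardized genotypes; residuals are bivariate normal with variances
1 − h² and correlation r_E; phenotypes are standardized after
generation. Defaults mirror the reference cohort: N = 1748, h² = 0.375.

Two generator properties matter for interpreting tests:

- *Realized-architecture noise.* The mixing construction hits r_G in
  expectation; the realized correlation of the effect vectors
  fluctuates with SD ≈ 1/√n_causal around it. Calibration suites
  (null p uniformity, the Visscher variance ratio) therefore use the
  infinitesimal architecture (n_causal = n_snps), where this component
  is negligible next to estimation noise; sparse-architecture suites
  measure means (bias), which the fluctuation does not affect.
- *Relatedness-filter regime.* With independent SNPs the GRM
  off-diagonal SD is 1/√M, so the 0.05 unrelatedness cutoff is only
  meaningful when M is large enough to put it in the far tail of the
  null relatedness distribution (with a real genome-wide panel it sits
  at ~8σ). The default M = 8000 puts it at ~4.5σ; study fixtures use
  M = 5000 at their smaller N.

The generator also emits a self-consistent study bundle: annotation,
an eQTL summary table in which each transcript's planted top eSNP has
p < 1e-6 and planted shared eSNPs carry sign-controlled cross rows for
both probes, contact lists with anchors at designated pairs' loci plus
background contacts placed in transcript-free regions, and a TF list
with optional excess TF labelling of the "hub" (shared-eSNP) genes for
enrichment plant-and-recover checks. What it does **not** emulate: LD
structure, array noise and probe effects, cell-type composition,
population stratification, or eQTL tables derived from actual
regressions (summary rows are synthesized directly). Passing tests
therefore validate the estimation and testing machinery, not robustness
to those real-data complications.

## Problem sizes

The test and acceptance suites run at desk scale, chosen so the whole
battery completes in minutes on one CPU while keeping each check
well-powered: recovery and calibration cohorts of N = 500 with M = 2000
SNPs (30–40 replicates per condition; 300–400 null fits), grid-search
oracles at n = 40, and study bundles of 8–12 transcript pairs at
N = 250–700. The pipeline itself is O(P · n) per pair after one O(n³)
eigendecomposition and comfortably handles thousands of pairs.

## Known limitations

- The AI-based SE underestimates slightly in small-N, weak-GRM regimes
  (the delta-method SE is first-order); the Monte-Carlo calibration
  test bounds the discrepancy at 25% under the tested conditions.
- Boundary solutions (r̂_G at ±1, variance at floor) carry flagged,
  unreliable SEs; downstream tests treat them as such rather than
  excluding them.
- The greedy relatedness filter is one reasonable resolution of
  pairwise violations into individual exclusions; alternatives (e.g.
  maximum independent set) retain slightly different cohorts.
- Multi-trait (>2) models, dominance, GxE and summary-statistic
  (LD-score) estimation are out of scope.
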
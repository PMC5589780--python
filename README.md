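# txgc — genetic correlations between transcript expression levels

`txgc` estimates, for pairs of expression traits measured on the same
cohort, how much of their co-expression is driven by shared genetic
variance. It implements bivariate genomic REML (GREML) over a genomic
relationship matrix (GRM), and the downstream analyses that interpret a
table of pairwise genetic correlations: a closed-form null model with
sigma exceedance thresholds, co-regulation networks and hub transcripts,
shared-eSNP cross-lookup against an independent eQTL catalogue,
chromatin-contact overlap permutation tests, and transcription-factor
enrichment. A synthetic cohort generator with planted ground truth makes
the whole pipeline testable end to end.

It is written for statistical geneticists and computational biologists
who want a transparent, fully tested desk-scale implementation of this
analysis chain rather than a wrapper around external tooling.

## Model

For transcripts *i* and *j* measured on *n* individuals,

    y_i = μ_i + g_i + e_i,    y_j = μ_j + g_j + e_j,

with polygenic effects g ~ N(0, σ²_g **A**) for the GRM **A** and
residuals e ~ N(0, σ²_e **I**). The stacked covariance is

    V = [ A σ²_gi + I σ²_ei     A σ_gi,gj + I σ_eij ]
        [ A σ_gi,gj + I σ_eij   A σ²_gj + I σ²_ej   ]

(the residual covariance block is optional and on by default). The
genetic correlation is

    r̂_G = σ̂_gi,gj / √(σ̂²_gi σ̂²_gj),   constrained to [−1, 1],

with a delta-method (first-order Taylor) standard error and a Wald test
r̂²_G / var(r̂_G) against χ²₁. Under H₀: r_G = 0 the sampling variance is
approximately 1 / (h̄²_gi h̄²_gj N² var(**A**_ij)) (Visscher's
approximation), whose square root σ sets the 2/3/4σ network-edge
thresholds.

Estimation is AI-REML (average-information updates with EM warmup and
fallback, variance floors and correlation clamps) on the eigenbasis of
**A**: one eigendecomposition is shared across all pair fits, making
each per-pair likelihood evaluation O(n).

## Worked example

The numbered scripts under `analysis/` run the full study on a synthetic
cohort (700 individuals × 5000 SNPs, 12 transcript pairs of which 6 have
planted |r_G| = 0.9, 6 carry a planted shared eSNP and 6 a planted
chromatin contact):

```
python analysis/01_simulate_study.py --seed 1
python analysis/02_relatedness_and_heritability.py
python analysis/03_genetic_correlations.py
python analysis/04_shared_esnps.py
python analysis/05_chromatin_overlap.py --seed 1
python analysis/06_networks_and_tf.py
```

Output of the central stages (seed 1):

```
GRM from 4992 SNPs; var(A_ij) = 1.98e-04
unrelatedness filter (> 0.05): kept 667 of 700 individuals
h2 screen (> 0.25): 23 of 24 probes retained (mean h2 of retained = 0.551)
fitted 253 pairs; 100.0% converged
Bonferroni (p < 1.98e-04): 4 significant pairs
BH-FDR (q = 0.05): 5 significant pairs
null model: var(r_G|0) = 0.0374; sigma thresholds 2/3/4 = 0.39/0.58/0.77
5 pairs examined; 5 evaluable; 5 with a significant shared eSNP (Bonferroni p < 5.00e-03)
concordance categories i-iv: {'i': 2, 'ii': 0, 'iii': 0, 'iv': 3}
window   500 kb: observed 5 overlaps, null mean 1.01, p = 0.01998
TF enrichment in hub genes: 1/12 TFs vs 4/24 in background, hypergeometric p = 0.953
```

Reading this: of the six pairs simulated with |r_G| = 0.9, five survive
the heritability screen and reach FDR significance; every one of their
planted shared eSNPs is recovered by the cross-lookup, with the sign
concordance category (i = positive r_G / same-sign betas, iv = negative
r_G / opposite-sign betas) matching the planted signs; the planted
contacts produce a five-fold overlap excess over the shuffled-pair null;
and TF enrichment is null because this run plants no TF bias.

Each stage writes its table under `results/` (r_G table, h² table,
eSNP results and bins, overlap counts, hub table, network edge list).

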
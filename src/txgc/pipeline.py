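"""End-to-end driver: filters -> GRM -> h2 screen -> pairwise r_G -> downstream.

Stage order mirrors the study design: build the GRM from MAF-filtered
genotypes, drop related individuals, screen transcripts for heritability
(h2 > 0.25 by default), fit bivariate GREML for every remaining
transcript pair, annotate multiplicity (Bonferroni and BH-FDR) and
null-model sigma thresholds, then run the interpretive layers: shared
eSNP cross-lookup, chromatin-contact overlap permutation tests, and
co-regulation networks with TF enrichment.  Every stage is an importable
function; ``run_pipeline`` composes them and returns a manifest of
per-stage counts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from txgc.esnp import SharedEsnpResult, bin_shared_fraction, cross_lookup
from txgc.greml import GRMEigen, fit_pair, reml_univariate
from txgc.grm import GRM, compute_grm, filter_unrelated, offdiag_variance
from txgc.hic import DEFAULT_WINDOWS, PermutationResult, filter_self_ligation, permutation_test
from txgc.network import EnrichmentResult, hub_table, tf_enrichment
from txgc.nullmodel import NullModel, bh_fdr, bonferroni, sigma_threshold
from txgc.simulate import StudyBundle

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Pipeline constants; defaults are the study's stated filter values."""

    h2_min: float = 0.25
    relatedness_threshold: float = 0.05
    maf_min: float = 0.01
    alpha: float = 0.05
    fdr_q: float = 0.05
    esnp_p_max: float = 1e-6
    windows: tuple[int, ...] = DEFAULT_WINDOWS
    n_permutations: int = 1000
    sigma_multipliers: tuple[int, ...] = (2, 3, 4)
    hub_sigma_multiplier: int = 3
    include_residual_cov: bool = True
    seed: int = 0


@dataclass
class PipelineResult:
    grm: GRM
    retained_individuals: np.ndarray
    h2_table: pd.DataFrame
    rg_table: pd.DataFrame
    null_model: NullModel | None
    sigma_thresholds: dict[int, float]
    esnp_results: list[SharedEsnpResult]
    esnp_bins: pd.DataFrame | None
    permutations: dict[int, PermutationResult]
    hubs: pd.DataFrame
    enrichment: EnrichmentResult | None
    manifest: dict = field(default_factory=dict)


def h2_screen(
    expression: pd.DataFrame, eig: GRMEigen, h2_min: float
) -> pd.DataFrame:
    """Univariate REML per probe; returns the h2 table with a pass flag."""
    rows = []
    for probe, y in expression.iterrows():
        fit = reml_univariate(y.to_numpy(dtype=float), eig)
        rows.append(
            {
                "probe_id": probe,
                "h2": fit.h2,
                "se_h2": fit.se_h2,
                "converged": fit.converged,
                "passed": fit.converged and fit.h2 > h2_min,
            }
        )
    return pd.DataFrame(rows)


def pairwise_rg(
    expression: pd.DataFrame,
    eig: GRMEigen,
    annotation: pd.DataFrame,
    probes: list[str],
    include_residual_cov: bool = True,
) -> pd.DataFrame:
    """Bivariate GREML over all unordered probe pairs."""
    ann = annotation.set_index("probe_id")
    rows = []
    for pi, pj in itertools.combinations(probes, 2):
        inter = bool(ann.loc[pi, "chromosome"] != ann.loc[pj, "chromosome"])
        est = fit_pair(
            expression.loc[pi].to_numpy(dtype=float),
            expression.loc[pj].to_numpy(dtype=float),
            eig,
            probe_i=pi,
            probe_j=pj,
            include_residual_cov=include_residual_cov,
            interchromosomal=inter,
        )
        rows.append(
            {
                "probe_i": pi,
                "probe_j": pj,
                "r_P": est.r_P,
                "r_G": est.r_G,
                "se_rG": est.se_rG,
                "chi2": est.chi2,
                "p_value": est.p_value,
                "interchromosomal": inter,
                "converged": est.converged,
                "boundary": est.boundary_flag,
                "defined": est.defined,
            }
        )
    return pd.DataFrame(rows)


def annotate_multiplicity(rg_table: pd.DataFrame, alpha: float, q: float) -> pd.DataFrame:
    """Append Bonferroni and BH-FDR significance columns to the r_G table."""
    out = rg_table.copy()
    testable = out["defined"] & out["p_value"].notna()
    n_tests = int(testable.sum())
    thr = bonferroni(alpha, n_tests) if n_tests else float("nan")
    out["bonferroni_significant"] = testable & (out["p_value"] < thr)
    out["fdr_significant"] = False
    out["p_fdr"] = np.nan
    if n_tests:
        reject, p_adj = bh_fdr(out.loc[testable, "p_value"].to_numpy(), q)
        out.loc[testable, "fdr_significant"] = reject
        out.loc[testable, "p_fdr"] = p_adj
    out.attrs["bonferroni_threshold"] = thr
    out.attrs["n_tests"] = n_tests
    return out


def pair_loci(rg_table: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    ann = annotation.set_index("probe_id")
    out = rg_table[["probe_i", "probe_j"]].copy()
    out["chrom_i"] = ann.reindex(out["probe_i"])["chromosome"].to_numpy()
    out["pos_i"] = ann.reindex(out["probe_i"])["position"].to_numpy()
    out["chrom_j"] = ann.reindex(out["probe_j"])["chromosome"].to_numpy()
    out["pos_j"] = ann.reindex(out["probe_j"])["position"].to_numpy()
    return out


def run_pipeline(bundle: StudyBundle, config: PipelineConfig | None = None) -> PipelineResult:
    """Run every stage on a study bundle and collect a count manifest.

    Per-pair non-convergence is recorded in the r_G table, never fatal.
    """
    config = config or PipelineConfig()
    import txgc

    manifest: dict = {
        "config": {k: v for k, v in config.__dict__.items()},
        "versions": {"txgc": txgc.__version__, "numpy": np.__version__},
    }

    # stage 1: GRM and relatedness filter
    grm_full = compute_grm(bundle.genotypes, maf_min=config.maf_min)
    retained = filter_unrelated(grm_full, threshold=config.relatedness_threshold)
    grm = GRM(
        A=grm_full.A[np.ix_(retained, retained)],
        individual_ids=grm_full.individual_ids[retained],
        n_snps_used=grm_full.n_snps_used,
    )
    expression = bundle.expression.iloc[:, retained]
    manifest["n_individuals"] = int(grm_full.n)
    manifest["n_retained"] = int(len(retained))
    manifest["n_snps_used"] = int(grm.n_snps_used)
    eig = GRMEigen.from_grm(grm)

    # stage 2: heritability screen
    h2_table = h2_screen(expression, eig, config.h2_min)
    probes = h2_table.loc[h2_table["passed"], "probe_id"].tolist()
    manifest["n_probes"] = int(len(h2_table))
    manifest["n_probes_h2_pass"] = int(len(probes))

    empty_rg = pd.DataFrame(
        columns=[
            "probe_i", "probe_j", "r_P", "r_G", "se_rG", "chi2", "p_value",
            "interchromosomal", "converged", "boundary", "defined",
            "bonferroni_significant", "fdr_significant", "p_fdr",
        ]
    )
    if len(probes) < 2:
        manifest["n_pairs_tested"] = 0
        return PipelineResult(
            grm=grm,
            retained_individuals=retained,
            h2_table=h2_table,
            rg_table=empty_rg,
            null_model=None,
            sigma_thresholds={},
            esnp_results=[],
            esnp_bins=None,
            permutations={},
            hubs=pd.DataFrame(),
            enrichment=None,
            manifest=manifest,
        )

    # stage 3: pairwise genetic correlations + multiplicity
    rg_table = pairwise_rg(
        expression, eig, bundle.annotation, probes, config.include_residual_cov
    )
    rg_table = annotate_multiplicity(rg_table, config.alpha, config.fdr_q)
    manifest["n_pairs_tested"] = int(len(rg_table))
    manifest["n_converged"] = int(rg_table["converged"].sum())
    manifest["fraction_converged"] = float(rg_table["converged"].mean())
    manifest["n_bonferroni_significant"] = int(rg_table["bonferroni_significant"].sum())
    manifest["n_fdr_significant"] = int(rg_table["fdr_significant"].sum())

    # stage 4: null model from the cohort's own quantities
    h2_mean = float(h2_table.loc[h2_table["passed"], "h2"].mean())
    var_A = offdiag_variance(grm)
    null_model = NullModel(
        h2_mean_i=h2_mean,
        h2_mean_j=h2_mean,
        n=grm.n,
        var_A_offdiag=var_A,
        m=len(probes) - 1,
    )
    thresholds = {
        k: sigma_threshold(null_model.var_rg_null, k) for k in config.sigma_multipliers
    }
    manifest["var_A_offdiag"] = var_A
    manifest["var_rg_null"] = null_model.var_rg_null
    manifest["sigma_thresholds"] = {k: round(v, 2) for k, v in thresholds.items()}

    # stage 5: shared-eSNP cross-lookup on the FDR-significant pairs
    focus = rg_table[rg_table["fdr_significant"]]
    if focus.empty:
        focus = rg_table
    n_evaluable = 2 * len(focus)  # two lookups attempted per pair
    esnp_results = []
    rg_by_pair = {}
    for _, row in focus.iterrows():
        res = cross_lookup(
            row["probe_i"],
            row["probe_j"],
            bundle.eqtl,
            n_evaluable=n_evaluable,
            alpha=config.alpha,
            p_max=config.esnp_p_max,
            annotation=bundle.annotation,
            r_G=row["r_G"],
        )
        esnp_results.append(res)
        rg_by_pair[(row["probe_i"], row["probe_j"])] = row["r_G"]
    esnp_bins = bin_shared_fraction(esnp_results, rg_by_pair)
    manifest["n_esnp_evaluable"] = int(sum(r.evaluable for r in esnp_results))
    manifest["n_esnp_shared_significant"] = int(sum(r.significant for r in esnp_results))

    # stage 6: chromatin-contact overlap permutation per window
    contacts = filter_self_ligation(bundle.contacts)
    loci = pair_loci(focus, bundle.annotation)
    permutations: dict[int, PermutationResult] = {}
    if len(loci) >= 2 and len(contacts):
        for w in config.windows:
            permutations[w] = permutation_test(
                loci, contacts, window=w, B=config.n_permutations, seed=config.seed
            )
    manifest["hic_observed"] = {w: p.observed for w, p in permutations.items()}
    manifest["hic_p"] = {w: p.p_two_tailed for w, p in permutations.items()}

    # stage 7: networks, hubs, TF enrichment
    hub_thr = thresholds.get(config.hub_sigma_multiplier, 0.72)
    hubs = hub_table(rg_table, bundle.annotation, threshold=min(hub_thr, 1.0))
    ann = bundle.annotation.set_index("probe_id")
    hub_genes = set(
        ann.reindex(hubs.loc[hubs["n_connections"] > 0, "probe_id"])["gene_id"].dropna()
    )
    background = set(bundle.annotation["gene_id"])
    enrichment = (
        tf_enrichment(hub_genes, set(bundle.tf_genes), background) if hub_genes else None
    )
    manifest["n_hub_genes"] = len(hub_genes)
    if enrichment is not None:
        manifest["tf_enrichment_p"] = enrichment.p_value

    return PipelineResult(
        grm=grm,
        retained_individuals=retained,
        h2_table=h2_table,
        rg_table=rg_table,
        null_model=null_model,
        sigma_thresholds=thresholds,
        esnp_results=esnp_results,
        esnp_bins=esnp_bins,
        permutations=permutations,
        hubs=hubs,
        enrichment=enrichment,
        manifest=manifest,
    )
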
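"""Synthetic cohort generator with known ground truth.

Emulates the data a genetic-correlation study consumes: Hardy–Weinberg
genotypes at independent SNPs, bivariate polygenic expression traits with
specified heritabilities and genetic/residual correlations, eQTL summary
tables with planted shared eSNPs of controlled sign, chromatin-contact
lists with anchors planted at transcript loci, and a transcription-factor
subset of the gene universe.  Every stage downstream can therefore be
tested against planted truth.

The generative model inverts the estimation model: for a transcript pair
(i, j) with heritabilities h2_i, h2_j, genetic correlation r_G and
residual correlation r_E, genetic values are linear combinations of
standardized genotypes over a common causal set,

    beta_i = sqrt(h2_i) * a,
    beta_j = sqrt(h2_j) * (r_G * a + sqrt(1 - r_G^2) * b),

with a, b i.i.d. N(0, 1/n_causal), so that var(g) = h2 and
corr(g_i, g_j) = r_G in expectation; residuals are bivariate normal with
variances 1 - h2 and correlation r_E.  Phenotypes are standardized to
zero mean, unit variance after generation, mirroring normalized
expression levels.  Genotypes are drawn i.i.d. per SNP (no linkage
disequilibrium), so the off-diagonal variance of the GRM is ~ 1/M.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from txgc.grm import GenotypeMatrix, standardize_genotypes

__all__ = [
    "SimConfig",
    "StudyConfig",
    "PairTruth",
    "StudyTruth",
    "StudyBundle",
    "simulate_genotypes",
    "simulate_transcript_pair",
    "simulate_study",
]


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror a large unrelated-blood-donor expression cohort:
    1748 individuals and mean transcript heritability 0.375.  The SNP
    panel is scaled down (independent markers only need to produce a
    usable GRM) but kept large enough that the GRM off-diagonal noise,
    SD = 1/sqrt(n_snps), leaves the 0.05 unrelatedness cutoff in the
    far tail, as it is with a genome-wide panel.
    """

    n_individuals: int = 1748
    n_snps: int = 8000
    maf_range: tuple[float, float] = (0.01, 0.5)
    n_causal: int = 100
    h2_i: float = 0.375
    h2_j: float = 0.375
    r_G: float = 0.5
    r_E: float = 0.2
    seed: int = 0
    n_chromosomes: int = 5
    chrom_length: int = 100_000_000

    def validate(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("need at least 2 individuals")
        if self.n_snps < 1:
            raise ValueError("need at least 1 SNP")
        lo, hi = self.maf_range
        if not (0.01 <= lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0.01 <= lo <= hi <= 0.5")
        for h2 in (self.h2_i, self.h2_j):
            if not 0.0 <= h2 <= 1.0:
                raise ValueError("heritabilities must lie in [0, 1]")
        if abs(self.r_G) > 1.0:
            raise ValueError("|r_G| must be <= 1")
        if not -1.0 < self.r_E < 1.0:
            raise ValueError("r_E must lie in (-1, 1)")
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal cannot exceed n_snps")


@dataclass
class PairTruth:
    """Planted ground truth for one simulated transcript pair."""

    causal_indices: np.ndarray
    beta_i: np.ndarray
    beta_j: np.ndarray
    h2_i: float
    h2_j: float
    r_G: float
    r_E: float
    g_i: np.ndarray = None  # type: ignore[assignment]
    g_j: np.ndarray = None  # type: ignore[assignment]
    e_i: np.ndarray = None  # type: ignore[assignment]
    e_j: np.ndarray = None  # type: ignore[assignment]


def simulate_genotypes(config: SimConfig, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Draw Hardy–Weinberg allele counts at independent SNPs.

    Per-SNP allele frequencies are uniform over ``maf_range`` and
    genotypes are Binomial(2, p).  SNPs are laid out in contiguous
    blocks over ``n_chromosomes`` synthetic chromosomes with sorted
    1-based positions.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, m = config.n_individuals, config.n_snps
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    counts = rng.binomial(2, mafs, size=(n, m)).astype(float)
    chroms = np.array([f"chr{1 + (i * config.n_chromosomes) // m}" for i in range(m)])
    positions = np.empty(m, dtype=int)
    for c in np.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        pos = np.sort(rng.choice(config.chrom_length, size=len(idx), replace=False)) + 1
        positions[idx] = pos
    return GenotypeMatrix(
        counts=counts,
        snp_ids=np.array([f"snp{i:06d}" for i in range(m)]),
        snp_chroms=chroms,
        snp_positions=positions,
        individual_ids=np.array([f"ind{i:05d}" for i in range(n)]),
        allele_freqs=counts.mean(axis=0) / 2.0,
    )


def simulate_transcript_pair(
    genotypes: GenotypeMatrix,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    causal_indices: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, PairTruth]:
    """Simulate one bivariate expression trait pair on a genotype cohort.

    Returns the two standardized phenotype vectors and the planted
    truth (causal set, effect vectors, genetic and residual components).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, m = genotypes.n_individuals, genotypes.n_snps
    if causal_indices is None:
        causal_indices = rng.choice(m, size=config.n_causal, replace=False)
    causal_indices = np.asarray(causal_indices)
    nc = len(causal_indices)

    W, _ = standardize_genotypes(genotypes.counts, genotypes.allele_freqs)
    Wc = W[:, causal_indices]

    a = rng.normal(0.0, np.sqrt(1.0 / nc), size=nc)
    b = rng.normal(0.0, np.sqrt(1.0 / nc), size=nc)
    beta_i = np.sqrt(config.h2_i) * a
    beta_j = np.sqrt(config.h2_j) * (config.r_G * a + np.sqrt(1.0 - config.r_G**2) * b)
    g_i = Wc @ beta_i
    g_j = Wc @ beta_j

    v_ei, v_ej = 1.0 - config.h2_i, 1.0 - config.h2_j
    cov_e = config.r_E * np.sqrt(v_ei * v_ej)
    E = rng.multivariate_normal([0.0, 0.0], [[v_ei, cov_e], [cov_e, v_ej]], size=n)
    e_i, e_j = E[:, 0], E[:, 1]

    y_i = g_i + e_i
    y_j = g_j + e_j
    y_i = (y_i - y_i.mean()) / y_i.std()
    y_j = (y_j - y_j.mean()) / y_j.std()
    truth = PairTruth(
        causal_indices=causal_indices,
        beta_i=beta_i,
        beta_j=beta_j,
        h2_i=config.h2_i,
        h2_j=config.h2_j,
        r_G=config.r_G,
        r_E=config.r_E,
        g_i=g_i,
        g_j=g_j,
        e_i=e_i,
        e_j=e_j,
    )
    return y_i, y_j, truth


@dataclass
class StudyConfig:
    """Layout of a full synthetic study over disjoint transcript pairs.

    The first ``n_shared_esnp_pairs`` pairs get a planted shared eSNP
    (cross-association rows for both probes, p far below any lookup
    threshold, beta signs matching the sign of the pair's r_G); their
    genes also form the "hub" group that the transcription-factor list
    can be biased toward via ``tf_hub_excess``.  The first
    ``n_planted_contact_pairs`` pairs get a chromatin contact whose
    anchors sit at the two transcript loci.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    n_pairs: int = 10
    rg_values: list[float] | None = None
    n_shared_esnp_pairs: int = 4
    n_planted_contact_pairs: int = 4
    n_background_contacts: int = 40
    n_noise_esnp_rows: int = 200
    tf_fraction: float = 0.10
    tf_hub_excess: float = 0.0
    anchor_halfwidth: int = 2500

    def pair_rg(self) -> list[float]:
        if self.rg_values is not None:
            if len(self.rg_values) != self.n_pairs:
                raise ValueError("rg_values length must equal n_pairs")
            return list(self.rg_values)
        vals = []
        for k in range(self.n_pairs):
            if k < self.n_shared_esnp_pairs:
                vals.append(0.9 if k % 2 == 0 else -0.9)
            else:
                vals.append(self.sim.r_G)
        return vals


@dataclass
class StudyTruth:
    """Planted truth across a whole synthetic study."""

    pairs: pd.DataFrame  # probe_i, probe_j, r_G, r_E, h2_i, h2_j, shared_esnp, esnp_sign_i, esnp_sign_j, contact_planted
    pair_truths: list[PairTruth]
    tf_genes: list[str]
    hub_genes: list[str]


@dataclass
class StudyBundle:
    """Self-consistent inputs for an end-to-end pipeline run."""

    genotypes: GenotypeMatrix
    expression: pd.DataFrame  # probes x individuals
    annotation: pd.DataFrame  # probe_id, gene_id, chromosome, position
    eqtl: pd.DataFrame  # snp_id, chromosome, position, probe_id, beta, se, p_value
    contacts: pd.DataFrame  # chrom1, start1, end1, chrom2, start2, end2 (1-based inclusive)
    tf_genes: list[str]
    truth: StudyTruth


def _place_transcripts(config: StudyConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign each transcript a probe/gene id and a genomic locus.

    Pairs alternate between interchromosomal and (well separated)
    intrachromosomal placement so both classes are represented.
    """
    rows = []
    sim = config.sim
    for k in range(config.n_pairs):
        inter = k % 2 == 0
        c1 = int(rng.integers(1, sim.n_chromosomes + 1))
        if inter:
            c2 = int(1 + (c1 % sim.n_chromosomes))
        else:
            c2 = c1
        p1 = int(rng.integers(1, sim.chrom_length // 2))
        # intrachromosomal partners sit >= 10 Mb away so window exclusion
        # rules do not silently remove them at the default window sizes
        p2 = int(rng.integers(1, sim.chrom_length // 2)) if inter else p1 + 10_000_000 + int(rng.integers(0, 10_000_000))
        for t, (c, p) in enumerate([(c1, p1), (c2, p2)]):
            idx = 2 * k + t
            rows.append(
                {
                    "probe_id": f"PROBE{idx:04d}",
                    "gene_id": f"GENE{idx:04d}",
                    "chromosome": f"chr{c}",
                    "position": p,
                }
            )
    return pd.DataFrame(rows)


def simulate_study(config: StudyConfig) -> StudyBundle:
    """Generate a complete synthetic study with planted structure.

    All randomness flows from ``config.sim.seed``.  The bundle is
    self-consistent: every expression probe has an annotation row, each
    transcript's planted top eSNP sits in the eQTL table with p below
    1e-6, and planted contacts anchor at transcript loci.
    """
    sim = config.sim
    sim.validate()
    rng = np.random.default_rng(sim.seed)
    genotypes = simulate_genotypes(sim, rng)
    annotation = _place_transcripts(config, rng)
    if annotation["probe_id"].duplicated().any():
        raise ValueError("duplicate probe identifiers in synthetic annotation")

    rg_vals = config.pair_rg()
    expr_rows = {}
    pair_truths: list[PairTruth] = []
    pair_records = []
    eqtl_rows = []
    contact_rows = []

    for k in range(config.n_pairs):
        pcfg = SimConfig(**{**sim.__dict__, "r_G": rg_vals[k]})
        y_i, y_j, truth = simulate_transcript_pair(genotypes, pcfg, rng)
        probe_i = annotation.iloc[2 * k]["probe_id"]
        probe_j = annotation.iloc[2 * k + 1]["probe_id"]
        expr_rows[probe_i] = y_i
        expr_rows[probe_j] = y_j
        pair_truths.append(truth)

        shared = k < config.n_shared_esnp_pairs
        contact = k < config.n_planted_contact_pairs

        # planted top eSNP rows: one strong association per transcript
        if shared:
            # one SNP drives both transcripts; cross rows are the same rows
            s = int(truth.causal_indices[0])
            sign_i = 1.0
            sign_j = 1.0 if rg_vals[k] > 0 else -1.0
            for probe, sign in [(probe_i, sign_i), (probe_j, sign_j)]:
                eqtl_rows.append(
                    {
                        "snp_id": genotypes.snp_ids[s],
                        "chromosome": genotypes.snp_chroms[s],
                        "position": int(genotypes.snp_positions[s]),
                        "probe_id": probe,
                        "beta": sign * 0.35,
                        "se": 0.04,
                        "p_value": 1e-12,
                    }
                )
            shared_esnp = genotypes.snp_ids[s]
        else:
            # distinct top eSNPs; cross rows exist but are far from significant
            s_i, s_j = (int(truth.causal_indices[0]), int(truth.causal_indices[1]))
            for s, probe_top, probe_cross in [(s_i, probe_i, probe_j), (s_j, probe_j, probe_i)]:
                eqtl_rows.append(
                    {
                        "snp_id": genotypes.snp_ids[s],
                        "chromosome": genotypes.snp_chroms[s],
                        "position": int(genotypes.snp_positions[s]),
                        "probe_id": probe_top,
                        "beta": 0.30,
                        "se": 0.04,
                        "p_value": 1e-10,
                    }
                )
                eqtl_rows.append(
                    {
                        "snp_id": genotypes.snp_ids[s],
                        "chromosome": genotypes.snp_chroms[s],
                        "position": int(genotypes.snp_positions[s]),
                        "probe_id": probe_cross,
                        "beta": float(rng.normal(0, 0.02)),
                        "se": 0.04,
                        "p_value": float(rng.uniform(0.3, 1.0)),
                    }
                )
            shared_esnp = ""
            sign_i = sign_j = 0.0

        if contact:
            hw = config.anchor_halfwidth
            a1 = annotation.iloc[2 * k]
            a2 = annotation.iloc[2 * k + 1]
            contact_rows.append(
                {
                    "chrom1": a1["chromosome"],
                    "start1": max(1, a1["position"] - hw),
                    "end1": a1["position"] + hw,
                    "chrom2": a2["chromosome"],
                    "start2": max(1, a2["position"] - hw),
                    "end2": a2["position"] + hw,
                }
            )

        pair_records.append(
            {
                "probe_i": probe_i,
                "probe_j": probe_j,
                "r_G": rg_vals[k],
                "r_E": sim.r_E,
                "h2_i": sim.h2_i,
                "h2_j": sim.h2_j,
                "shared_esnp": shared_esnp,
                "esnp_sign_i": sign_i,
                "esnp_sign_j": sign_j,
                "contact_planted": contact,
            }
        )

    # noise eQTL rows: random SNP/probe combinations, never significant
    probes = annotation["probe_id"].to_numpy()
    for _ in range(config.n_noise_esnp_rows):
        s = int(rng.integers(0, genotypes.n_snps))
        eqtl_rows.append(
            {
                "snp_id": genotypes.snp_ids[s],
                "chromosome": genotypes.snp_chroms[s],
                "position": int(genotypes.snp_positions[s]),
                "probe_id": str(rng.choice(probes)),
                "beta": float(rng.normal(0, 0.02)),
                "se": 0.04,
                "p_value": float(rng.uniform(1e-5, 1.0)),
            }
        )

    # background contacts away from transcript loci (second half of each
    # chromosome is transcript-free by construction)
    for _ in range(config.n_background_contacts):
        c1 = f"chr{int(rng.integers(1, sim.n_chromosomes + 1))}"
        c2 = f"chr{int(rng.integers(1, sim.n_chromosomes + 1))}"
        s1 = int(rng.integers(sim.chrom_length // 2 + 20_000_000, sim.chrom_length - 10_000))
        s2 = int(rng.integers(sim.chrom_length // 2 + 20_000_000, sim.chrom_length - 10_000))
        contact_rows.append(
            {
                "chrom1": c1,
                "start1": s1,
                "end1": s1 + 5000,
                "chrom2": c2,
                "start2": s2,
                "end2": s2 + 5000,
            }
        )

    # transcription-factor labels: baseline fraction everywhere, elevated
    # in the hub (shared-eSNP) group when tf_hub_excess > 0
    hub_genes = [
        annotation.iloc[2 * k + t]["gene_id"]
        for k in range(config.n_shared_esnp_pairs)
        for t in range(2)
    ]
    tf_genes = []
    for _, row in annotation.iterrows():
        p_tf = config.tf_fraction + (config.tf_hub_excess if row["gene_id"] in hub_genes else 0.0)
        if rng.uniform() < min(p_tf, 1.0):
            tf_genes.append(row["gene_id"])

    expression = pd.DataFrame(expr_rows, index=genotypes.individual_ids).T
    expression.index.name = "probe_id"
    truth = StudyTruth(
        pairs=pd.DataFrame(pair_records),
        pair_truths=pair_truths,
        tf_genes=tf_genes,
        hub_genes=hub_genes,
    )
    return StudyBundle(
        genotypes=genotypes,
        expression=expression,
        annotation=annotation,
        eqtl=pd.DataFrame(eqtl_rows),
        contacts=pd.DataFrame(contact_rows),
        tf_genes=tf_genes,
        truth=truth,
    )
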
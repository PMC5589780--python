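"""Genomic relationship matrix (GRM) construction and relatedness filtering.

The GRM entry for individuals j and k is the average over SNPs of the
product of their standardized allele counts,

    A_jk = (1/M) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i)),

the per-SNP standardization used throughout the GREML literature.  Allele
frequencies are estimated from the sample; missing genotypes are mean
imputed before standardization; monomorphic SNPs are excluded.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenotypeMatrix",
    "GRM",
    "compute_grm",
    "offdiag_variance",
    "filter_unrelated",
]


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs allele-count matrix with SNP metadata.

    ``counts`` holds 0/1/2 allele counts as a float array; missing
    genotypes are NaN.  ``allele_freqs`` is the sample frequency of the
    counted allele, recomputed lazily if not supplied.
    """

    counts: np.ndarray
    snp_ids: np.ndarray
    snp_chroms: np.ndarray
    snp_positions: np.ndarray
    individual_ids: np.ndarray
    allele_freqs: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D individuals x SNPs matrix")
        valid = np.isnan(self.counts) | np.isin(self.counts, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("allele counts must be in {0, 1, 2} or missing (NaN)")
        if self.allele_freqs is None:
            with np.errstate(invalid="ignore"):
                self.allele_freqs = np.nanmean(self.counts, axis=0) / 2.0
        self.allele_freqs = np.asarray(self.allele_freqs, dtype=float)

    @property
    def n_individuals(self) -> int:
        return self.counts.shape[0]

    @property
    def n_snps(self) -> int:
        return self.counts.shape[1]


@dataclass
class GRM:
    """Symmetric genomic relationship matrix with provenance counts."""

    A: np.ndarray
    individual_ids: np.ndarray
    n_snps_used: int

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise ValueError("GRM must be square")
        if not np.allclose(self.A, self.A.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")

    @property
    def n(self) -> int:
        return self.A.shape[0]


def standardize_genotypes(
    counts: np.ndarray, freqs: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Center and scale allele counts to (x - 2p) / sqrt(2 p (1-p)).

    Missing genotypes are imputed to the per-SNP mean (i.e. zero after
    centering).  Returns the standardized matrix and a boolean mask of
    polymorphic SNPs (monomorphic columns cannot be standardized and are
    zeroed; callers decide whether to drop them).
    """
    counts = np.asarray(counts, dtype=float)
    if freqs is None:
        with np.errstate(invalid="ignore"):
            freqs = np.nanmean(counts, axis=0) / 2.0
    freqs = np.asarray(freqs, dtype=float)
    poly = (freqs > 0.0) & (freqs < 1.0)
    centered = counts - 2.0 * freqs
    centered[np.isnan(centered)] = 0.0  # mean imputation
    scale = np.ones_like(freqs)
    scale[poly] = np.sqrt(2.0 * freqs[poly] * (1.0 - freqs[poly]))
    W = centered / scale
    W[:, ~poly] = 0.0
    return W, poly


def compute_grm(genotypes: GenotypeMatrix, maf_min: float = 0.01) -> GRM:
    """Build the GRM from standardized genotypes after a MAF filter.

    SNPs with minor allele frequency below ``maf_min`` (or monomorphic)
    are excluded.  Raises ``ValueError`` when no SNP survives.
    """
    p = genotypes.allele_freqs
    maf = np.minimum(p, 1.0 - p)
    keep = maf >= maf_min
    W, poly = standardize_genotypes(genotypes.counts, p)
    keep &= poly
    M = int(keep.sum())
    if M == 0:
        raise ValueError("no SNPs survive the MAF filter; cannot build GRM")
    Wk = W[:, keep]
    A = (Wk @ Wk.T) / M
    A = (A + A.T) / 2.0
    return GRM(A=A, individual_ids=genotypes.individual_ids, n_snps_used=M)


def offdiag_variance(grm: GRM) -> float:
    """Population variance of the GRM's strictly-lower-triangle entries.

    This is the var(A_ij) that enters the closed-form null variance of
    the genetic-correlation estimate.
    """
    if grm.n < 2:
        raise ValueError("off-diagonal variance requires at least 2 individuals")
    off = grm.A[np.tril_indices(grm.n, k=-1)]
    return float(np.var(off))  # population (ddof=0) variance


def filter_unrelated(grm: GRM, threshold: float = 0.05) -> np.ndarray:
    """Greedily drop individuals until no pair exceeds the relatedness cutoff.

    Repeatedly removes the individual involved in the most violating
    pairs (A_jk > threshold); ties drop the larger index.  Returns the
    retained row indices into the GRM, in ascending order.
    """
    if threshold <= 0:
        raise ValueError("relatedness threshold must be positive")
    A = grm.A
    n = grm.n
    active = np.ones(n, dtype=bool)
    viol = (A > threshold) & ~np.eye(n, dtype=bool)
    while True:
        counts = (viol & active[None, :] & active[:, None]).sum(axis=1)
        counts[~active] = 0
        worst = counts.max() if n else 0
        if worst == 0:
            break
        # argmax returns the first maximum; we want the largest index on ties
        candidates = np.flatnonzero(counts == worst)
        active[candidates[-1]] = False
    return np.flatnonzero(active)


def write_gcta_grm(grm: GRM, prefix: str) -> None:
    """Write a GCTA-compatible binary GRM triple (grm.bin / grm.N.bin / grm.id).

    Lower-triangle (including diagonal), little-endian 4-byte floats, for
    interoperability with GREML tooling.  The per-pair SNP count is the
    single ``n_snps_used`` value replicated.
    """
    n = grm.n
    tril = [grm.A[i, j] for i in range(n) for j in range(i + 1)]
    with open(prefix + ".grm.bin", "wb") as fh:
        fh.write(struct.pack(f"<{len(tril)}f", *tril))
    with open(prefix + ".grm.N.bin", "wb") as fh:
        fh.write(struct.pack(f"<{len(tril)}f", *([float(grm.n_snps_used)] * len(tril))))
    with open(prefix + ".grm.id", "w") as fh:
        for iid in grm.individual_ids:
            fh.write(f"{iid}\t{iid}\n")
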
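"""Closed-form null model for r_G and multiple-testing procedures.

Under H0: r_G = 0 the sampling variance of the GREML genetic-correlation
estimate between two traits with mean heritabilities h2_i, h2_j on N
individuals is approximately

    var(r_G_hat | r_G = 0)  ~=  1 / (h2_i * h2_j * N^2 * var(A_ij)),

where var(A_ij) is the variance of the off-diagonal entries of the GRM
(Visscher's approximation).  Its square root sigma defines the 2/3/4
sigma exceedance thresholds used to call co-regulation network edges,
and the Gaussian tail mass gives the expected number of exceedances per
transcript.  Bonferroni and Benjamini-Hochberg corrections round out the
multiplicity toolbox.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "NullModel",
    "null_rg_variance",
    "sigma_threshold",
    "expected_exceedances",
    "bonferroni",
    "bh_fdr",
]

# two-sided Gaussian central masses as conventionally rounded; used by
# default so the printed expected-exceedance numbers are reproduced
CENTRAL_MASS_CONVENTIONAL = {2: 0.9545, 3: 0.9973}


def null_rg_variance(h2_i: float, h2_j: float, n: int, var_A: float) -> float:
    """Evaluate 1 / (h2_i * h2_j * N^2 * var(A_ij))."""
    for name, v in [("h2_i", h2_i), ("h2_j", h2_j), ("n", n), ("var_A", var_A)]:
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    return 1.0 / (h2_i * h2_j * float(n) ** 2 * var_A)


def sigma_threshold(var_rg_null: float, k: float) -> float:
    """k-sigma exceedance threshold on |r_G|: k * sqrt(var)."""
    if var_rg_null < 0:
        raise ValueError("variance must be non-negative")
    return k * math.sqrt(var_rg_null)


def expected_exceedances(
    m: int, k: int, conventional: bool = True
) -> tuple[float, int]:
    """Expected number of |r_G| exceedances beyond k sigma among m nulls.

    Returns (expectation, ceiling).  With ``conventional`` (default) the
    two-sided tail mass uses the textbook rounded central masses (0.9545
    at 2 sigma, 0.9973 at 3 sigma); otherwise, and for k values without
    a conventional constant, the exact Gaussian mass is used.
    """
    if m < 0:
        raise ValueError("m must be non-negative")
    if conventional and k in CENTRAL_MASS_CONVENTIONAL:
        tail = 1.0 - CENTRAL_MASS_CONVENTIONAL[k]
    else:
        tail = 2.0 * stats.norm.sf(k)
    expect = m * tail
    return expect, int(math.ceil(expect))


def bonferroni(alpha: float, n_tests: int) -> float:
    """Per-test threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    return alpha / n_tests


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up procedure.

    Returns (significant boolean mask, adjusted p-values) in the input
    order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


@dataclass
class NullModel:
    """Bundle of the null-variance inputs and derived thresholds."""

    h2_mean_i: float
    h2_mean_j: float
    n: int
    var_A_offdiag: float
    m: int  # comparisons per transcript

    @property
    def var_rg_null(self) -> float:
        return null_rg_variance(self.h2_mean_i, self.h2_mean_j, self.n, self.var_A_offdiag)

    @property
    def sigma(self) -> float:
        return math.sqrt(self.var_rg_null)

    def threshold(self, k: float) -> float:
        return sigma_threshold(self.var_rg_null, k)

    def expected_exceedances(self, k: int, conventional: bool = True) -> tuple[float, int]:
        return expected_exceedances(self.m, k, conventional=conventional)
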
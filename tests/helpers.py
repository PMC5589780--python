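"""Independent brute-force oracles used to validate the implementation.

Everything here is written from first principles (dense matrices,
double loops, enumeration) and deliberately shares no code with the
package's optimized paths.
"""

from __future__ import annotations

import math

import numpy as np


def dense_reml_loglik_uni(y, A, sigma2_g, sigma2_e):
    """Restricted log-likelihood of y = mu + g + e via dense matrices."""
    n = len(y)
    V = A * sigma2_g + np.eye(n) * sigma2_e
    X = np.ones((n, 1))
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    _, ldV = np.linalg.slogdet(V)
    _, ldX = np.linalg.slogdet(XtViX)
    return float(-0.5 * (ldV + ldX + r @ Vi @ r))


def dense_reml_loglik_biv(y_i, y_j, A, theta, include_residual_cov=True):
    """Restricted log-likelihood of the stacked bivariate model."""
    n = len(y_i)
    gi, gj, gc, ei, ej = theta[:5]
    ec = theta[5] if include_residual_cov else 0.0
    I = np.eye(n)
    V = np.block(
        [
            [A * gi + I * ei, A * gc + I * ec],
            [A * gc + I * ec, A * gj + I * ej],
        ]
    )
    X = np.zeros((2 * n, 2))
    X[:n, 0] = 1.0
    X[n:, 1] = 1.0
    y = np.concatenate([y_i, y_j])
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    _, ldV = np.linalg.slogdet(V)
    _, ldX = np.linalg.slogdet(XtViX)
    return float(-0.5 * (ldV + ldX + r @ Vi @ r))


def brute_force_grm(counts):
    """Per-pair double-loop GRM with per-SNP standardization."""
    counts = np.asarray(counts, dtype=float)
    n, m = counts.shape
    p = counts.mean(axis=0) / 2.0
    keep = (p > 0) & (p < 1)
    A = np.zeros((n, n))
    M = int(keep.sum())
    for j in range(n):
        for k in range(n):
            s = 0.0
            for i in range(m):
                if not keep[i]:
                    continue
                denom = 2.0 * p[i] * (1.0 - p[i])
                s += (counts[j, i] - 2 * p[i]) * (counts[k, i] - 2 * p[i]) / denom
            A[j, k] = s / M
    return A


def brute_force_bh(p_values, q):
    """Literal step-up definition of Benjamini-Hochberg."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= q * rank / n:
            k_max = rank
    sig = np.zeros(n, dtype=bool)
    sig[order[:k_max]] = True
    return sig


def brute_force_hypergeom_upper(M, K, N, k):
    """P(X >= k) by direct enumeration of the hypergeometric pmf."""
    total = 0.0
    for x in range(k, min(K, N) + 1):
        total += (
            math.comb(K, x) * math.comb(M - K, N - x) / math.comb(M, N)
        )
    return total


def brute_force_overlap(pairs, contacts, window):
    """All-pairs-vs-all-contacts double loop overlap count."""

    def dist(pos, start, end):
        if pos < start:
            return start - pos
        if pos > end:
            return pos - end
        return 0

    n_eval = 0
    n_overlap = 0
    for _, pr in pairs.iterrows():
        if pr["chrom_i"] == pr["chrom_j"] and abs(pr["pos_i"] - pr["pos_j"]) < window:
            continue
        n_eval += 1
        hit = False
        for _, ct in contacts.iterrows():
            d1i = pr["chrom_i"] == ct["chrom1"] and dist(pr["pos_i"], ct["start1"], ct["end1"]) <= window
            d2j = pr["chrom_j"] == ct["chrom2"] and dist(pr["pos_j"], ct["start2"], ct["end2"]) <= window
            d1j = pr["chrom_j"] == ct["chrom1"] and dist(pr["pos_j"], ct["start1"], ct["end1"]) <= window
            d2i = pr["chrom_i"] == ct["chrom2"] and dist(pr["pos_i"], ct["start2"], ct["end2"]) <= window
            if (d1i and d2j) or (d1j and d2i):
                hit = True
                break
        if hit:
            n_overlap += 1
    return n_eval, n_overlap
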
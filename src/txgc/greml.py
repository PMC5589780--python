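"""Restricted maximum likelihood for expression heritability and genetic correlation.

Model
-----
For a transcript pair (i, j) measured on the same n individuals,

    y_i = mu_i + g_i + e_i,      y_j = mu_j + g_j + e_j,

with g ~ N(0, sigma2_g * A) for the genomic relationship matrix A and
e ~ N(0, sigma2_e * I).  The stacked covariance is block structured:

    V = [ A s2_gi + I s2_ei     A s_gigj + I s_eij ]
        [ A s_gigj + I s_eij    A s2_gj + I s2_ej  ]

The residual covariance block (I * s_eij) is optional; with it off the
model is the literal two-independent-samples form.  The genetic
correlation is r_G = s_gigj / sqrt(s2_gi * s2_gj), constrained to
[-1, 1].

Implementation
--------------
One eigendecomposition A = U diag(d) U' is shared across all pair fits.
In the rotated basis V splits into n independent 2x2 blocks
S_k = d_k G + E (G and E the 2x2 genetic and residual covariance
matrices), so each REML likelihood, score and average-information (AI)
matrix evaluation is O(n).  Updates are AI-REML steps with projection
into the feasible region (variances >= floor, implied |correlations|
<= 1), step halving on likelihood decrease, and an EM-REML fallback
step.  Fixed effects are intercepts only; covariates are assumed
pre-regressed from the normalized expression values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from txgc.grm import GRM

__all__ = [
    "GRMEigen",
    "VarianceComponents",
    "BivariateFit",
    "RgEstimate",
    "reml_univariate",
    "reml_bivariate",
    "rg_from_components",
    "rg_se_taylor",
    "rg_test",
    "fit_pair",
]

MAX_ITER = 100
LOGL_TOL = 1e-4
VAR_FLOOR_FRAC = 1e-6
CORR_CLAMP = 1.0 - 1e-6


@dataclass
class GRMEigen:
    """Cached eigendecomposition of a GRM, shared across pair fits."""

    d: np.ndarray
    U: np.ndarray
    c: np.ndarray  # rotated intercept column U' 1

    @classmethod
    def from_grm(cls, grm: GRM | np.ndarray) -> "GRMEigen":
        A = grm.A if isinstance(grm, GRM) else np.asarray(grm, dtype=float)
        d, U = np.linalg.eigh(A)
        d = np.clip(d, 0.0, None)
        return cls(d=d, U=U, c=U.T @ np.ones(A.shape[0]))

    @property
    def n(self) -> int:
        return len(self.d)

    def transform(self, y: np.ndarray) -> np.ndarray:
        return self.U.T @ np.asarray(y, dtype=float)


def _as_eigen(grm: GRM | GRMEigen | np.ndarray) -> GRMEigen:
    return grm if isinstance(grm, GRMEigen) else GRMEigen.from_grm(grm)


def _ai_reml_loop(theta, loglik, evaluate, project, free_mask, n, max_iter, tol):
    """Generic AI-REML ascent with EM warmup, projection and EM fallback.

    ``free_mask(theta, score)`` marks parameters free to move; boundary
    parameters whose gradient points outward are pinned (active-set
    treatment), which keeps the AI step well-scaled when a variance sits
    at its floor or a correlation at its clamp.  Convergence is declared
    when the restricted log-likelihood changes by less than ``tol``.
    """
    ll, score, AI = evaluate(theta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        free = free_mask(theta, score)
        delta = np.zeros_like(theta)
        if it == 1:
            delta[free] = (2.0 * theta**2 * score / n)[free]  # EM-style warmup
        elif free.any():
            sub = AI[np.ix_(free, free)]
            try:
                delta[free] = np.linalg.solve(sub, score[free])
            except np.linalg.LinAlgError:
                delta[free] = score[free] / np.maximum(np.diag(sub), 1e-12)
        step, accepted = 1.0, False
        ll_new = ll
        for _ in range(15):
            cand = project(theta + step * delta)
            ll_new = loglik(cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                accepted = True
                break
            step /= 2.0
        if not accepted:
            # projected-gradient fallback: ascent under the projection
            # unless theta is a constrained stationary point
            t_grad = 1.0 / max(np.abs(np.diag(AI)).max(), 1e-12)
            for _ in range(40):
                cand = project(theta + t_grad * score)
                ll_new = loglik(cand)
                if np.isfinite(ll_new) and ll_new > ll:
                    accepted = True
                    break
                t_grad /= 2.0
        if not accepted:
            cand = project(theta + 2.0 * theta**2 * score / n)  # EM-REML fallback
            ll_new = loglik(cand)
            if not (np.isfinite(ll_new) and ll_new >= ll):
                converged = True  # constrained stationary point
                break
        dll = abs(ll_new - ll)
        theta, ll = cand, ll_new
        _, score, AI = evaluate(theta)
        if it > 1 and dll < tol:
            if step == 1.0:
                converged = True
                break
            # tiny change from a halved step: confirm stationarity with a
            # projected-gradient probe before declaring convergence
            t_grad = 1.0 / max(np.abs(np.diag(AI)).max(), 1e-12)
            probe_improved = False
            for _ in range(25):
                cand = project(theta + t_grad * score)
                ll_probe = loglik(cand)
                if np.isfinite(ll_probe) and ll_probe > ll + tol:
                    theta, ll = cand, ll_probe
                    _, score, AI = evaluate(theta)
                    probe_improved = True
                    break
                t_grad /= 2.0
            if not probe_improved:
                converged = True
                break
    return theta, ll, AI, converged, it


def _polish(theta, loglik, floor, include_ec, tol):
    """Quasi-Newton polish in a smooth unconstrained parameterization.

    Near the variance floor the AI curvature approximation degrades
    (the likelihood is extremely anisotropic there), so the AI loop can
    stall short of the optimum.  Re-maximizing over (log variances,
    atanh-scaled correlations) is smooth and bounded; the polished point
    is adopted only when it improves the restricted likelihood.
    Works for the bivariate (6 or 5 params) and univariate (2 params)
    layouts.
    """
    n_par = len(theta)

    if n_par == 2:  # univariate: (sigma2_g, sigma2_e)
        def unpack(u):
            return np.exp(u)

        u0 = np.log(np.maximum(theta, floor))
        bounds = [(np.log(floor), 10.0)] * 2
    else:
        include_ec = n_par == 6

        def unpack(u):
            gi, gj = np.exp(u[0]), np.exp(u[1])
            gc = np.tanh(u[2]) * CORR_CLAMP * np.sqrt(gi * gj)
            ei, ej = np.exp(u[3]), np.exp(u[4])
            out = [gi, gj, gc, ei, ej]
            if include_ec:
                out.append(np.tanh(u[5]) * CORR_CLAMP * np.sqrt(ei * ej))
            return np.array(out)

        def z_of(c, va, vb):
            r = np.clip(c / (CORR_CLAMP * np.sqrt(va * vb)), -1 + 1e-12, 1 - 1e-12)
            return np.arctanh(r)

        gi, gj, gc, ei, ej = theta[:5]
        u0 = [np.log(max(gi, floor)), np.log(max(gj, floor)), z_of(gc, max(gi, floor), max(gj, floor)),
              np.log(max(ei, floor)), np.log(max(ej, floor))]
        bounds = [(np.log(floor), 10.0)] * 2 + [(-20.0, 20.0)] + [(np.log(floor), 10.0)] * 2
        if include_ec:
            u0.append(z_of(theta[5], max(ei, floor), max(ej, floor)))
            bounds.append((-20.0, 20.0))
        u0 = np.array(u0)

    def neg(u):
        ll = loglik(unpack(u))
        return -ll if np.isfinite(ll) else 1e12

    res = optimize.minimize(neg, u0, method="L-BFGS-B", bounds=bounds)
    theta_new = unpack(res.x)
    return theta_new, -res.fun


@dataclass
class VarianceComponents:
    """Univariate REML fit: variances, heritability and diagnostics."""

    sigma2_g: float
    sigma2_e: float
    h2: float
    se_h2: float
    logL: float
    converged: bool
    n_iterations: int
    se_reliable: bool = True
    param_cov: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


@dataclass
class BivariateFit:
    """Bivariate REML fit: genetic/residual (co)variances and curvature."""

    sigma2_gi: float
    sigma2_gj: float
    sigma_gigj: float
    sigma2_ei: float
    sigma2_ej: float
    sigma_eij: float | None
    param_names: tuple[str, ...]
    param_cov: np.ndarray = field(repr=False)
    logL: float = 0.0
    converged: bool = False
    boundary_flag: bool = False
    n_iterations: int = 0
    var_floor: float = 0.0


@dataclass
class RgEstimate:
    """Genetic correlation for one transcript pair with its test."""

    probe_i: str
    probe_j: str
    r_G: float
    se_rG: float
    chi2: float
    p_value: float
    r_P: float
    interchromosomal: bool | None = None
    converged: bool = True
    boundary_flag: bool = False
    defined: bool = True


# ---------------------------------------------------------------------------
# univariate REML
# ---------------------------------------------------------------------------


def _uni_loglik(theta, d, c, z):
    sg, se = theta
    s = d * sg + se
    T = np.sum(c * c / s)
    beta = np.sum(c * z / s) / T
    r = z - c * beta
    quad = np.sum(r * r / s)
    return -0.5 * (np.sum(np.log(s)) + np.log(T) + quad)


def _uni_eval(theta, d, c, z):
    """Log-likelihood, score and AI matrix for (sigma2_g, sigma2_e)."""
    sg, se = theta
    s = d * sg + se
    inv = 1.0 / s
    T = np.sum(c * c * inv)
    beta = np.sum(c * z * inv) / T
    r = z - c * beta
    p = r * inv
    quad = np.sum(r * p)
    ll = -0.5 * (np.sum(np.log(s)) + np.log(T) + quad)

    # tr(P V_theta) with M_k = 1/s - c^2 / (s^2 T)
    m = inv - (c * c) * inv * inv / T
    derivs = (d, np.ones_like(d))
    score = np.empty(2)
    a_vecs = []
    for k, D in enumerate(derivs):
        tr = np.sum(m * D)
        qf = np.sum(p * p * D)
        score[k] = -0.5 * (tr - qf)
        a_vecs.append(D * p)

    def apply_P(v):
        gamma = np.sum(c * v * inv) / T
        return (v - c * gamma) * inv

    Pa = [apply_P(a) for a in a_vecs]
    AI = np.empty((2, 2))
    for k in range(2):
        for l in range(k, 2):
            AI[k, l] = AI[l, k] = 0.5 * np.dot(a_vecs[k], Pa[l])
    return ll, score, AI


def reml_univariate(
    y: np.ndarray,
    grm: GRM | GRMEigen,
    max_iter: int = MAX_ITER,
    tol: float = LOGL_TOL,
) -> VarianceComponents:
    """Fit y = mu + g + e with g ~ N(0, sigma2_g A) by AI-REML.

    Returns variance components, h2 = sigma2_g / (sigma2_g + sigma2_e)
    with a delta-method SE from the inverse AI matrix, and convergence
    diagnostics.  When the GRM carries almost no relatedness contrast
    (eigenvalues nearly constant) the direction separating the two
    components is unidentifiable; the fit still converges but SEs are
    flagged unreliable.
    """
    eig = _as_eigen(grm)
    y = np.asarray(y, dtype=float)
    if len(y) != eig.n:
        raise ValueError("phenotype length does not match GRM order")
    if eig.n < 10:
        raise ValueError("need at least 10 individuals")
    z = eig.transform(y)
    vy = float(np.var(y, ddof=1))
    floor = VAR_FLOOR_FRAC * vy
    theta = np.array([vy / 2.0, vy / 2.0])

    def project(t):
        return np.maximum(t, floor)

    def free_mask(t, score):
        at_floor = t <= floor * (1 + 1e-9)
        return ~(at_floor & (score < 0))

    theta, ll, AI, converged, it = _ai_reml_loop(
        theta,
        loglik=lambda t: _uni_loglik(t, eig.d, eig.c, z),
        evaluate=lambda t: _uni_eval(t, eig.d, eig.c, z),
        project=project,
        free_mask=free_mask,
        n=eig.n,
        max_iter=max_iter,
        tol=tol,
    )
    theta_p, ll_p = _polish(theta, lambda t: _uni_loglik(t, eig.d, eig.c, z), floor, False, tol)
    if ll_p > ll + tol / 10.0:
        theta, ll = project(theta_p), ll_p
        converged = True
        _, _, AI = _uni_eval(theta, eig.d, eig.c, z)
    sg, se = theta
    h2 = sg / (sg + se)
    se_reliable = True
    try:
        C = np.linalg.inv(AI)
        if not np.all(np.isfinite(C)) or np.linalg.cond(AI) > 1e10:
            se_reliable = False
    except np.linalg.LinAlgError:
        C = np.linalg.pinv(AI)
        se_reliable = False
    grad = np.array([se, -sg]) / (sg + se) ** 2
    var_h2 = float(grad @ C @ grad)
    se_h2 = float(np.sqrt(max(var_h2, 0.0)))
    if np.ptp(eig.d) < 1e-8:
        se_reliable = False
    return VarianceComponents(
        sigma2_g=float(sg),
        sigma2_e=float(se),
        h2=float(h2),
        se_h2=se_h2,
        logL=float(ll),
        converged=converged,
        n_iterations=it,
        se_reliable=se_reliable,
        param_cov=C,
    )


# ---------------------------------------------------------------------------
# bivariate REML
# ---------------------------------------------------------------------------


def _biv_params(theta, include_ec):
    if include_ec:
        gi, gj, gc, ei, ej, ec = theta
    else:
        gi, gj, gc, ei, ej = theta
        ec = 0.0
    return gi, gj, gc, ei, ej, ec


def _biv_blocks(theta, d, include_ec):
    gi, gj, gc, ei, ej, ec = _biv_params(theta, include_ec)
    S11 = d * gi + ei
    S22 = d * gj + ej
    S12 = d * gc + ec
    det = S11 * S22 - S12 * S12
    return S11, S22, S12, det


def _biv_core(theta, d, c, z1, z2, include_ec):
    """Shared quantities: block inverses, GLS intercepts, residual solves."""
    S11, S22, S12, det = _biv_blocks(theta, d, include_ec)
    I11 = S22 / det
    I22 = S11 / det
    I12 = -S12 / det
    cc = c * c
    T = np.array(
        [
            [np.sum(cc * I11), np.sum(cc * I12)],
            [np.sum(cc * I12), np.sum(cc * I22)],
        ]
    )
    u = np.array(
        [
            np.sum(c * (I11 * z1 + I12 * z2)),
            np.sum(c * (I12 * z1 + I22 * z2)),
        ]
    )
    beta = np.linalg.solve(T, u)
    r1 = z1 - c * beta[0]
    r2 = z2 - c * beta[1]
    p1 = I11 * r1 + I12 * r2
    p2 = I12 * r1 + I22 * r2
    quad = np.sum(r1 * p1) + np.sum(r2 * p2)
    sign_T, logdet_T = np.linalg.slogdet(T)
    ll = -0.5 * (np.sum(np.log(det)) + logdet_T + quad)
    return dict(
        I11=I11, I22=I22, I12=I12, T=T, p1=p1, p2=p2, ll=ll, det=det
    )


def _biv_loglik(theta, d, c, z1, z2, include_ec):
    return _biv_core(theta, d, c, z1, z2, include_ec)["ll"]


# derivative blocks dS_k/dtheta as (D11, D22, D12) coefficient triples
def _biv_deriv_triples(d, include_ec):
    one = np.ones_like(d)
    zero = np.zeros_like(d)
    triples = [
        (d, zero, zero),  # s2_gi
        (zero, d, zero),  # s2_gj
        (zero, zero, d),  # s_gigj
        (one, zero, zero),  # s2_ei
        (zero, one, zero),  # s2_ej
    ]
    if include_ec:
        triples.append((zero, zero, one))  # s_eij
    return triples


def _biv_eval(theta, d, c, z1, z2, include_ec):
    """Log-likelihood, score vector and AI matrix at theta."""
    core = _biv_core(theta, d, c, z1, z2, include_ec)
    I11, I22, I12 = core["I11"], core["I22"], core["I12"]
    p1, p2, T = core["p1"], core["p2"], core["T"]
    Tinv = np.linalg.inv(T)
    cc = c * c
    # M = S^-1 - c^2 S^-1 Tinv S^-1  (2x2 per eigenvalue, vectorized)
    K11 = I11 * I11 * Tinv[0, 0] + 2 * I11 * I12 * Tinv[0, 1] + I12 * I12 * Tinv[1, 1]
    K12 = (
        I11 * I12 * Tinv[0, 0]
        + (I11 * I22 + I12 * I12) * Tinv[0, 1]
        + I12 * I22 * Tinv[1, 1]
    )
    K22 = I12 * I12 * Tinv[0, 0] + 2 * I12 * I22 * Tinv[0, 1] + I22 * I22 * Tinv[1, 1]
    M11 = I11 - cc * K11
    M12 = I12 - cc * K12
    M22 = I22 - cc * K22

    triples = _biv_deriv_triples(d, include_ec)
    n_par = len(triples)
    score = np.empty(n_par)
    a_vecs = []
    for k, (D11, D22, D12) in enumerate(triples):
        tr = np.sum(M11 * D11 + M22 * D22 + 2.0 * M12 * D12)
        qf = np.sum(D11 * p1 * p1 + D22 * p2 * p2 + 2.0 * D12 * p1 * p2)
        score[k] = -0.5 * (tr - qf)
        a_vecs.append((D11 * p1 + D12 * p2, D12 * p1 + D22 * p2))

    def apply_P(v1, v2):
        g = Tinv @ np.array(
            [
                np.sum(c * (I11 * v1 + I12 * v2)),
                np.sum(c * (I12 * v1 + I22 * v2)),
            ]
        )
        w1 = v1 - c * g[0]
        w2 = v2 - c * g[1]
        return I11 * w1 + I12 * w2, I12 * w1 + I22 * w2

    Pa = [apply_P(*a) for a in a_vecs]
    AI = np.empty((n_par, n_par))
    for k in range(n_par):
        for l in range(k, n_par):
            AI[k, l] = AI[l, k] = 0.5 * (
                np.dot(a_vecs[k][0], Pa[l][0]) + np.dot(a_vecs[k][1], Pa[l][1])
            )
    return core["ll"], score, AI


def _biv_project(theta, include_ec, floor):
    gi, gj, gc, ei, ej, ec = _biv_params(theta, include_ec)
    gi, gj, ei, ej = (max(v, floor) for v in (gi, gj, ei, ej))
    gmax = CORR_CLAMP * np.sqrt(gi * gj)
    gc = float(np.clip(gc, -gmax, gmax))
    if include_ec:
        emax = CORR_CLAMP * np.sqrt(ei * ej)
        ec = float(np.clip(ec, -emax, emax))
        return np.array([gi, gj, gc, ei, ej, ec])
    return np.array([gi, gj, gc, ei, ej])


def reml_bivariate(
    y_i: np.ndarray,
    y_j: np.ndarray,
    grm: GRM | GRMEigen,
    include_residual_cov: bool = True,
    max_iter: int = MAX_ITER,
    tol: float = LOGL_TOL,
) -> BivariateFit:
    """Bivariate AI-REML fit of the block covariance model.

    Non-convergence within ``max_iter`` iterations is returned as a
    flagged result, never raised.  ``include_residual_cov`` toggles the
    I*sigma_eij block; the default keeps it, since both traits are
    measured on the same individuals.
    """
    eig = _as_eigen(grm)
    y_i = np.asarray(y_i, dtype=float)
    y_j = np.asarray(y_j, dtype=float)
    if len(y_i) != eig.n or len(y_j) != eig.n:
        raise ValueError("phenotype length does not match GRM order")
    z1, z2 = eig.transform(y_i), eig.transform(y_j)
    v1 = float(np.var(y_i, ddof=1))
    v2 = float(np.var(y_j, ddof=1))
    c12 = float(np.cov(y_i, y_j, ddof=1)[0, 1])
    floor = VAR_FLOOR_FRAC * max(v1, v2)
    include_ec = include_residual_cov
    if include_ec:
        theta = np.array([v1 / 2, v2 / 2, c12 / 2, v1 / 2, v2 / 2, c12 / 2])
    else:
        theta = np.array([v1 / 2, v2 / 2, c12 / 2, v1 / 2, v2 / 2])
    theta = _biv_project(theta, include_ec, floor)
    args = (eig.d, eig.c, z1, z2, include_ec)

    def free_mask(t, score):
        gi, gj, gc, ei, ej, ec = _biv_params(t, include_ec)
        free = np.ones(len(t), dtype=bool)
        for k, v in zip((0, 1, 3, 4), (gi, gj, ei, ej)):
            if v <= floor * (1 + 1e-9) and score[k] < 0:
                free[k] = False
        if abs(gc) >= CORR_CLAMP * np.sqrt(gi * gj) * (1 - 1e-12) and score[2] * gc > 0:
            free[2] = False
        if include_ec and abs(ec) >= CORR_CLAMP * np.sqrt(ei * ej) * (1 - 1e-12) and score[5] * ec > 0:
            free[5] = False
        return free

    theta, ll, AI, converged, it = _ai_reml_loop(
        theta,
        loglik=lambda t: _biv_loglik(t, *args),
        evaluate=lambda t: _biv_eval(t, *args),
        project=lambda t: _biv_project(t, include_ec, floor),
        free_mask=free_mask,
        n=eig.n,
        max_iter=max_iter,
        tol=tol,
    )
    theta_p, ll_p = _polish(theta, lambda t: _biv_loglik(t, *args), floor, include_ec, tol)
    if ll_p > ll + tol / 10.0:
        theta, ll = _biv_project(theta_p, include_ec, floor), ll_p
        converged = True
        _, _, AI = _biv_eval(theta, *args)

    try:
        C = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        C = np.linalg.pinv(AI)
    C = (C + C.T) / 2.0
    gi, gj, gc, ei, ej, ec = _biv_params(theta, include_ec)
    at_floor = min(gi, gj, ei, ej) <= floor * (1 + 1e-9)
    g_corr = abs(gc) / np.sqrt(gi * gj)
    e_corr = abs(ec) / np.sqrt(ei * ej) if include_ec else 0.0
    boundary = bool(at_floor or g_corr >= CORR_CLAMP - 1e-9 or e_corr >= CORR_CLAMP - 1e-9)
    names = ("sigma2_gi", "sigma2_gj", "sigma_gigj", "sigma2_ei", "sigma2_ej")
    if include_ec:
        names = names + ("sigma_eij",)
    return BivariateFit(
        sigma2_gi=float(gi),
        sigma2_gj=float(gj),
        sigma_gigj=float(gc),
        sigma2_ei=float(ei),
        sigma2_ej=float(ej),
        sigma_eij=float(ec) if include_ec else None,
        param_names=names,
        param_cov=C,
        logL=float(ll),
        converged=converged,
        boundary_flag=boundary,
        n_iterations=it,
        var_floor=floor,
    )


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------


def rg_from_components(fit: BivariateFit, probe_i: str = "i", probe_j: str = "j") -> RgEstimate:
    """Genetic correlation r_G = cov / sqrt(var_i var_j), clamped to [-1, 1].

    When either genetic variance sits at its floor the ratio is
    undefined and the estimate is flagged (r_G = NaN, ``defined`` False).
    """
    gi, gj, gc = fit.sigma2_gi, fit.sigma2_gj, fit.sigma_gigj
    tol = fit.var_floor * (1 + 1e-9) if fit.var_floor > 0 else 0.0
    if gi <= tol or gj <= tol or gi <= 0 or gj <= 0:
        return RgEstimate(
            probe_i=probe_i,
            probe_j=probe_j,
            r_G=float("nan"),
            se_rG=float("nan"),
            chi2=float("nan"),
            p_value=float("nan"),
            r_P=float("nan"),
            converged=fit.converged,
            boundary_flag=True,
            defined=False,
        )
    r = gc / np.sqrt(gi * gj)
    boundary = fit.boundary_flag
    if abs(r) > 1.0:
        r = float(np.clip(r, -1.0, 1.0))
        boundary = True
    return RgEstimate(
        probe_i=probe_i,
        probe_j=probe_j,
        r_G=float(r),
        se_rG=float("nan"),
        chi2=float("nan"),
        p_value=float("nan"),
        r_P=float("nan"),
        converged=fit.converged,
        boundary_flag=boundary,
    )


def rg_se_taylor(fit: BivariateFit) -> float:
    """First-order delta-method SE of r_G.

    Propagates the 3x3 covariance of (sigma_gigj, sigma2_gi, sigma2_gj)
    from the inverse AI matrix through the gradient of
    r_G = s_c / sqrt(s_i s_j).  At a boundary solution the curvature is
    one-sided and the value should be treated as unreliable.
    """
    gi, gj, gc = fit.sigma2_gi, fit.sigma2_gj, fit.sigma_gigj
    if gi <= 0 or gj <= 0:
        raise ValueError("Taylor SE undefined when a genetic variance is non-positive")
    idx = [fit.param_names.index(k) for k in ("sigma_gigj", "sigma2_gi", "sigma2_gj")]
    C = fit.param_cov[np.ix_(idx, idx)]
    r = gc / np.sqrt(gi * gj)
    grad = np.array([1.0 / np.sqrt(gi * gj), -r / (2.0 * gi), -r / (2.0 * gj)])
    var = float(grad @ C @ grad)
    return float(np.sqrt(max(var, 0.0)))


def rg_test(r_G: float, se_rG: float) -> tuple[float, float]:
    """Wald test of H0: r_G = 0 against chi-square with 1 df.

    chi2 = (r_G / SE)^2; the p-value is the upper tail.
    """
    if se_rG < 0:
        raise ValueError("SE must be non-negative")
    if se_rG == 0:
        if r_G == 0:
            return 0.0, 1.0
        raise ValueError("zero SE with nonzero r_G: test undefined")
    chi2 = (r_G / se_rG) ** 2
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def fit_pair(
    y_i: np.ndarray,
    y_j: np.ndarray,
    grm: GRM | GRMEigen,
    probe_i: str = "i",
    probe_j: str = "j",
    include_residual_cov: bool = True,
    interchromosomal: bool | None = None,
) -> RgEstimate:
    """Full per-pair workflow: bivariate fit, r_G, Taylor SE and Wald test."""
    fit = reml_bivariate(y_i, y_j, grm, include_residual_cov=include_residual_cov)
    est = rg_from_components(fit, probe_i=probe_i, probe_j=probe_j)
    est.r_P = float(np.corrcoef(y_i, y_j)[0, 1])
    est.interchromosomal = interchromosomal
    if est.defined:
        est.se_rG = rg_se_taylor(fit)
        if est.se_rG > 0:
            est.chi2, est.p_value = rg_test(est.r_G, est.se_rG)
        elif est.r_G == 0:
            est.chi2, est.p_value = 0.0, 1.0
    return est
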
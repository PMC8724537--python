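"""Mixed-model analysis of the replicated growth trait.

The trait (stem diameter, cm) is modelled as

    y = mu + block + replicate + water + month + g + gw + e

with fixed design factors, a random genotype effect g ~ N(0, sigma_g2 I), a
random genotype-by-water interaction gw ~ N(0, sigma_gw2 I) and residual
e ~ N(0, sigma_e2 I).  Variance components are estimated by REML on
Henderson's mixed-model equations: EM steps (monotone, safe near the
boundary) refined by average-information (AI) Newton steps for fast
convergence; BLUPs of g and gw are read off the converged equations.

Identities used (X: n x p fixed design, Z: n x q random design, D the
random-effect covariance, lambda_k = sigma_e2/sigma_k2, M the MME
coefficient matrix, T = M^-1):

    log|V|          = (n - q) log sigma_e2 + sum_k q_k log sigma_k2
                      + log|Z'Z + Lambda|
    log|X'V^-1 X|   = log|M| - log|Z'Z + Lambda| - p log sigma_e2
    y'Py            = (y'y - beta'X'y - u'Z'y) / sigma_e2
    EM update       : sigma_k2 <- (u_k'u_k + sigma_e2 tr(T_kk)) / q_k
    tr(P Z_k Z_k')  = (q_k - lambda_k tr(T_kk)) / sigma_k2
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
from scipy.stats import chi2

from ._core import VarianceComponents

__all__ = ["fit_mixed_model", "lrt_random_effect", "heritability"]

_FIXED_FACTORS = ("block", "replicate", "water", "month")
_LOG2PI = float(np.log(2.0 * np.pi))


def _design_matrices(table: pd.DataFrame, include_gw: bool):
    """Build X (fixed), Z blocks (random) and level labels from the table."""
    n = len(table)
    X_cols = [np.ones(n)]
    names = ["(Intercept)"]
    for factor in _FIXED_FACTORS:
        levels = sorted(table[factor].astype(str).unique())
        if len(levels) == 1:
            warnings.warn(f"fixed factor '{factor}' has one level; dropped", stacklevel=3)
            continue
        codes = pd.Categorical(table[factor].astype(str), categories=levels).codes
        for li in range(1, len(levels)):
            X_cols.append((codes == li).astype(float))
            names.append(f"{factor}[{levels[li]}]")
    X = np.column_stack(X_cols)

    # rank check with aliased-column identification
    q_, r_ = np.linalg.qr(X)
    diag = np.abs(np.diag(r_))
    bad = diag < 1e-8 * diag.max()
    if bad.any():
        aliased = [names[i] for i in np.flatnonzero(bad)]
        raise ValueError(f"singular fixed-effect design; aliased columns: {aliased}")

    geno = table["genotype"].astype(str)
    g_levels = sorted(geno.unique())
    g_codes = pd.Categorical(geno, categories=g_levels).codes
    Zg = sp.csr_matrix(
        (np.ones(n), (np.arange(n), g_codes)), shape=(n, len(g_levels))
    )
    blocks = [("g", Zg, g_levels)]
    if include_gw:
        gw = geno + "::" + table["water"].astype(str)
        gw_levels = sorted(gw.unique())
        gw_codes = pd.Categorical(gw, categories=gw_levels).codes
        Zgw = sp.csr_matrix(
            (np.ones(n), (np.arange(n), gw_codes)), shape=(n, len(gw_levels))
        )
        blocks.append(("gw", Zgw, gw_levels))
    return X, names, blocks


class _MME:
    """Precomputed cross-products for the mixed-model equations."""

    def __init__(self, y, X, blocks):
        self.y = y
        self.X = X
        self.n, self.p = X.shape
        self.Z = sp.hstack([Z for _, Z, _ in blocks], format="csr")
        self.q_sizes = [Z.shape[1] for _, Z, _ in blocks]
        self.q = sum(self.q_sizes)
        self.XtX = X.T @ X
        self.XtZ = X.T @ self.Z
        self.ZtZ = (self.Z.T @ self.Z).toarray()
        self.Xty = X.T @ y
        self.Zty = self.Z.T @ y
        self.yty = float(y @ y)
        self.block_slices = []
        start = self.p
        for qk in self.q_sizes:
            self.block_slices.append(slice(start, start + qk))
            start += qk

    def assemble(self, sigmas, sigma_e2):
        lam = [sigma_e2 / s for s in sigmas]
        M = np.zeros((self.p + self.q, self.p + self.q))
        M[: self.p, : self.p] = self.XtX
        M[: self.p, self.p :] = self.XtZ
        M[self.p :, : self.p] = self.XtZ.T
        M[self.p :, self.p :] = self.ZtZ
        start = 0
        for lk, qk in zip(lam, self.q_sizes):
            idx = np.arange(self.p + start, self.p + start + qk)
            M[idx, idx] += lk
            start += qk
        return M, lam

    def loglik(self, sigmas, sigma_e2, M, sol, rhs):
        n, p, q = self.n, self.p, self.q
        # log|Z'Z + Lambda| via Cholesky of the random-effect block of M
        # (that block IS Z'Z + Lambda)
        ZZL = M[p:, p:]
        cf1 = sla.cho_factor(ZZL, lower=True, check_finite=False)
        logdet_ZZL = 2.0 * np.sum(np.log(np.diag(cf1[0])))
        cfM = sla.cho_factor(M, lower=True, check_finite=False)
        logdet_M = 2.0 * np.sum(np.log(np.diag(cfM[0])))
        yPy = (self.yty - float(sol @ rhs)) / sigma_e2
        logdet_V = (
            (n - q) * np.log(sigma_e2)
            + sum(qk * np.log(s) for qk, s in zip(self.q_sizes, sigmas))
            + logdet_ZZL
        )
        logdet_XVX = logdet_M - logdet_ZZL - p * np.log(sigma_e2)
        return -0.5 * ((n - p) * _LOG2PI + logdet_V + logdet_XVX + yPy)


def fit_mixed_model(
    table: pd.DataFrame,
    include_gw: bool = True,
    max_iter: int = 500,
    tol: float = 1e-8,
    n_em_start: int = 3,
) -> VarianceComponents:
    """REML fit of the growth-trait mixed model.

    Parameters
    ----------
    table
        Phenotype records with columns sample, genotype, block, replicate,
        water, month, value.
    include_gw
        Fit the genotype-by-water interaction component (drop it for the
        reduced model of a likelihood-ratio test).

    Returns the variance components, REML log-likelihood and BLUPs; a
    non-converged fit is returned flagged (``converged=False``), never
    silently.
    """
    if table["genotype"].nunique() < 2:
        raise ValueError("need >= 2 genotypes")
    if not np.all(np.isfinite(table["value"].to_numpy(dtype=float))):
        raise ValueError("non-finite trait values")
    dup = table.duplicated(subset=["sample", "month"])
    if dup.any():
        raise ValueError("duplicated (sample, month) records")

    y = table["value"].to_numpy(dtype=float)
    X, names, blocks = _design_matrices(table, include_gw)
    mme = _MME(y, X, blocks)
    n, p = mme.n, mme.p

    vary = float(np.var(y)) or 1.0
    floor = 1e-10 * vary
    k = len(blocks)
    sigmas = [vary / (k + 1)] * k
    sigma_e2 = vary / (k + 1)

    ll_old = -np.inf
    ll_trace: list[float] = []
    converged = False
    it = 0
    sol = None
    for it in range(1, max_iter + 1):
        M, lam = mme.assemble(sigmas, sigma_e2)
        rhs = np.concatenate([mme.Xty, np.asarray(mme.Zty).ravel()])
        cfM = sla.cho_factor(M, lower=True, check_finite=False)
        sol = sla.cho_solve(cfM, rhs, check_finite=False)
        ll = mme.loglik(sigmas, sigma_e2, M, sol, rhs)
        ll_trace.append(float(ll))

        # block traces of T = M^-1 (dpotri on the Cholesky factor)
        Tinv, info = sla.lapack.dpotri(cfM[0], lower=True)
        if info != 0:
            raise RuntimeError("MME inversion failed")
        tr_T = [float(np.trace(Tinv[bs, bs])) for bs in mme.block_slices]
        u_blocks = [sol[bs] for bs in mme.block_slices]
        beta = sol[:p]

        # EM proposals (monotone in the REML objective)
        em_sigmas = [
            max(floor, (float(u @ u) + sigma_e2 * tr) / qk)
            for u, tr, qk in zip(u_blocks, tr_T, mme.q_sizes)
        ]
        em_e2 = max(
            floor,
            (mme.yty - float(beta @ mme.Xty) - float(sol[p:] @ np.asarray(mme.Zty).ravel()))
            / (n - p),
        )

        proposal = None
        if it > n_em_start:
            proposal = _ai_step(
                mme, sigmas, sigma_e2, lam, tr_T, u_blocks, sol, cfM, floor
            )
        new = proposal if proposal is not None else (em_sigmas, em_e2)

        # accept AI step only if it does not break the likelihood; else EM
        if proposal is not None:
            M2, _ = mme.assemble(new[0], new[1])
            try:
                cf2 = sla.cho_factor(M2, lower=True, check_finite=False)
                sol2 = sla.cho_solve(cf2, rhs, check_finite=False)
                ll2 = mme.loglik(new[0], new[1], M2, sol2, rhs)
                if not np.isfinite(ll2) or ll2 < ll - 1e-6:
                    new = (em_sigmas, em_e2)
            except np.linalg.LinAlgError:
                new = (em_sigmas, em_e2)

        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
        sigmas, sigma_e2 = new
    else:
        warnings.warn("REML did not converge within max_iter", stacklevel=2)

    # final solve at converged components for BLUPs and log-likelihood
    M, lam = mme.assemble(sigmas, sigma_e2)
    rhs = np.concatenate([mme.Xty, np.asarray(mme.Zty).ravel()])
    cfM = sla.cho_factor(M, lower=True, check_finite=False)
    sol = sla.cho_solve(cfM, rhs, check_finite=False)
    ll = mme.loglik(sigmas, sigma_e2, M, sol, rhs)

    g_levels = blocks[0][2]
    g_blups = dict(zip(g_levels, sol[mme.block_slices[0]]))
    gw_blups: dict[tuple[str, str], float] = {}
    if include_gw:
        for lev, val in zip(blocks[1][2], sol[mme.block_slices[1]]):
            g_id, w = lev.split("::")
            gw_blups[(g_id, w)] = float(val)

    fixed = dict(zip(names, sol[:p]))
    return VarianceComponents(
        sigma_g2=float(sigmas[0]),
        sigma_gw2=float(sigmas[1]) if include_gw else 0.0,
        sigma_e2=float(sigma_e2),
        mu=float(fixed["(Intercept)"]),
        blups={g: float(v) for g, v in g_blups.items()},
        gw_blups=gw_blups,
        loglik=float(ll),
        converged=converged,
        fixed_effects={k_: float(v) for k_, v in fixed.items()},
        n_iter=it,
        ll_trace=ll_trace,
    )


def _ai_step(mme, sigmas, sigma_e2, lam, tr_T, u_blocks, sol, cfM, floor):
    """One average-information Newton step; None if it cannot be formed."""
    n, p = mme.n, mme.p
    beta = sol[:p]
    u_all = sol[p:]
    resid = mme.y - mme.X @ beta - mme.Z @ u_all
    Py = resid / sigma_e2

    # working vectors f_k = d V/d sigma_k2 @ Py
    fs = []
    for (bs, u, s) in zip(mme.block_slices, u_blocks, sigmas):
        Zk = mme.Z[:, bs.start - p : bs.stop - p]
        fs.append(Zk @ (u / s))
    fs.append(Py)

    def P_apply(f):
        rhs_f = np.concatenate([mme.X.T @ f, np.asarray(mme.Z.T @ f).ravel()])
        sol_f = sla.cho_solve(cfM, rhs_f, check_finite=False)
        return (f - mme.X @ sol_f[:p] - mme.Z @ sol_f[p:]) / sigma_e2

    Pf = [P_apply(f) for f in fs]
    k = len(fs)
    AI = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            AI[i, j] = AI[j, i] = 0.5 * float(fs[i] @ Pf[j])

    # scores
    tr_PZZ = [
        (qk - lk * tr) / s
        for qk, lk, tr, s in zip(mme.q_sizes, lam, tr_T, sigmas)
    ]
    scores = []
    for u, s, tr in zip(u_blocks, sigmas, tr_PZZ):
        scores.append(-0.5 * (tr - float(u @ u) / s**2))
    tr_P = (n - p - sum(s * t for s, t in zip(sigmas, tr_PZZ))) / sigma_e2
    scores.append(-0.5 * (tr_P - float(Py @ Py)))
    scores = np.asarray(scores)

    try:
        delta = np.linalg.solve(AI, scores)
    except np.linalg.LinAlgError:
        return None
    theta = np.array(list(sigmas) + [sigma_e2])
    new = theta + delta
    # step-halve into the feasible region
    for _ in range(20):
        if np.all(new > 0):
            break
        delta *= 0.5
        new = theta + delta
    else:
        return None
    new = np.maximum(new, floor)
    return list(new[:-1]), float(new[-1])


def lrt_random_effect(full: VarianceComponents, reduced: VarianceComponents, df: int = 1):
    """Likelihood-ratio test of a variance component on the boundary.

    The null distribution is the 50:50 mixture of chi2(df-1) and chi2(df)
    (chi2(0) is a point mass at zero), appropriate for testing one variance
    component against zero.  Returns (statistic, p).
    """
    stat = 2.0 * (full.loglik - reduced.loglik)
    if stat < -1e-4:  # beyond boundary-convergence noise of the solver
        raise ValueError(
            "full model log-likelihood below reduced model: non-nested or failed fit"
        )
    stat = max(0.0, stat)
    if stat == 0.0:
        return 0.0, 1.0
    lower = chi2.sf(stat, df - 1) if df > 1 else 0.0
    p = 0.5 * (lower + chi2.sf(stat, df))
    return float(stat), float(p)


def heritability(v: VarianceComponents, s: int, a: int) -> float:
    """Broad-sense heritability on a genotype-mean basis.

    H2 = sigma_g2 / (sigma_g2 + sigma_gw2/s + sigma_e2/a) with s the number
    of environments (water levels) and a the number of blocks.
    """
    if s < 1 or a < 1:
        raise ValueError("s and a must be >= 1")
    denom = v.sigma_g2 + v.sigma_gw2 / s + v.sigma_e2 / a
    if denom <= 0:
        raise ValueError("zero total variance")
    return float(v.sigma_g2 / denom)
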
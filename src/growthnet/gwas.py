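"""FarmCPU-style association scan and LD-based signal expansion.

The scan alternates a fixed-effect step (per-marker OLS of the BLUP
phenotype on intercept, principal components and the current pseudo-QTNs,
t-test on the marker coefficient) with a random-effect step that re-selects
pseudo-QTNs: candidate markers are binned along the genome, the best marker
per bin is taken, and the bin size / pseudo-QTN count combination is chosen
by the REML likelihood of a one-component mixed model on the pseudo-QTN
kinship.  Iteration stops when the pseudo-QTN set is stable.

The genome-wide significance threshold is empirical: the phenotype is
permuted (covariates fixed), the genome-wide minimum p of a single
fixed-effect scan is recorded per permutation, and the threshold is the
(1 - quantile) type-7 quantile of those minima (30 permutations, 95%
quantile by default).
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import t as t_dist

from ._core import AssociationResult, GenotypeMatrix, MarkerSets
from .genotype import ld_r2_matrix

__all__ = [
    "farmcpu_scan",
    "permutation_threshold",
    "threshold_from_minima",
    "snp_statistics",
    "additive_variance",
    "expand_ld_set",
    "build_ld_network",
]

#: genome bin sizes (bp) and pseudo-QTN counts searched in the random-effect step
BIN_SIZE_GRID = (500_000, 5_000_000, 50_000_000)
QTN_COUNT_GRID = (5, 10, 15)

#: p-value gate for a marker to become a pseudo-QTN candidate (Bonferroni-type)
_QTN_GATE_ALPHA = 0.01


def _ols_scan(y: np.ndarray, D: np.ndarray, C: np.ndarray):
    """Per-marker OLS p-values/effects with covariates projected out.

    Frisch-Waugh: residualise y and every dosage column on C, then the
    simple-regression slope and its t-test (df = n - cols(C) - 1) equal the
    marker terms of the full multiple regression.  Markers collinear with C
    (or monomorphic) get p = 1, effect 0.
    """
    n = len(y)
    Q, _ = np.linalg.qr(C)
    My = y - Q @ (Q.T @ y)
    MD = D - Q @ (Q.T @ D)
    sxx = np.einsum("ij,ij->j", MD, MD)
    sxy = MD.T @ My
    syy = float(My @ My)
    df = n - C.shape[1] - 1
    if df <= 0:
        raise ValueError("more covariates than samples")
    ok = sxx > 1e-10 * n
    slope = np.zeros(D.shape[1])
    pvals = np.ones(D.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        b = np.where(ok, sxy / np.where(ok, sxx, 1.0), 0.0)
        sse = syy - b * sxy
        sse = np.maximum(sse, 0.0)
        se = np.sqrt(sse / df / np.where(ok, sxx, 1.0))
        tstat = np.where(se > 0, b / np.where(se > 0, se, 1.0), np.inf)
    p = 2.0 * t_dist.sf(np.abs(tstat), df)
    slope[ok] = b[ok]
    pvals[ok] = np.clip(p[ok], np.finfo(float).tiny, 1.0)
    return pvals, slope


def _kinship_reml_ll(y: np.ndarray, K: np.ndarray) -> float:
    """REML log-likelihood of y = mu + u, u ~ N(0, s2g K), e ~ N(0, s2e I).

    Profiled over the variance scale via the eigendecomposition of K; the
    variance ratio is optimised numerically (FaST-LMM-style).
    """
    n = len(y)
    S, U = np.linalg.eigh(K)
    S = np.maximum(S, 0.0)
    yt = U.T @ y
    xt = U.T @ np.ones(n)

    def neg_ll(log_delta):
        d = S + np.exp(log_delta)
        xvx = float(np.sum(xt * xt / d))
        xvy = float(np.sum(xt * yt / d))
        beta = xvy / xvx
        r2 = yt - beta * xt
        ypy = float(np.sum(r2 * r2 / d))
        s2 = ypy / (n - 1)
        ll = -0.5 * (
            (n - 1) * np.log(2 * np.pi * s2)
            + np.sum(np.log(d))
            + np.log(xvx)
            + (n - 1)
        )
        return -ll

    res = minimize_scalar(neg_ll, bounds=(-10.0, 10.0), method="bounded")
    return -float(res.fun)


def _select_pseudo_qtns(
    G: GenotypeMatrix, y: np.ndarray, pvals: np.ndarray
) -> list[int]:
    """Random-effect step: bin the genome, keep the best marker per bin and
    choose (bin size, count) by the pseudo-QTN kinship REML likelihood."""
    m = G.n_markers
    gate = _QTN_GATE_ALPHA / m
    cand = np.flatnonzero(pvals < gate)
    if cand.size == 0:
        return []
    chroms = G.markers["chrom"].to_numpy()
    pos = G.markers["pos"].to_numpy()
    best_combo: tuple[float, list[int]] | None = None
    for bin_size in BIN_SIZE_GRID:
        bins: dict[tuple[str, int], int] = {}
        for j in cand:
            key = (chroms[j], int(pos[j]) // bin_size)
            if key not in bins or pvals[j] < pvals[bins[key]]:
                bins[key] = j
        per_bin = sorted(bins.values(), key=lambda j: pvals[j])
        for n_qtn in QTN_COUNT_GRID:
            chosen = _drop_collinear(G, per_bin[:n_qtn])
            if not chosen:
                continue
            Dq = G.dosage[:, chosen]
            pq = Dq.mean(axis=0) / 2.0
            Z = Dq - 2.0 * pq
            denom = 2.0 * np.sum(pq * (1.0 - pq))
            K = Z @ Z.T / (denom if denom > 0 else 1.0)
            ll = _kinship_reml_ll(y, K)
            if best_combo is None or ll > best_combo[0]:
                best_combo = (ll, chosen)
    return best_combo[1] if best_combo else []


def _drop_collinear(G: GenotypeMatrix, idx: list[int], r_max: float = 0.99) -> list[int]:
    """Drop later-entering markers nearly collinear with earlier ones."""
    kept: list[int] = []
    for j in idx:
        col = G.dosage[:, j]
        if col.std() == 0:
            continue
        redundant = False
        for k in kept:
            r = np.corrcoef(col, G.dosage[:, k])[0, 1]
            if abs(r) > r_max:
                redundant = True
                break
        if not redundant:
            kept.append(j)
    return kept


def _align(G: GenotypeMatrix, blups: pd.Series, covariates: pd.DataFrame | None):
    """Align phenotype and covariates to the panel's sample order."""
    missing = set(G.samples) - set(blups.index)
    if missing:
        raise ValueError(f"BLUPs missing for samples: {sorted(missing)[:5]}")
    y = blups.loc[G.samples].to_numpy(dtype=float)
    if covariates is None:
        C = np.ones((len(y), 1))
        cov_names = ["(Intercept)"]
    else:
        C = np.column_stack(
            [np.ones(len(y)), covariates.loc[G.samples].to_numpy(dtype=float)]
        )
        cov_names = ["(Intercept)"] + list(covariates.columns)
    return y, C, cov_names


def farmcpu_scan(
    G: GenotypeMatrix,
    blups: pd.Series,
    covariates: pd.DataFrame | None = None,
    kinship: pd.DataFrame | None = None,
    max_iter: int = 10,
) -> AssociationResult:
    """Iterative fixed/random-effect association scan.

    ``blups`` maps sample id to the BLUP phenotype; ``covariates`` holds the
    principal-component scores (kinship enters only through the pseudo-QTN
    selection step, mirroring the method's design).  Monomorphic markers are
    excluded (p = 1) with a warning.
    """
    if np.isnan(G.dosage).any():
        raise ValueError("scan requires an imputed genotype matrix")
    y, C, cov_names = _align(G, blups, covariates)

    mono = G.dosage.std(axis=0) == 0
    if mono.any():
        warnings.warn(f"{int(mono.sum())} monomorphic markers excluded", stacklevel=2)

    qtns: list[int] = []
    pvals, slopes = _ols_scan(y, G.dosage, C)
    n_it = 1
    for n_it in range(2, max_iter + 2):
        new_qtns = _select_pseudo_qtns(G, y, pvals)
        if sorted(new_qtns) == sorted(qtns):
            break
        qtns = new_qtns
        Cq = np.column_stack([C, G.dosage[:, qtns]]) if qtns else C
        if Cq.shape[1] >= len(y):
            raise ValueError("more covariates + pseudo-QTNs than samples")
        pvals, slopes = _ols_scan(y, G.dosage, Cq)

    # pseudo-QTNs are tested as covariates of the joint model, not against
    # themselves (self-collinear markers keep p = 1)
    if qtns:
        Cq = np.column_stack([C, G.dosage[:, qtns]])
        pq, bq = _joint_ttest(y, Cq, first=C.shape[1])
        for j, pj, bj in zip(qtns, pq, bq):
            pvals[j] = pj
            slopes[j] = bj

    maf = G.maf()
    table = pd.DataFrame(
        {
            "chrom": G.markers["chrom"].to_numpy(),
            "pos": G.markers["pos"].to_numpy(),
            "p": pvals,
            "effect": slopes,
            "maf": maf,
        },
        index=G.markers.index,
    )
    return AssociationResult(
        table=table,
        covariates=cov_names,
        pseudo_qtns=[G.marker_ids[j] for j in qtns],
        n_iterations=n_it,
    )


def _joint_ttest(y: np.ndarray, Xfull: np.ndarray, first: int):
    """t-tests on the trailing columns of a joint OLS fit."""
    n, k = Xfull.shape
    beta, _, rank, _ = np.linalg.lstsq(Xfull, y, rcond=None)
    resid = y - Xfull @ beta
    df = n - rank
    s2 = float(resid @ resid) / df
    XtX_inv = np.linalg.pinv(Xfull.T @ Xfull)
    se = np.sqrt(np.maximum(s2 * np.diag(XtX_inv), 1e-300))
    tstat = beta / se
    p = 2.0 * t_dist.sf(np.abs(tstat), df)
    return p[first:], beta[first:]


def permutation_threshold(
    G: GenotypeMatrix,
    blups: pd.Series,
    covariates: pd.DataFrame | None = None,
    n_perm: int = 30,
    quantile: float = 0.95,
    seed: int = 0,
) -> float:
    """Permutation-based genome-wide p-value threshold.

    The BLUP phenotype is permuted ``n_perm`` times with covariates fixed;
    each permutation contributes the genome-wide minimum p of a single
    fixed-effect scan, and the threshold is the type-7 (linearly
    interpolated) ``1 - quantile`` quantile of those minima.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    y, C, _ = _align(G, blups, covariates)
    rng = np.random.default_rng(seed)
    minima = np.empty(n_perm)
    for i in range(n_perm):
        yp = rng.permutation(y)
        p, _ = _ols_scan(yp, G.dosage, C)
        minima[i] = p.min()
    return threshold_from_minima(minima, quantile)


def threshold_from_minima(minima: np.ndarray, quantile: float = 0.95) -> float:
    """Type-7 (linearly interpolated) 1-quantile quantile of permutation minima."""
    return float(np.quantile(np.asarray(minima, dtype=float), 1.0 - quantile,
                             method="linear"))


def snp_statistics(result: AssociationResult, blups: pd.Series) -> AssociationResult:
    """Attach per-marker additive variance and PVE.

    Va = 2 p (1 - p) alpha^2 with p the minor allele frequency and alpha the
    additive effect; PVE = Va / var(BLUP phenotype).  Values are stored at
    full precision and rounded only in reports.
    """
    tab = result.table
    va = 2.0 * tab["maf"] * (1.0 - tab["maf"]) * tab["effect"] ** 2
    vary = float(np.var(blups.to_numpy(dtype=float)))
    tab = tab.assign(va=va, pve=va / vary if vary > 0 else np.nan)
    return AssociationResult(
        table=tab,
        covariates=result.covariates,
        threshold=result.threshold,
        pseudo_qtns=result.pseudo_qtns,
        n_iterations=result.n_iterations,
    )


def additive_variance(maf: float, effect: float) -> float:
    """Per-locus additive variance 2 p (1 - p) alpha^2."""
    return 2.0 * maf * (1.0 - maf) * effect**2


def expand_ld_set(
    G: GenotypeMatrix, snps_gwas: list[str], min_r2: float = 0.7
) -> MarkerSets:
    """Expand GWAS hits into the set of markers linked at r^2 >= ``min_r2``.

    Linkage is genome-wide (any chromosome).  The returned ``snps_ld``
    excludes the hits themselves; ``ld_edges`` records every qualifying
    (hit, partner, r2) pair.
    """
    if not snps_gwas:
        raise ValueError("snps_gwas must be non-empty")
    unknown = set(snps_gwas) - set(G.marker_ids)
    if unknown:
        raise ValueError(f"snpsGWAS absent from panel: {sorted(unknown)}")
    ids = G.marker_ids
    hit_idx = np.array([G.markers.index.get_loc(s) for s in snps_gwas])
    R2 = ld_r2_matrix(G, columns=hit_idx)
    edges: list[tuple[str, str, float]] = []
    linked: set[str] = set()
    hits = set(snps_gwas)
    for hi, hrow in zip(hit_idx, R2):
        for j in np.flatnonzero(np.nan_to_num(hrow, nan=-1.0) >= min_r2):
            if j == hi:
                continue
            edges.append((ids[hi], ids[j], float(hrow[j])))
            if ids[j] not in hits:
                linked.add(ids[j])
    return MarkerSets(
        snps_gwas=list(snps_gwas),
        snps_ld=sorted(linked),
        ld_edges=edges,
    )


def build_ld_network(sets: MarkerSets) -> nx.Graph:
    """Undirected LD network over snpsGWAS + snpsLD, edges weighted by r^2."""
    g = nx.Graph()
    g.add_nodes_from(sets.snps_gwas, kind="snpsGWAS")
    g.add_nodes_from(sets.snps_ld, kind="snpsLD")
    for a, b, r2 in sets.ld_edges:
        if a != b and (not g.has_edge(a, b) or g[a][b]["weight"] < r2):
            g.add_edge(a, b, weight=r2)
    return g
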
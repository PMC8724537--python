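"""Genotype QC, imputation, population structure and linkage disequilibrium.

Markers are filtered on missing rate and minor allele frequency, missing
calls are imputed by k-nearest-neighbour averaging, population structure is
summarised by PCA plus a VanRaden genomic relationship matrix, and LD is the
squared Pearson correlation of dosage columns with an exponential
decay-with-distance fit y = a + b*exp(-c*x).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from ._core import GenotypeMatrix, LdDecayFit

__all__ = [
    "FilterReport",
    "filter_markers",
    "impute_knn",
    "population_structure",
    "ld_r2",
    "ld_r2_matrix",
    "fit_ld_decay",
    "retention_percent",
]


@dataclass
class FilterReport:
    """Counts from marker filtering, with the retention percentage."""

    n_discovered: int
    n_retained: int
    n_removed_missing: int
    n_removed_maf: int

    @property
    def percent_retained(self) -> float:
        return retention_percent(self.n_discovered, self.n_retained)


def retention_percent(n_discovered: int, n_retained: int) -> float:
    """Retention percentage, rounded to two decimals as reported."""
    if n_discovered <= 0:
        raise ValueError("n_discovered must be positive")
    return round(100.0 * n_retained / n_discovered, 2)


def filter_markers(
    G: GenotypeMatrix,
    max_missing: float = 0.20,
    min_maf: float = 0.05,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop markers with missing rate > ``max_missing`` or MAF < ``min_maf``.

    Boundaries follow the filtering rule "more than 20% missing" and
    "MAF < 0.05": exactly 20% missing is kept, exactly 0.05 MAF is kept.
    MAF is computed on non-missing calls after the missing-rate filter;
    because MAF does not depend on how many *other* markers survive, the
    joint filter equals the two-stage filter.
    """
    miss = G.missing_rate()
    keep_miss = miss <= max_missing
    maf = G.maf()
    with np.errstate(invalid="ignore"):
        keep_maf = np.nan_to_num(maf, nan=-1.0) >= min_maf
    keep = keep_miss & keep_maf
    report = FilterReport(
        n_discovered=G.n_markers,
        n_retained=int(keep.sum()),
        n_removed_missing=int((~keep_miss).sum()),
        n_removed_maf=int((keep_miss & ~keep_maf).sum()),
    )
    if report.n_retained == 0:
        warnings.warn("all markers removed by filtering", stacklevel=2)
    return G.subset_markers(keep), report


def impute_knn(G: GenotypeMatrix, k: int = 5) -> tuple[GenotypeMatrix, float]:
    """k-nearest-neighbour imputation of missing dosages.

    Neighbours are ranked by Euclidean distance over shared non-missing
    markers (distance scaled by the number of shared markers so sparsity is
    comparable); ties broken by sample order.  The imputed value is the mean
    dosage of the k nearest samples with an observed call at that marker,
    rounded to the nearest integer in {0, 1, 2}.
    """
    D = G.dosage
    nan_mask = np.isnan(D)
    n_missing = int(nan_mask.sum())
    if n_missing == 0:
        return G, 0.0
    fully_missing = np.flatnonzero(nan_mask.all(axis=0))
    if fully_missing.size:
        raise ValueError(
            f"marker(s) fully missing: {[G.marker_ids[j] for j in fully_missing[:5]]}"
        )
    obs_count = (~nan_mask).sum(axis=0)
    low = np.flatnonzero(obs_count < k)
    if low.size:
        raise ValueError(
            f"marker(s) with fewer than k={k} observed calls: "
            f"{[G.marker_ids[j] for j in low[:5]]}"
        )

    n = G.n_samples
    X = np.nan_to_num(D, nan=0.0)
    obs = (~nan_mask).astype(float)
    # squared distances over shared observed markers, scaled to a per-marker
    # mean so samples with different missingness are comparable
    sq = X**2
    shared = obs @ obs.T
    # sum over markers observed in BOTH samples of (x_i - x_j)^2; the
    # nan_to_num zeros make the masked terms drop out of each product
    d2 = (sq @ obs.T) + (obs @ sq.T) - 2.0 * (X @ X.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        d2_scaled = np.where(shared > 0, d2 / shared, np.inf)
    np.fill_diagonal(d2_scaled, np.inf)

    out = D.copy()
    order_all = np.argsort(d2_scaled, axis=1, kind="stable")
    for i in range(n):
        miss_j = np.flatnonzero(nan_mask[i])
        if miss_j.size == 0:
            continue
        order = order_all[i]
        for j in miss_j:
            donors = order[~nan_mask[order, j]][:k]
            val = D[donors, j].mean()
            out[i, j] = min(2.0, max(0.0, round(val)))
    rate = n_missing / D.size
    G2 = GenotypeMatrix(samples=list(G.samples), markers=G.markers.copy(), dosage=out)
    return G2, rate


def population_structure(
    G: GenotypeMatrix, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """PCA scores, per-component variance explained, and VanRaden kinship.

    Requires an imputed matrix.  PCA is on column-centred dosages; kinship is
    K = ZZ' / (2 * sum p(1-p)) with Z the dosage matrix centred at 2p.
    """
    D = G.dosage
    if np.isnan(D).any():
        raise ValueError("population_structure requires an imputed matrix")
    p = D.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic markers in panel")
    Dp = D[:, poly]
    pp = p[poly]
    centered = Dp - Dp.mean(axis=0)
    U, S, Vt = np.linalg.svd(centered, full_matrices=False)
    total_var = (S**2).sum()
    n_components = min(n_components, len(S))
    scores = pd.DataFrame(
        U[:, :n_components] * S[:n_components],
        index=pd.Index(G.samples, name="sample"),
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    var_explained = (S[:n_components] ** 2) / total_var
    Z = Dp - 2.0 * pp
    K = Z @ Z.T / (2.0 * np.sum(pp * (1.0 - pp)))
    kin = pd.DataFrame(K, index=list(G.samples), columns=list(G.samples))
    return scores, var_explained, kin


def ld_r2(G: GenotypeMatrix, marker_a: str, marker_b: str) -> float:
    """Squared Pearson correlation between two dosage columns.

    Monomorphic columns have undefined correlation and return NaN, never 0.
    """
    x = G.column(marker_a)
    y = G.column(marker_b)
    return _r2_vec(x, y)


def _r2_vec(x: np.ndarray, y: np.ndarray) -> float:
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_r2_matrix(G: GenotypeMatrix, columns: np.ndarray | None = None) -> np.ndarray:
    """All-pairs r^2 (or query columns vs all markers when ``columns`` given).

    Requires an imputed matrix; monomorphic markers yield NaN rows/columns.
    """
    D = G.dosage
    if np.isnan(D).any():
        raise ValueError("ld_r2_matrix requires an imputed matrix")
    sd = D.std(axis=0)
    Z = np.zeros_like(D)
    np.divide(D - D.mean(axis=0), sd, out=Z, where=sd > 0)
    n = D.shape[0]
    if columns is None:
        R = (Z.T @ Z) / n
    else:
        R = (Z[:, columns].T @ Z) / n
    R2 = R**2
    bad = sd == 0
    if columns is None:
        R2[bad, :] = np.nan
        R2[:, bad] = np.nan
    else:
        R2[:, bad] = np.nan
        R2[bad[columns], :] = np.nan
    return R2


def _decay(x, a, b, c):
    return a + b * np.exp(-c * x)


def fit_ld_decay(points: np.ndarray | pd.DataFrame) -> LdDecayFit:
    """Nonlinear least squares fit of r^2 = a + b*exp(-c*distance).

    Multi-start initialisation over a grid of plausible (a, b, c); the start
    with the lowest SSE wins.  ``points`` is an (n, 2) array of
    (distance bp, r^2).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 4:
        raise ValueError("need >= 4 (distance, r2) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.unique(x).size < 2:
        raise ValueError("distances are degenerate (single distance value)")

    ymin, ymax = float(y.min()), float(y.max())
    best = None
    starts = []
    for a0 in (0.0, ymin):
        b0 = max(ymax - a0, 1e-6)
        for c0 in np.logspace(-6, -2, 5):
            starts.append((a0, b0, c0))
    for a0, b0, c0 in starts:
        try:
            popt, _ = curve_fit(
                _decay,
                x,
                y,
                p0=(a0, b0, c0),
                bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
                maxfev=20_000,
            )
        except RuntimeError:
            continue
        sse = float(np.sum((y - _decay(x, *popt)) ** 2))
        if best is None or sse < best[1]:
            best = (popt, sse)
    if best is None:
        raise RuntimeError("LD decay fit failed from every start")
    (a, b, c), sse = best
    return LdDecayFit(a=float(a), b=float(b), c=float(c), sse=sse)
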
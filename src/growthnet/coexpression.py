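"""Weighted gene coexpression analysis seeded by GWAS candidates.

Counts are CPM-filtered (mean CPM >= 10 by default), log2-transformed and
quantile-normalised; a soft-threshold power beta is chosen so the
|correlation|^beta network approximates scale-free topology (fit R^2 >=
0.85); gene pairs are scored by the topological overlap measure (TOM), whose
dissimilarity feeds UPGMA clustering with an adaptive branch cut; modules
containing GWAS-assigned genes seed a focused subnetwork (|r| >= 0.5 edges)
whose genes are ranked by Kleinberg hub scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

__all__ = [
    "ExpressionMatrix",
    "SeededSubnetwork",
    "preprocess_counts",
    "pick_soft_threshold",
    "tom_matrix",
    "cut_modules",
    "select_seeded_modules",
    "build_seeded_subnetwork",
]

UNASSIGNED = "unassigned"


@dataclass
class ExpressionMatrix:
    """Raw counts plus the normalized log2-CPM matrix (genes x samples)."""

    counts: pd.DataFrame
    library_sizes: pd.Series
    normalized: pd.DataFrame


@dataclass
class SeededSubnetwork:
    """GWAS-seeded coexpression subnetwork with Kleinberg hub scores."""

    graph: nx.Graph
    hub_scores: dict[str, float]
    seed_genes: list[str]
    modules: dict[str, str] = field(default_factory=dict)

    def top_hubs(self, k: int = 10) -> list[tuple[str, float]]:
        return sorted(self.hub_scores.items(), key=lambda kv: (-kv[1], kv[0]))[:k]


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million; invariant to uniform library-size scaling."""
    lib = counts.sum(axis=0)
    zero = lib[lib == 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    return counts / lib * 1e6


def quantile_normalize(X: pd.DataFrame) -> pd.DataFrame:
    """Force identical value distributions across sample columns.

    Each column's values are replaced, in rank order, by the across-sample
    mean of the column-sorted values.  Rank order within a column is
    preserved, so the transform is idempotent.
    """
    arr = X.to_numpy(dtype=float)
    order = np.argsort(arr, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(arr, order, axis=0)
    ref = sorted_vals.mean(axis=1)
    out = np.empty_like(arr)
    np.put_along_axis(out, order, ref[:, None], axis=0)
    return pd.DataFrame(out, index=X.index, columns=X.columns)


def preprocess_counts(
    counts: pd.DataFrame, min_cpm: float = 10.0, any_sample: bool = False
) -> ExpressionMatrix:
    """CPM filter, log2(CPM + 1) transform and quantile normalisation.

    Genes are retained when their mean CPM across samples is at least
    ``min_cpm`` (or, with ``any_sample``, when any single sample reaches it).
    """
    if counts.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    C = cpm(counts)
    keep = (C >= min_cpm).any(axis=1) if any_sample else C.mean(axis=1) >= min_cpm
    logged = np.log2(C.loc[keep] + 1.0)
    return ExpressionMatrix(
        counts=counts.loc[keep],
        library_sizes=counts.sum(axis=0),
        normalized=quantile_normalize(logged),
    )


def _adjacency(X: pd.DataFrame, beta: int) -> np.ndarray:
    """Unsigned soft-threshold adjacency |cor|^beta with zero diagonal."""
    arr = X.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    if (sd == 0).any():
        bad = list(X.index[sd == 0][:5])
        raise ValueError(f"constant gene rows: {bad}")
    A = np.abs(np.corrcoef(arr)) ** beta
    np.fill_diagonal(A, 0.0)
    return A


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log degree-distribution regression.

    Connectivities are pooled into log-spaced bins (rather than equal-width
    ones) before regressing log10 p(k) on log10 k: with equal-width bins a
    degenerate near-zero connectivity profile, as produced by a high beta on
    null data, collapses into a few occupied bins and passes as scale-free.
    The fit is reported negative when the slope is positive.
    """
    k = k[k > 0]
    if k.size < 2 or k.min() == k.max():
        return 0.0
    edges = np.logspace(np.log10(k.min()), np.log10(k.max()) + 1e-9, n_bins + 1)
    which = np.digitize(k, edges[1:-1])
    xs, ys = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        xs.append(np.log10(k[sel].mean()))
        ys.append(np.log10(sel.mean()))
    if len(xs) < 3:
        return 0.0
    xs, ys = np.asarray(xs), np.asarray(ys)
    slope, intercept = np.polyfit(xs, ys, 1)
    pred = slope * xs + intercept
    ss_res = float(np.sum((ys - pred) ** 2))
    ss_tot = float(np.sum((ys - ys.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return -r2 if slope > 0 else r2


def pick_soft_threshold(
    X: pd.DataFrame,
    betas: range | list[int] = range(1, 21),
    target_r2: float = 0.85,
) -> tuple[int, pd.DataFrame]:
    """Smallest beta whose scale-free fit reaches ``target_r2``.

    Returns (beta, fit table with columns beta, fit_r2, mean_connectivity).
    Falls back, with a warning, to the beta of maximal fit when no candidate
    reaches the target.
    """
    if X.shape[0] < 30:
        raise ValueError("need >= 30 genes to assess scale-free fit")
    rows = []
    for beta in betas:
        A = _adjacency(X, beta)
        k = A.sum(axis=1)
        rows.append(
            {"beta": beta, "fit_r2": _scale_free_fit(k), "mean_connectivity": k.mean()}
        )
    fits = pd.DataFrame(rows)
    ok = fits[fits["fit_r2"] >= target_r2]
    if len(ok):
        return int(ok.iloc[0]["beta"]), fits
    best = int(fits.loc[fits["fit_r2"].idxmax(), "beta"])
    warnings.warn(
        f"no beta reached scale-free fit {target_r2}; using argmax beta={best}",
        stacklevel=2,
    )
    return best, fits


def tom_matrix(X: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Topological overlap of the unsigned |cor|^beta network.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_u a_iu a_uj; the diagonal is 1 by convention.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    A = _adjacency(X, beta)
    k = A.sum(axis=1)
    L = A @ A
    denom = np.minimum.outer(k, k) + 1.0 - A
    T = (L + A) / denom
    np.fill_diagonal(T, 1.0)
    return pd.DataFrame(T, index=X.index, columns=X.index)


def _branch_members(Z: np.ndarray, n: int):
    """Leaves and internal merge heights for every internal node of a linkage."""
    members: list[list[int]] = [[i] for i in range(n)] + [None] * (n - 1)
    heights: list[list[float]] = [[] for _ in range(2 * n - 1)]
    for t in range(n - 1):
        left, right = int(Z[t, 0]), int(Z[t, 1])
        node = n + t
        members[node] = members[left] + members[right]
        heights[node] = heights[left] + heights[right] + [float(Z[t, 2])]
    return members, heights


def cut_modules(
    dissimilarity: pd.DataFrame, min_module_size: int = 30
) -> dict[str, str]:
    """UPGMA clustering with an adaptive branch cut into modules.

    A dendrogram branch qualifies as a module when (i) it holds at least
    ``min_module_size`` leaves and (ii) it is cleanly separated from its
    surroundings: the height gap to its parent merge exceeds both three
    times the median step between its internal merge heights and twice the
    branch's final internal step (so a loose union of tight branches, whose
    last internal merge is itself a big jump, cannot swallow its children).
    Where qualifying branches are nested, the branch with the larger
    separation gap wins (qualifying branches are accepted greedily by
    descending gap, skipping overlaps; the root never qualifies); all other
    genes are labelled ``unassigned``.
    """
    genes = list(dissimilarity.index)
    n = len(genes)
    if n < min_module_size:
        warnings.warn("fewer genes than min_module_size; all unassigned", stacklevel=2)
        return {g: UNASSIGNED for g in genes}
    D = dissimilarity.to_numpy(dtype=float)
    Z = linkage(squareform(D, checks=False), method="average")
    members, heights = _branch_members(Z, n)

    parent_height = {}
    for t in range(n - 1):
        for child in (int(Z[t, 0]), int(Z[t, 1])):
            parent_height[child] = float(Z[t, 2])

    def separation_gap(node: int) -> float | None:
        """Parent gap if the branch qualifies as a module, else None."""
        if node < n or node not in parent_height:  # leaf or root
            return None
        if len(members[node]) < min_module_size:
            return None
        hs = np.sort(np.asarray(heights[node]))
        gap = parent_height[node] - hs[-1]
        steps = np.diff(hs)
        median_step = float(np.median(steps)) if steps.size else 0.0
        last_step = float(steps[-1]) if steps.size else 0.0
        if gap > 3.0 * median_step and gap > 2.0 * last_step and gap > 0:
            return float(gap)
        return None

    qualifying = []
    for node in range(n, 2 * n - 1):
        gap = separation_gap(node)
        if gap is not None:
            qualifying.append((gap, node))
    qualifying.sort(key=lambda t: -t[0])

    modules: list[list[int]] = []
    taken: set[int] = set()
    for _gap, node in qualifying:
        leaves = members[node]
        if taken.isdisjoint(leaves):
            modules.append(leaves)
            taken.update(leaves)

    assignment = {g: UNASSIGNED for g in genes}
    for mi, leaf_ids in enumerate(sorted(modules, key=len, reverse=True), start=1):
        for li in leaf_ids:
            assignment[genes[li]] = f"M{mi}"
    return assignment


def select_seeded_modules(
    partition: dict[str, str], seed_genes: list[str]
) -> list[str]:
    """Module labels containing at least one seed gene."""
    absent = [g for g in seed_genes if g not in partition]
    if absent:
        warnings.warn(f"seed genes absent from partition: {absent[:5]}", stacklevel=2)
    selected = sorted(
        {
            partition[g]
            for g in seed_genes
            if g in partition and partition[g] != UNASSIGNED
        }
    )
    if not selected:
        warnings.warn("no seed gene falls in any module", stacklevel=2)
    return selected


def _hits_hub_scores(A: np.ndarray) -> np.ndarray:
    """Kleinberg hub vector: principal eigenvector of A A^T, max-normalised.

    For the symmetric adjacency used here hub and authority coincide; the
    principal eigenvector of A^T A is the eigenvector of A's largest-
    magnitude eigenvalue.
    """
    if not A.any():
        return np.zeros(len(A))
    vals, vecs = np.linalg.eigh(A.T @ A)
    v = np.abs(vecs[:, np.argmax(vals)])
    return v / v.max()


def build_seeded_subnetwork(
    X: pd.DataFrame,
    partition: dict[str, str],
    selected_modules: list[str],
    seed_genes: list[str],
    extra_genes: list[str] | None = None,
    min_abs_r: float = 0.5,
) -> SeededSubnetwork:
    """Correlation subnetwork over seeded modules, seeds and snpsLD genes.

    Edges connect node pairs with |Pearson r| >= ``min_abs_r`` (signed r as
    weight, pairwise-complete observations, never with <= 2 shared samples);
    hub scores are the HITS hub vector of the |r|-weighted adjacency,
    normalised so the best hub scores 1.
    """
    nodes: list[str] = []
    wanted = set(seed_genes) | set(extra_genes or [])
    wanted |= {g for g, m in partition.items() if m in set(selected_modules)}
    for g in sorted(wanted):
        if g in X.index:
            nodes.append(g)
        else:
            warnings.warn(f"gene {g} absent from expression matrix", stacklevel=2)
    if not nodes:
        raise ValueError("empty node set for seeded subnetwork")

    sub = X.loc[nodes]
    if sub.isna().any().any():
        R = sub.T.corr(min_periods=3).to_numpy()
    else:
        R = np.atleast_2d(np.corrcoef(sub.to_numpy(dtype=float)))
    np.fill_diagonal(R, 0.0)
    R = np.nan_to_num(R, nan=0.0)
    A = np.where(np.abs(R) >= min_abs_r, np.abs(R), 0.0)

    g = nx.Graph()
    for i, gene in enumerate(nodes):
        g.add_node(gene, seed=gene in set(seed_genes))
    ii, jj = np.nonzero(np.triu(A, 1))
    for i, j in zip(ii, jj):
        g.add_edge(nodes[i], nodes[j], weight=float(R[i, j]))

    scores = _hits_hub_scores(A)
    return SeededSubnetwork(
        graph=g,
        hub_scores={gene: float(s) for gene, s in zip(nodes, scores)},
        seed_genes=list(seed_genes),
        modules={g_: partition.get(g_, UNASSIGNED) for g_ in nodes},
    )
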
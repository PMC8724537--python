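"""Synthetic inputs with the statistical structure the pipeline assumes.

Four generators emulate the study-type data: an LD-blocked diploid genotype
panel (with optional low-LD transposon-dense regions and missing calls), a
mixed-model phenotype with planted additive QTLs, a negative-binomial
expression matrix with planted coexpression modules tied to QTL genotypes,
and a KEGG-like toy pathway database.  Each generator is fully determined by
its integer seed and returns (or updates) a :class:`SimulationTruth` record
so downstream recovery can be scored against the planted signal.

LD blocks are built by copying a latent haplotype and flipping each marker's
allele independently with probability f; under symmetric flipping the
marker-latent correlation is (1 - 2f) at allele frequency 0.5, so the
pairwise marker correlation is (1 - 2f)^2 and f is solved in closed form
from the target r^2.  TE-dense regions use the block target scaled by 0.25.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._core import GenotypeMatrix, SimulationTruth

__all__ = [
    "simulate_genotypes",
    "make_design",
    "simulate_phenotypes",
    "simulate_expression",
    "simulate_pathway_db",
    "CURRENCY_COMPOUNDS",
]

#: multiplier applied to a block's target r^2 inside TE-dense regions
TE_R2_FACTOR = 0.25

#: currency/cofactor metabolites excluded when wiring enzyme-graph edges
CURRENCY_COMPOUNDS = (
    "ATP", "ADP", "NAD+", "NADH", "NADP+", "NADPH",
    "H2O", "H+", "CO2", "Pi", "PPi", "CoA", "O2",
)

_MARKER_SPACING = 1_000  # bp between markers inside a block
_BLOCK_GAP = 50_000  # bp between consecutive blocks
_BLOCKS_PER_CHROM = 4


def simulate_genotypes(
    n_samples: int,
    blocks: list[tuple[int, float]],
    te_fraction: float = 0.0,
    maf_range: tuple[float, float] = (0.1, 0.5),
    seed: int = 0,
    missing_rate: float = 0.05,
    qtl_markers: list[tuple[int, float]] | None = None,
    variance_components: tuple[float, float, float] = (4.56, 0.0001, 26.69),
) -> tuple[GenotypeMatrix, SimulationTruth]:
    """Generate an LD-blocked dosage panel plus its ground-truth record.

    Parameters
    ----------
    blocks
        One ``(n_markers, within_block_r2)`` tuple per LD block; blocks are
        laid out four per chromosome with strictly increasing coordinates.
    te_fraction
        Fraction of blocks (taken from the end of the list) marked as
        TE-dense; their target r^2 is multiplied by ``TE_R2_FACTOR``.
    qtl_markers
        Optional ``(global marker index, additive effect)`` pairs planted
        into the truth record for phenotype simulation.
    variance_components
        Residual polygenic, genotype-by-water and error variances stored in
        the truth record; defaults are the study-scale stem-diameter values
        (4.56, 0.0001, 26.69 cm^2).
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if not blocks:
        raise ValueError("blocks list must be non-empty")
    for nm, r2 in blocks:
        if nm <= 0:
            raise ValueError("block marker counts must be positive")
        if not 0.0 <= r2 <= 1.0:
            raise ValueError("within_block_r2 must lie in [0, 1]")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must be a sub-interval of (0, 0.5]")

    rng = np.random.default_rng(seed)
    n_te = int(round(te_fraction * len(blocks)))
    te_block_ids = set(range(len(blocks) - n_te, len(blocks)))

    cols, ids, chroms, poss = [], [], [], []
    ld_block_map: dict[str, int] = {}
    te_regions: list[tuple[str, int, int]] = []
    marker_counter = 0
    for b, (nm, r2) in enumerate(blocks):
        chrom = f"chrom{b // _BLOCKS_PER_CHROM + 1:02d}"
        offset = (b % _BLOCKS_PER_CHROM) * (_BLOCK_GAP + _MARKER_SPACING * max(nm, 1))
        r2_eff = r2 * TE_R2_FACTOR if b in te_block_ids else r2
        rho = r2_eff ** 0.25  # marker-latent correlation
        flip = (1.0 - rho) / 2.0
        p0 = rng.uniform(lo, hi)
        # two latent haplotypes per sample, shared across the block
        h = rng.random((n_samples, 2)) < p0
        start_pos = offset + 1
        for m in range(nm):
            flips = rng.random((n_samples, 2)) < flip
            alleles = np.where(flips, ~h, h)
            cols.append(alleles.sum(axis=1).astype(float))
            mid = f"SNP{marker_counter}"
            ids.append(mid)
            chroms.append(chrom)
            poss.append(offset + 1 + m * _MARKER_SPACING)
            ld_block_map[mid] = b
            marker_counter += 1
        if b in te_block_ids:
            te_regions.append((chrom, start_pos, offset + 1 + (nm - 1) * _MARKER_SPACING))

    dosage = np.column_stack(cols)
    if missing_rate > 0:
        mask = rng.random(dosage.shape) < missing_rate
        dosage[mask] = np.nan

    markers = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": "A", "alt": "G"},
        index=pd.Index(ids, name="marker"),
    )
    samples = [f"S{i:04d}" for i in range(n_samples)]
    G = GenotypeMatrix(samples=samples, markers=markers, dosage=dosage)

    qtls = [(ids[j], float(a)) for j, a in (qtl_markers or [])]
    truth = SimulationTruth(
        qtl_markers=qtls,
        variance_components=tuple(float(v) for v in variance_components),
        module_assignment={},
        ld_block_map=ld_block_map,
        te_regions=te_regions,
        seed=int(seed),
    )
    return G, truth


def make_design(
    genotypes: list[str],
    n_blocks: int = 2,
    n_water: int = 2,
    n_months: int = 2,
    n_reps: int = 1,
) -> pd.DataFrame:
    """Fully crossed block x water x month design, replicated within plot.

    Every genotype appears once per (block, replicate, water, month) cell, so
    the default yields 8 records per genotype.  Factors are crossed rather
    than nested so that no fixed effect is aliased with another.
    """
    rows = []
    for g in genotypes:
        for b in range(n_blocks):
            for r in range(n_reps):
                for w in range(n_water):
                    for m in range(n_months):
                        rows.append(
                            {
                                "sample": f"{g}_b{b}r{r}w{w}",
                                "genotype": g,
                                "block": f"B{b + 1}",
                                "replicate": f"R{r + 1}",
                                "water": f"W{w + 1}",
                                "month": f"M{m + 1}",
                            }
                        )
    return pd.DataFrame(rows)


def _default_fixed_effects(design: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Deterministic, centred level effects for each fixed factor."""
    scales = {"block": 1.0, "replicate": 0.5, "water": 2.0, "month": 0.5}
    effects: dict[str, dict[str, float]] = {}
    for factor, scale in scales.items():
        levels = sorted(design[factor].unique())
        if len(levels) == 1:
            effects[factor] = {levels[0]: 0.0}
        else:
            vals = np.linspace(-scale / 2, scale / 2, len(levels))
            effects[factor] = dict(zip(levels, vals))
    return effects


def simulate_phenotypes(
    G: GenotypeMatrix,
    truth: SimulationTruth,
    design: pd.DataFrame,
    mu: float = 10.0,
    fixed_effects: dict[str, dict[str, float]] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate trait records under the growth-trait mixed model.

    y = mu + block + replicate + water + month + g + gw + eps, with
    g ~ N(sum_k alpha_k * dosage_k, sigma_g2), gw ~ N(0, sigma_gw2) per
    (genotype, water) cell and eps ~ N(0, sigma_e2) per record.  Missing
    dosages at QTL markers contribute via the marker's mean dosage.
    """
    missing = set(design["genotype"]) - set(G.samples)
    if missing:
        raise ValueError(f"design genotypes absent from panel: {sorted(missing)[:5]}")
    sg2, sgw2, se2 = truth.variance_components
    if min(sg2, sgw2, se2) < 0:
        raise ValueError("variance components must be non-negative")
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    fx = fixed_effects or _default_fixed_effects(design)

    sample_idx = {s: i for i, s in enumerate(G.samples)}
    qtl_part = np.zeros(G.n_samples)
    for mid, alpha in truth.qtl_markers:
        col = G.column(mid).copy()
        col[np.isnan(col)] = np.nanmean(col)
        qtl_part += alpha * col

    genotypes = sorted(design["genotype"].unique())
    g_eff = {
        g: qtl_part[sample_idx[g]] + rng.normal(0.0, np.sqrt(sg2)) for g in genotypes
    }
    waters = sorted(design["water"].unique())
    gw_eff = {
        (g, w): rng.normal(0.0, np.sqrt(sgw2)) for g in genotypes for w in waters
    }

    out = design.copy()
    eps = rng.normal(0.0, np.sqrt(se2), size=len(design))
    values = []
    for i, row in enumerate(design.itertuples(index=False)):
        y = (
            mu
            + fx["block"][row.block]
            + fx["replicate"][row.replicate]
            + fx["water"][row.water]
            + fx["month"][row.month]
            + g_eff[row.genotype]
            + gw_eff[(row.genotype, row.water)]
            + eps[i]
        )
        values.append(y)
    out["value"] = values
    return out


def simulate_expression(
    G: GenotypeMatrix,
    truth: SimulationTruth,
    n_modules: int,
    module_sizes: list[int],
    cor_within: float,
    n_samples_expr: int,
    seed: int = 0,
    n_background: int = 0,
    base_mean: float = 200.0,
    dispersion: float = 0.1,
    ec_pool: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial counts with planted coexpression modules.

    Each module follows one latent factor; module k's factor is the
    standardised dosage of planted QTL k (when one exists and the expression
    samples are drawn from the genotyped panel), so modules correlate with
    QTL genotypes.  Gene latent profiles are
    sqrt(c)*factor + sqrt(1-c)*noise with c = ``cor_within``; counts are
    NB(mean = lib * base * exp(latent), dispersion) so observed log-CPM
    correlations sit slightly below c (the NB noise adds variance).

    The annotation table places module k's first gene adjacent to QTL k's
    marker and assigns GO/EC terms to module genes from ``ec_pool``.
    Updates ``truth.module_assignment`` in place and returns
    (counts, annotation).
    """
    if not 0.0 < cor_within < 1.0:
        raise ValueError("cor_within must lie in (0, 1)")
    if len(module_sizes) != n_modules:
        raise ValueError("module_sizes length must equal n_modules")
    rng = np.random.default_rng(seed)
    n_genes = sum(module_sizes) + n_background

    expr_samples = [f"E{i:03d}" for i in range(n_samples_expr)]
    use_genotypes = n_samples_expr <= G.n_samples

    factors = np.empty((n_samples_expr, n_modules))
    for k in range(n_modules):
        if use_genotypes and k < len(truth.qtl_markers):
            col = G.column(truth.qtl_markers[k][0])[:n_samples_expr].copy()
            col[np.isnan(col)] = np.nanmean(col)
            sd = col.std()
            factors[:, k] = (col - col.mean()) / (sd if sd > 0 else 1.0)
        else:
            factors[:, k] = rng.standard_normal(n_samples_expr)

    latent = np.empty((n_genes, n_samples_expr))
    gene_module: list[str | None] = []
    row = 0
    for k, size in enumerate(module_sizes):
        noise = rng.standard_normal((size, n_samples_expr))
        latent[row : row + size] = (
            np.sqrt(cor_within) * factors[:, k][None, :]
            + np.sqrt(1.0 - cor_within) * noise
        )
        gene_module.extend([f"PM{k + 1}"] * size)
        row += size
    if n_background:
        latent[row:] = rng.standard_normal((n_background, n_samples_expr))
        gene_module.extend([None] * n_background)

    gene_ids = [f"gene{i:05d}" for i in range(n_genes)]
    base = base_mean * np.exp(rng.normal(0.0, 0.25, size=n_genes))
    lib_factor = np.exp(rng.normal(0.0, 0.1, size=n_samples_expr))
    mean = base[:, None] * np.exp(latent) * lib_factor[None, :]
    # numpy's NB: n successes, success prob; mean = n (1-p)/p
    n_nb = 1.0 / dispersion
    p_nb = n_nb / (n_nb + mean)
    counts = rng.negative_binomial(n_nb, p_nb)
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=expr_samples)

    truth.module_assignment.update(
        {g: m for g, m in zip(gene_ids, gene_module) if m is not None}
    )

    annot = _place_genes(G, truth, gene_ids, gene_module, module_sizes, ec_pool, rng)
    return counts_df, annot


def _place_genes(G, truth, gene_ids, gene_module, module_sizes, ec_pool, rng):
    """Assign coordinates; module k's first gene flanks planted QTL k."""
    qtl_pos = {}
    for k, (mid, _a) in enumerate(truth.qtl_markers):
        r = G.markers.loc[mid]
        qtl_pos[f"PM{k + 1}"] = (r["chrom"], int(r["pos"]))
    chroms, starts, ends, strands, products, gos, ecs = [], [], [], [], [], [], []
    cursor = 1_000_000
    seen_modules: set[str] = set()
    for i, gid in enumerate(gene_ids):
        mod = gene_module[i]
        if mod is not None and mod not in seen_modules and mod in qtl_pos:
            chrom, pos = qtl_pos[mod]
            start = max(1, pos - 500)
            end = start + 999
            seen_modules.add(mod)
        else:
            chrom = "chrom90"
            start = cursor
            end = cursor + 999
            cursor += 10_000
        chroms.append(chrom)
        starts.append(start)
        ends.append(end)
        strands.append("+" if rng.random() < 0.5 else "-")
        products.append(f"hypothetical protein {gid}")
        if mod is not None:
            gos.append(f"GO:{7000000 + int(mod[2:]):07d}")
            ecs.append(ec_pool[i % len(ec_pool)] if ec_pool else "")
        else:
            gos.append("")
            ecs.append("")
    annot = pd.DataFrame(
        {
            "chrom": chroms,
            "start": starts,
            "end": ends,
            "strand": strands,
            "product": products,
            "GO": gos,
            "EC": ecs,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return annot.sort_values(["chrom", "start"])


def simulate_pathway_db(
    n_pathways: int,
    ec_pool: list[str],
    shared_compound_rate: float = 0.3,
    seed: int = 0,
    reactions_per_pathway: tuple[int, int] = (3, 6),
    cofactor_rate: float = 0.2,
) -> pd.DataFrame:
    """KEGG-like flat pathway table (pathway, reaction, EC, compounds).

    With probability ``shared_compound_rate`` a reaction consumes the product
    of an earlier reaction in the same pathway, chaining the derived enzyme
    graph; cofactors from the fixed currency list are appended to a
    ``cofactor_rate`` fraction of reactions (they never create edges
    downstream).
    """
    if not ec_pool:
        raise ValueError("ec_pool must be non-empty")
    rng = np.random.default_rng(seed)
    rows = []
    compound_counter = 0
    rxn_counter = 0
    for pw in range(n_pathways):
        pw_id = f"path{pw + 1:04d}"
        lo, hi = reactions_per_pathway
        n_rxn = int(rng.integers(lo, hi + 1))
        products_so_far: list[str] = []
        for _ in range(n_rxn):
            ec = ec_pool[int(rng.integers(len(ec_pool)))]
            if products_so_far and rng.random() < shared_compound_rate:
                substrate = products_so_far[int(rng.integers(len(products_so_far)))]
            else:
                substrate = f"C{compound_counter:05d}"
                compound_counter += 1
            product = f"C{compound_counter:05d}"
            compound_counter += 1
            substrates = [substrate]
            products = [product]
            if rng.random() < cofactor_rate:
                substrates.append(CURRENCY_COMPOUNDS[int(rng.integers(len(CURRENCY_COMPOUNDS)))])
                products.append(CURRENCY_COMPOUNDS[int(rng.integers(len(CURRENCY_COMPOUNDS)))])
            rows.append(
                {
                    "pathway_id": pw_id,
                    "reaction_id": f"R{rxn_counter:05d}",
                    "ec": ec,
                    "substrates": ";".join(substrates),
                    "products": ";".join(products),
                }
            )
            products_so_far.append(product)
            rxn_counter += 1
    return pd.DataFrame(rows)
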
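"""Core in-memory containers shared across the pipeline.

The pipeline's substrate is a diploid biallelic dosage matrix with marker
coordinates, a tidy phenotype table, and small result records (variance
components, per-marker association statistics, LD marker sets).  Containers
are plain dataclasses around numpy arrays and pandas frames; heavier objects
(graphs) use networkx directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "VarianceComponents",
    "LdDecayFit",
    "AssociationResult",
    "MarkerSets",
    "SimulationTruth",
]


@dataclass
class GenotypeMatrix:
    """Samples x markers dosage matrix in {0, 1, 2} with NaN for missing.

    ``markers`` is a DataFrame indexed by marker id with columns
    ``chrom``, ``pos`` (1-based bp), ``ref``, ``alt``.  Positions must be
    strictly increasing within each chromosome.
    """

    samples: list[str]
    markers: pd.DataFrame
    dosage: np.ndarray  # float array, shape (n_samples, n_markers)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        for chrom, grp in self.markers.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.markers.index)

    def column(self, marker_id: str) -> np.ndarray:
        """Dosage vector for one marker id."""
        j = self.markers.index.get_loc(marker_id)
        return self.dosage[:, j]

    def maf(self) -> np.ndarray:
        """Minor allele frequency per marker, computed on non-missing calls."""
        with np.errstate(invalid="ignore"):
            p = np.nanmean(self.dosage, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> np.ndarray:
        return np.mean(np.isnan(self.dosage), axis=0)

    def subset_markers(self, keep: np.ndarray | list) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return GenotypeMatrix(
            samples=list(self.samples),
            markers=self.markers.iloc[idx].copy(),
            dosage=self.dosage[:, idx].copy(),
        )


@dataclass
class VarianceComponents:
    """REML variance components and BLUPs from the growth-trait mixed model.

    sigma_g2, sigma_gw2, sigma_e2 are the genotype, genotype-by-water
    interaction and residual variances (trait units squared); ``blups`` maps
    genotype id to its predicted random effect g, ``gw_blups`` maps
    (genotype, water) to the interaction effect.
    """

    sigma_g2: float
    sigma_gw2: float
    sigma_e2: float
    mu: float
    blups: dict[str, float]
    gw_blups: dict[tuple[str, str], float]
    loglik: float
    converged: bool = True
    fixed_effects: dict[str, float] = field(default_factory=dict)
    n_iter: int = 0
    ll_trace: list[float] = field(default_factory=list)


@dataclass
class LdDecayFit:
    """Parameters of the exponential LD decay curve y = a + b*exp(-c*x)."""

    a: float
    b: float
    c: float
    sse: float

    def predict(self, x):
        return self.a + self.b * np.exp(-self.c * np.asarray(x, dtype=float))


@dataclass
class AssociationResult:
    """Per-marker association scan output plus the significance threshold.

    ``table`` is indexed by marker id with columns chrom, pos, p, effect,
    maf and (after :func:`snp_statistics`) va, pve.
    """

    table: pd.DataFrame
    covariates: list[str]
    threshold: float | None = None
    pseudo_qtns: list[str] = field(default_factory=list)
    n_iterations: int = 1

    def significant(self) -> pd.DataFrame:
        if self.threshold is None:
            raise ValueError("no significance threshold set")
        return self.table[self.table["p"] <= self.threshold]


@dataclass
class MarkerSets:
    """GWAS hits and their LD-linked companions.

    ``snps_gwas``: markers below the scan threshold; ``snps_ld``: markers
    linked at r^2 >= the expansion threshold to at least one hit (hits
    themselves excluded); ``ld_edges``: (hit, partner, r2) triples.
    """

    snps_gwas: list[str]
    snps_ld: list[str]
    ld_edges: list[tuple[str, str, float]]


@dataclass
class SimulationTruth:
    """Ground truth record emitted by the synthetic-data generators.

    ``variance_components`` are the residual polygenic, genotype-by-water and
    error variances; planted QTLs contribute additional additive variance
    2p(1-p)*alpha^2 on top of sigma_g2.
    """

    qtl_markers: list[tuple[str, float]]
    variance_components: tuple[float, float, float]
    module_assignment: dict[str, str]
    ld_block_map: dict[str, int]
    te_regions: list[tuple[str, int, int]]
    seed: int

    def to_json_dict(self) -> dict:
        return {
            "qtl_markers": [[m, float(a)] for m, a in self.qtl_markers],
            "variance_components": [float(v) for v in self.variance_components],
            "module_assignment": dict(self.module_assignment),
            "ld_block_map": {k: int(v) for k, v in self.ld_block_map.items()},
            "te_regions": [[c, int(s), int(e)] for c, s, e in self.te_regions],
            "seed": int(self.seed),
        }
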
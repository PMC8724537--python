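import numpy as np
import pandas as pd
import pytest

from growthnet import GenotypeMatrix, simulate_genotypes


def make_panel(dosage: np.ndarray, chrom: str = "chrom01", spacing: int = 1000):
    """Wrap a raw dosage array into a GenotypeMatrix with synthetic coordinates."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    markers = pd.DataFrame(
        {
            "chrom": [chrom] * m,
            "pos": np.arange(1, m + 1) * spacing,
            "ref": "A",
            "alt": "G",
        },
        index=pd.Index([f"SNP{j}" for j in range(m)], name="marker"),
    )
    return GenotypeMatrix(
        samples=[f"S{i:04d}" for i in range(n)], markers=markers, dosage=dosage
    )


@pytest.fixture(scope="session")
def block_panel():
    """Small imputed panel with strong LD blocks, shared across tests."""
    G, truth = simulate_genotypes(
        120, [(10, 0.8)] * 4, seed=11, missing_rate=0.0
    )
    return G, truth


@pytest.fixture
def annotation_frame():
    """Three genes on one chromosome plus one on another."""
    return pd.DataFrame(
        {
            "chrom": ["chrom01", "chrom01", "chrom01", "chrom02"],
            "start": [100, 1200, 5000, 400],
            "end": [900, 2000, 6000, 800],
            "strand": ["+", "-", "+", "+"],
            "product": ["kinase", "phosphatase", "transporter", "ligase"],
            "GO": ["GO:0001;GO:0002", "GO:0002", "", "GO:0003"],
            "EC": ["2.7.1.1", "", "3.1.3.2;2.7.1.1", ""],
        },
        index=pd.Index(["geneA", "geneB", "geneC", "geneD"], name="gene_id"),
    )
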
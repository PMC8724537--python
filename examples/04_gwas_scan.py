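"""FarmCPU-style association scan with a permutation threshold and LD
expansion of the hits.

Simulates a 300-sample, 2,000-marker panel with one planted QTL
(alpha = 0.84, MAF ~ 0.45, per-locus h2 ~ 0.09 — the scale of the largest
reported stem-diameter association), scans with PC covariates, thresholds by
30 phenotype permutations at the 95% quantile and expands the hits into the
r2 >= 0.7 linked set.
"""

import warnings

import numpy as np
import pandas as pd

from growthnet import (
    build_ld_network,
    expand_ld_set,
    farmcpu_scan,
    permutation_threshold,
    population_structure,
    simulate_genotypes,
    snp_statistics,
)

warnings.simplefilter("ignore")

G, truth = simulate_genotypes(
    300, [(20, 0.8)] * 100, maf_range=(0.35, 0.5), seed=1, missing_rate=0.0
)
qtl = 1010
alpha = 0.84
dose = G.dosage[:, qtl]
va = alpha**2 * dose.var()
rng = np.random.default_rng(2)
y = pd.Series(
    alpha * dose + rng.normal(0, np.sqrt(va / 0.09 - va), G.n_samples),
    index=G.samples,
)

scores, _, kinship = population_structure(G)
result = farmcpu_scan(G, y, covariates=scores, kinship=kinship)
result.threshold = permutation_threshold(G, y, covariates=scores, seed=3)
result = snp_statistics(result, y)

sig = result.significant().sort_values("p")
print(f"scan       : {G.n_markers} markers, threshold p <= {result.threshold:.2e}")
print(f"pseudo-QTNs: {result.pseudo_qtns}")
print("significant markers:")
print(sig[["chrom", "pos", "p", "effect", "maf", "va", "pve"]].round(4).to_string())
print(f"planted QTL was marker SNP{qtl}")

# expand from the single best hit: its whole LD block joins the snpsLD set
top_hit = result.table["p"].idxmin()
sets = expand_ld_set(G, [top_hit], min_r2=0.7)
net = build_ld_network(sets)
print(f"snpsLD     : {len(sets.snps_ld)} markers linked at r2 >= 0.7")
print(f"LD network : {net.number_of_nodes()} nodes, {net.number_of_edges()} edges")
print("The linked set captures the QTL's whole LD block — candidates a")
print("single-marker threshold would miss.")
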
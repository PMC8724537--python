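"""Generate a complete synthetic study: genotypes, phenotypes, expression,
annotation and a toy pathway database, written to ./cohort_out/.

The panel mimics a clonally replicated tree population: LD-blocked SNPs with
a TE-dense low-LD region, a stem-diameter-like trait from the mixed model
(block/replicate/water/month fixed effects, genotype and genotype-by-water
random effects) with two planted QTLs, and counts with planted coexpression
modules tied to the QTL genotypes.
"""

from pathlib import Path

from growthnet import (
    make_design,
    simulate_expression,
    simulate_genotypes,
    simulate_pathway_db,
    simulate_phenotypes,
)
from growthnet.io import (
    write_annotation_tsv,
    write_counts,
    write_pathway_db,
    write_phenotypes,
    write_truth,
    write_vcf,
)

out = Path("cohort_out")
out.mkdir(exist_ok=True)

G, truth = simulate_genotypes(
    n_samples=300,
    blocks=[(20, 0.8)] * 12,
    te_fraction=0.25,
    seed=7,
    qtl_markers=[(10, 0.84), (130, -0.60)],
    variance_components=(4.56, 0.0001, 26.69),
)
pheno = simulate_phenotypes(G, truth, make_design(G.samples))
ec_pool = [f"2.7.1.{i}" for i in range(1, 20)]
counts, annot = simulate_expression(
    G, truth, n_modules=2, module_sizes=[60, 60], cor_within=0.95,
    n_samples_expr=60, seed=8, n_background=400, ec_pool=ec_pool,
)
pathways = simulate_pathway_db(28, ec_pool, shared_compound_rate=0.5, seed=9)

write_vcf(G, out / "genotypes.vcf")
write_phenotypes(pheno, out / "phenotypes.tsv")
write_counts(counts, out / "counts.tsv")
write_annotation_tsv(annot, out / "annotation.tsv")
write_pathway_db(pathways, out / "pathways.tsv")
write_truth(truth, out / "truth.json")

print(f"panel      : {G.n_samples} samples x {G.n_markers} markers")
print(f"TE regions : {truth.te_regions}")
print(f"QTLs       : {truth.qtl_markers}")
print(f"phenotypes : {len(pheno)} records "
      f"(mean {pheno['value'].mean():.2f} cm, var {pheno['value'].var():.2f})")
print(f"expression : {counts.shape[0]} genes x {counts.shape[1]} samples")
print(f"pathways   : {pathways['pathway_id'].nunique()} pathways, "
      f"{len(pathways)} reactions")
print("The truth.json file records the planted QTLs, variance components and")
print("module labels so downstream recovery can be scored against them.")
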
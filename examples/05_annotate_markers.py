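"""Assign candidate genes to associated markers and intersect with QTLs.

Each marker gets its containing transcript or the nearest transcripts up-
and downstream (genome-coordinate sense); GO/EC terms are pooled per marker
set and marker positions are checked against externally mapped QTL
intervals.
"""

import pandas as pd

from growthnet import (
    assign_flanking_genes,
    collect_terms,
    mean_assignment_distance,
    qtl_overlap,
)

markers = pd.DataFrame(
    {"chrom": ["chrom01", "chrom01", "chrom02"], "pos": [1_000, 55_000, 14_000]},
    index=pd.Index(["SNP_a", "SNP_b", "SNP_c"], name="marker"),
)
annot = pd.DataFrame(
    {
        "chrom": ["chrom01", "chrom01", "chrom01", "chrom02"],
        "start": [200, 3_000, 60_000, 13_500],
        "end": [900, 4_000, 61_000, 14_800],
        "strand": ["+", "-", "+", "+"],
        "product": ["subtilisin-like protease", "deacylase", "kinase", "IQ motif protein"],
        "GO": ["GO:0006508", "GO:0106074", "", "GO:0005516"],
        "EC": ["3.4.21.-", "", "2.7.1.1", ""],
    },
    index=pd.Index(["geneA", "geneB", "geneC", "geneD"], name="gene_id"),
)

assignments = assign_flanking_genes(markers, annot)
for mid, fa in assignments.items():
    if fa.containing:
        print(f"{mid}: inside {fa.containing}")
    else:
        print(f"{mid}: upstream {fa.upstream} ({fa.upstream_distance} bp), "
              f"downstream {fa.downstream} ({fa.downstream_distance} bp)")
print(f"mean assignment distance: {mean_assignment_distance(assignments):,.0f} bp")

terms = collect_terms(assignments, annot,
                      {"snpsGWAS": ["SNP_a", "SNP_c"], "snpsLD": ["SNP_b"]})
print("\nterms per marker set:")
print(terms.to_string(index=False))

qtls = pd.DataFrame(
    {"chrom": ["chrom02"], "start": [10_000], "end": [20_000], "label": ["SD-QTL-1"]}
)
print("\nQTL overlap (closed intervals):")
print(qtl_overlap(markers, qtls).to_string())
print("SNP_c falls inside the mapped stem-diameter QTL, corroborating the")
print("association with an independent linkage result.")
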
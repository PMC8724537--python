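"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as VCF 4.2 (GT-only, ``./.`` for missing; read back with
cyvcf2), annotation as GFF3 or a flat TSV, expression counts as TSV,
the toy pathway database as a documented TSV dialect and simulation truth
as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ._core import GenotypeMatrix, SimulationTruth

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1"}

PATHWAY_COLUMNS = ["pathway_id", "reaction_id", "ec", "substrates", "products"]


def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT genotypes (``./.`` when missing)."""
    path = Path(path)
    chroms = list(dict.fromkeys(G.markers["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=growthnet\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.samples)
            + "\n"
        )
        for j, (mid, row) in enumerate(G.markers.iterrows()):
            calls = []
            for d in G.dosage[:, j]:
                calls.append("./." if np.isnan(d) else _GT_CODE[int(round(d))])
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{mid}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a biallelic VCF into a dosage matrix (multi-allelic sites rejected)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    ids, chroms, poss, refs, alts, cols = [], [], [], [], [], []
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1:
            raise ValueError(f"non-biallelic record at {var.CHROM}:{var.POS}")
        ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        gt = var.gt_types.astype(float)  # 0/1/2, 3 = unknown
        gt[gt == 3] = np.nan
        cols.append(gt)
    markers = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts},
        index=pd.Index(ids, name="marker"),
    )
    dosage = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    return GenotypeMatrix(samples=samples, markers=markers, dosage=dosage)


def write_phenotypes(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t", dtype={"sample": str, "genotype": str})
    required = {"sample", "genotype", "block", "replicate", "water", "month", "value"}
    missing = required - set(tab.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    return tab


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_annotation_tsv(annot: pd.DataFrame, path: str | Path) -> None:
    """Flat annotation: gene_id, chrom, start, end, strand, product, GO, EC.

    GO and EC columns hold ``;``-separated term lists (empty string if none).
    """
    annot.to_csv(path, sep="\t", index_label="gene_id")


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    annot = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False)
    for col in ("GO", "EC"):
        if col in annot.columns:
            annot[col] = annot[col].astype(str).replace("nan", "")
    return annot


def write_annotation_gff3(annot: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid, row in annot.iterrows():
            attrs = [f"ID={gid}"]
            if row.get("product"):
                attrs.append(f"product={row['product']}")
            if row.get("GO"):
                attrs.append(f"Ontology_term={row['GO']}")
            if row.get("EC"):
                attrs.append(f"ec_number={row['EC']}")
            fh.write(
                f"{row['chrom']}\tgrowthnet\tgene\t{int(row['start'])}\t"
                f"{int(row['end'])}\t.\t{row['strand']}\t.\t" + ";".join(attrs) + "\n"
            )


def write_pathway_db(db: pd.DataFrame, path: str | Path) -> None:
    """TSV dialect: pathway_id, reaction_id, ec, substrates, products.

    Substrate/product compound lists are ``;``-separated.
    """
    db.loc[:, PATHWAY_COLUMNS].to_csv(path, sep="\t", index=False)


def read_pathway_db(path: str | Path) -> pd.DataFrame:
    db = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(PATHWAY_COLUMNS) - set(db.columns)
    if missing:
        raise ValueError(f"pathway db missing columns: {sorted(missing)}")
    return db


def write_truth(truth: SimulationTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1)


def read_truth(path: str | Path) -> SimulationTruth:
    with open(path) as fh:
        d = json.load(fh)
    return SimulationTruth(
        qtl_markers=[(m, float(a)) for m, a in d["qtl_markers"]],
        variance_components=tuple(d["variance_components"]),
        module_assignment=d["module_assignment"],
        ld_block_map={k: int(v) for k, v in d["ld_block_map"].items()},
        te_regions=[(c, int(s), int(e)) for c, s, e in d["te_regions"]],
        seed=int(d["seed"]),
    )
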
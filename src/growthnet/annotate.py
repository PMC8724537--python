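"""Candidate-gene assignment for associated markers.

Each marker is assigned its containing transcript (distance 0) or the
nearest transcripts on either side in genome coordinates ("upstream" = ends
before the marker, "downstream" = starts after it, strand-agnostic); GO/EC
terms are collected per marker set, and marker positions are intersected
with externally supplied QTL intervals (closed, 1-based).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FlankAssignment",
    "assign_flanking_genes",
    "collect_terms",
    "qtl_overlap",
]


@dataclass
class FlankAssignment:
    """Flanking-gene assignment for one marker.

    Either ``containing`` is set (distance 0) or up to one gene on each side
    with its bp distance to the nearest transcript boundary.
    """

    marker: str
    containing: str | None = None
    upstream: str | None = None
    upstream_distance: int | None = None
    downstream: str | None = None
    downstream_distance: int | None = None

    def genes(self) -> list[str]:
        if self.containing is not None:
            return [self.containing]
        return [g for g in (self.upstream, self.downstream) if g is not None]

    def distances(self) -> list[int]:
        if self.containing is not None:
            return [0]
        return [
            d
            for d in (self.upstream_distance, self.downstream_distance)
            if d is not None
        ]


def assign_flanking_genes(
    markers: pd.DataFrame, annot: pd.DataFrame
) -> dict[str, FlankAssignment]:
    """Assign each marker its containing or nearest flanking transcripts.

    ``markers``: frame indexed by marker id with chrom and pos columns.
    ``annot``: frame indexed by gene id with chrom, start, end (1-based
    inclusive).  Ties between equidistant transcripts break toward the
    smaller start coordinate.  Markers on chromosomes absent from the
    annotation get an empty assignment with a warning.
    """
    by_chrom = {
        chrom: grp.sort_values(["start", "end"]) for chrom, grp in annot.groupby("chrom")
    }
    out: dict[str, FlankAssignment] = {}
    for mid, row in markers.iterrows():
        chrom, pos = row["chrom"], int(row["pos"])
        fa = FlankAssignment(marker=str(mid))
        grp = by_chrom.get(chrom)
        if grp is None:
            warnings.warn(f"marker {mid}: chromosome {chrom} absent from annotation",
                          stacklevel=2)
            out[str(mid)] = fa
            continue
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        inside = np.flatnonzero((starts <= pos) & (pos <= ends))
        if inside.size:
            fa.containing = str(grp.index[inside[0]])
            out[str(mid)] = fa
            continue
        up = np.flatnonzero(ends < pos)
        if up.size:
            d = pos - ends[up]
            best = up[np.lexsort((starts[up], d))[0]]
            fa.upstream = str(grp.index[best])
            fa.upstream_distance = int(pos - ends[best])
        down = np.flatnonzero(starts > pos)
        if down.size:
            d = starts[down] - pos
            best = down[np.lexsort((starts[down], d))[0]]
            fa.downstream = str(grp.index[best])
            fa.downstream_distance = int(starts[best] - pos)
        out[str(mid)] = fa
    return out


def mean_assignment_distance(
    assignments: dict[str, FlankAssignment], include_contained: bool = True
) -> float:
    """Mean bp distance over all assigned flanks.

    Contained markers contribute distance 0 when ``include_contained``;
    excluding them gives the mean over genuine flank gaps only (both
    statistics are of interest when summarising assignment distance).
    """
    dists: list[int] = []
    for fa in assignments.values():
        ds = fa.distances()
        if not include_contained and fa.containing is not None:
            continue
        dists.extend(ds)
    return float(np.mean(dists)) if dists else float("nan")


def collect_terms(
    assignments: dict[str, FlankAssignment],
    annot: pd.DataFrame,
    marker_sets: dict[str, list[str]],
) -> pd.DataFrame:
    """De-duplicated GO/EC terms per marker set with gene provenance.

    ``marker_sets`` maps a set label (snpsGWAS, snpsLD, ...) to marker ids.
    Returns a tidy frame (set, term_type, term, genes).
    """
    rows = []
    for set_label, mids in marker_sets.items():
        terms: dict[tuple[str, str], set[str]] = {}
        for mid in mids:
            fa = assignments.get(mid)
            if fa is None:
                continue
            for gene in fa.genes():
                if gene not in annot.index:
                    continue
                for term_type in ("GO", "EC"):
                    raw = str(annot.loc[gene].get(term_type, "") or "")
                    for term in filter(None, raw.split(";")):
                        terms.setdefault((term_type, term), set()).add(gene)
        for (term_type, term), genes in sorted(terms.items()):
            rows.append(
                {
                    "set": set_label,
                    "term_type": term_type,
                    "term": term,
                    "genes": ";".join(sorted(genes)),
                }
            )
    return pd.DataFrame(rows, columns=["set", "term_type", "term", "genes"])


def qtl_overlap(
    markers: pd.DataFrame, qtl_intervals: pd.DataFrame
) -> pd.DataFrame:
    """Markers falling inside QTL intervals (closed-interval containment).

    ``qtl_intervals``: frame with chrom, start, end (1-based inclusive) and
    label columns.  Returns one row per marker with the ;-joined labels of
    the containing intervals and a hit count.
    """
    bad = qtl_intervals["start"] > qtl_intervals["end"]
    if bad.any():
        raise ValueError(
            f"malformed interval(s): {qtl_intervals.loc[bad, 'label'].tolist()}"
        )
    rows = []
    for mid, row in markers.iterrows():
        pos = int(row["pos"])
        hits = qtl_intervals[
            (qtl_intervals["chrom"] == row["chrom"])
            & (qtl_intervals["start"] <= pos)
            & (pos <= qtl_intervals["end"])
        ]
        rows.append(
            {
                "marker": str(mid),
                "qtls": ";".join(hits["label"].astype(str)),
                "n_qtls": len(hits),
            }
        )
    return pd.DataFrame(rows).set_index("marker")
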
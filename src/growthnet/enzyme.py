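"""Enzyme (EC) network from pathway membership, topology and communities.

Every pathway containing a query EC is retrieved and ALL its enzymes become
nodes; a directed edge runs from EC_a to EC_b when, within one pathway, a
product compound of a reaction of EC_a is a substrate of a reaction of EC_b
— currency metabolites (ATP, NADH, water, ...) are excluded so they do not
connect everything to everything.  Five node-level topology measures are
reported (degree, betweenness, stress, eccentricity + mean shortest path,
neighbourhood connectivity), hubs are Tukey-fence degree outliers, and
communities come from multi-resolution modularity with cross-resolution
Jaccard persistence (the pan-resolution idea behind HiDeF).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .simulate import CURRENCY_COMPOUNDS

__all__ = [
    "EnzymeNetwork",
    "TopologyReport",
    "CommunityHierarchy",
    "extract_ec",
    "build_network",
    "topology",
    "detect_hubs",
    "detect_communities",
]

_EC_FULL = re.compile(r"^\d+\.\d+\.\d+\.\d+$")
_EC_PARTIAL = re.compile(r"^\d+\.\d+\.\d+\.-$")


@dataclass
class EnzymeNetwork:
    """Directed EC graph with pathway provenance and an undirected shadow."""

    digraph: nx.DiGraph
    graph: nx.Graph
    query_ecs: set[str]
    pathways: dict[str, set[str]]  # pathway id -> member ECs


@dataclass
class TopologyReport:
    """Per-node topology table plus graph-level summaries.

    ``table`` columns: in_degree, out_degree, degree, betweenness, stress,
    eccentricity, avg_shortest_path, neighborhood_connectivity.  Infinite
    distances (across components) never enter the means; eccentricity is
    within-component.
    """

    table: pd.DataFrame
    n_nodes: int
    n_edges: int
    mean_neighbors: float
    mean_degree_directed: float
    diameter: int


@dataclass
class CommunityHierarchy:
    """Communities persistent across a resolution sweep."""

    communities: dict[str, set[str]]
    resolution_range: dict[str, tuple[float, float]]
    persistence: dict[str, int]
    summaries: pd.DataFrame = field(default_factory=pd.DataFrame)


def extract_ec(annot: pd.DataFrame, genes: list[str] | None = None):
    """Unique valid EC numbers with gene provenance.

    Partial ECs (trailing ``-``) are kept but flagged; malformed strings are
    rejected with a warning; genes without an EC are skipped silently.
    Returns (ec -> genes dict, flagged partial set).
    """
    rows = annot if genes is None else annot.loc[[g for g in genes if g in annot.index]]
    provenance: dict[str, set[str]] = {}
    partial: set[str] = set()
    for gid, row in rows.iterrows():
        raw = str(row.get("EC", "") or "")
        for ec in filter(None, (s.strip() for s in raw.split(";"))):
            if _EC_FULL.match(ec):
                provenance.setdefault(ec, set()).add(str(gid))
            elif _EC_PARTIAL.match(ec):
                provenance.setdefault(ec, set()).add(str(gid))
                partial.add(ec)
            else:
                warnings.warn(f"malformed EC '{ec}' for gene {gid}; rejected",
                              stacklevel=2)
    return provenance, partial


def build_network(
    query_ecs: set[str] | dict[str, set[str]],
    pathway_db: pd.DataFrame,
    currency: tuple[str, ...] = CURRENCY_COMPOUNDS,
    reversible: bool = False,
) -> EnzymeNetwork:
    """Build the EC graph from all pathways containing a query enzyme.

    ``query_ecs`` may carry gene provenance (dict ec -> genes).  Directed
    edges follow product -> substrate compound sharing within each retrieved
    pathway, ignoring currency compounds; with ``reversible`` every edge is
    doubled in the opposite direction.  Disconnected member enzymes remain
    as isolated nodes.
    """
    provenance = query_ecs if isinstance(query_ecs, dict) else {e: set() for e in query_ecs}
    queries = set(provenance)
    currency_set = set(currency)

    pw_members: dict[str, set[str]] = {}
    for pw, grp in pathway_db.groupby("pathway_id"):
        pw_members[pw] = set(grp["ec"])
    retrieved = {pw for pw, members in pw_members.items() if members & queries}
    if not retrieved:
        warnings.warn("no pathway contains any query EC; empty network", stacklevel=2)

    dg = nx.DiGraph()
    for pw in sorted(retrieved):
        grp = pathway_db[pathway_db["pathway_id"] == pw]
        reactions = []
        for _, row in grp.iterrows():
            subs = set(filter(None, str(row["substrates"]).split(";"))) - currency_set
            prods = set(filter(None, str(row["products"]).split(";"))) - currency_set
            reactions.append((row["ec"], subs, prods))
            if row["ec"] not in dg:
                dg.add_node(row["ec"], pathways=set(), genes=set())
            dg.nodes[row["ec"]]["pathways"].add(pw)
        for ec_a, _subs_a, prods_a in reactions:
            for ec_b, subs_b, _prods_b in reactions:
                if ec_a == ec_b:
                    continue
                if prods_a & subs_b:
                    dg.add_edge(ec_a, ec_b)
                    if reversible:
                        dg.add_edge(ec_b, ec_a)
    for ec, genes in provenance.items():
        if ec in dg:
            dg.nodes[ec]["genes"] |= set(genes)
    g = nx.Graph(dg)  # simple undirected shadow, no self-loops by construction
    g.remove_edges_from(nx.selfloop_edges(g))
    return EnzymeNetwork(
        digraph=dg,
        graph=g,
        query_ecs=queries & set(dg.nodes),
        pathways={pw: pw_members[pw] for pw in retrieved},
    )


def _stress_centrality(g: nx.Graph) -> dict:
    """Stress = number of shortest paths through each node (unnormalised).

    Computed from per-source BFS shortest-path counts: sigma_st(v) =
    sigma_sv * sigma_vt when d(s,v) + d(v,t) = d(s,t); each unordered pair
    is counted once.
    """
    nodes = list(g.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    D = np.full((n, n), np.inf)
    S = np.zeros((n, n))
    for v in nodes:
        dist, sig = _bfs_counts(g, v, idx)
        D[idx[v]] = dist
        S[idx[v]] = sig
    stress = {}
    for v in nodes:
        i = idx[v]
        through = (D[:, i][:, None] + D[i, :][None, :]) == D
        cnt = S[:, i][:, None] * S[i, :][None, :]
        cnt = np.where(through & np.isfinite(D), cnt, 0.0)
        cnt[i, :] = 0.0
        cnt[:, i] = 0.0
        np.fill_diagonal(cnt, 0.0)
        stress[v] = int(round(np.triu(cnt, 1).sum()))
    return stress


def _bfs_counts(g: nx.Graph, source, idx):
    n = len(idx)
    dist = np.full(n, np.inf)
    sig = np.zeros(n)
    s = idx[source]
    dist[s] = 0
    sig[s] = 1
    frontier = [source]
    d = 0
    while frontier:
        nxt = []
        for u in frontier:
            for w in g[u]:
                wi = idx[w]
                if np.isinf(dist[wi]):
                    dist[wi] = d + 1
                    nxt.append(w)
                if dist[wi] == d + 1:
                    sig[wi] += sig[idx[u]]
        frontier = nxt
        d += 1
    return dist, sig


def topology(N: EnzymeNetwork) -> TopologyReport:
    """Node-level topology measures and graph-level summaries.

    Degrees come from the directed graph; betweenness (normalised by
    (n-1)(n-2)/2), stress, eccentricity and mean shortest path use the
    undirected simple graph within connected components; neighbourhood
    connectivity is the mean total degree of a node's neighbours; the
    diameter is the largest component's maximum eccentricity.
    """
    dg, g = N.digraph, N.graph
    if len(g) == 0:
        raise ValueError("empty network")
    nodes = list(g.nodes)
    betw = nx.betweenness_centrality(g, normalized=True)
    stress = _stress_centrality(g)
    ecc: dict = {}
    aspl: dict = {}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        e = nx.eccentricity(sub)
        ecc.update(e)
        for v in comp:
            lengths = nx.single_source_shortest_path_length(sub, v)
            others = [d for u, d in lengths.items() if u != v]
            aspl[v] = float(np.mean(others)) if others else 0.0
    total_deg = {v: dg.in_degree(v) + dg.out_degree(v) for v in nodes}
    neigh_conn = {}
    for v in nodes:
        nbrs = list(g[v])
        neigh_conn[v] = float(np.mean([total_deg[u] for u in nbrs])) if nbrs else 0.0
    table = pd.DataFrame(
        {
            "in_degree": [dg.in_degree(v) for v in nodes],
            "out_degree": [dg.out_degree(v) for v in nodes],
            "degree": [total_deg[v] for v in nodes],
            "betweenness": [betw[v] for v in nodes],
            "stress": [stress[v] for v in nodes],
            "eccentricity": [ecc[v] for v in nodes],
            "avg_shortest_path": [aspl[v] for v in nodes],
            "neighborhood_connectivity": [neigh_conn[v] for v in nodes],
        },
        index=pd.Index(nodes, name="ec"),
    )
    comps = list(nx.connected_components(g))
    largest = max(comps, key=len)
    diameter = int(max(ecc[v] for v in largest)) if len(largest) > 1 else 0
    return TopologyReport(
        table=table,
        n_nodes=len(g),
        n_edges=g.number_of_edges(),
        mean_neighbors=float(np.mean([g.degree(v) for v in nodes])),
        mean_degree_directed=float(np.mean(list(total_deg.values()))),
        diameter=diameter,
    )


def detect_hubs(report: TopologyReport, k: float = 1.5) -> list[str]:
    """Degree-outlier hubs by the Tukey fence: degree > Q3 + k * IQR."""
    if report.n_nodes < 4:
        raise ValueError("need >= 4 nodes for the quartile rule")
    deg = report.table["degree"].to_numpy(dtype=float)
    q1, q3 = np.percentile(deg, [25, 75])
    fence = q3 + k * (q3 - q1)
    return sorted(report.table.index[deg > fence])


def detect_communities(
    N: EnzymeNetwork,
    resolutions: np.ndarray | None = None,
    persistence_min: int = 2,
    min_size: int = 4,
    jaccard_min: float = 0.75,
    seed: int = 0,
) -> CommunityHierarchy:
    """Pan-resolution modularity communities with Jaccard persistence.

    Louvain modularity partitions are computed at each resolution of a
    log-spaced grid (default 20 values in [0.1, 10]); communities re-found
    (Jaccard >= ``jaccard_min``) in at least ``persistence_min`` consecutive
    resolutions and holding >= ``min_size`` members are reported, tagged with
    their resolution range.  Per-community betweenness/stress/eccentricity
    summaries are computed on the community-contracted graph.
    """
    g = N.graph
    if g.number_of_edges() == 0:
        warnings.warn("edgeless network; no communities reported", stacklevel=2)
        return CommunityHierarchy(communities={}, resolution_range={}, persistence={})
    if resolutions is None:
        resolutions = np.logspace(np.log10(0.1), np.log10(10.0), 20)

    tracks: list[dict] = []  # {"members", "res": [..], "last_level"}
    for level, gamma in enumerate(resolutions):
        parts = nx.community.louvain_communities(g, resolution=float(gamma), seed=seed)
        for comm in parts:
            comm = set(comm)
            best = None
            for tr in tracks:
                if tr["last_level"] == level - 1 or tr["last_level"] == level:
                    jac = len(comm & tr["members"]) / len(comm | tr["members"])
                    if jac >= jaccard_min and (best is None or jac > best[0]):
                        best = (jac, tr)
            if best is not None and best[1]["last_level"] == level - 1:
                tr = best[1]
                tr["res"].append(float(gamma))
                tr["last_level"] = level
            elif best is None:
                tracks.append(
                    {"members": comm, "res": [float(gamma)], "last_level": level}
                )

    communities: dict[str, set[str]] = {}
    res_range: dict[str, tuple[float, float]] = {}
    persistence: dict[str, int] = {}
    ci = 0
    for tr in tracks:
        if len(tr["res"]) >= persistence_min and len(tr["members"]) >= min_size:
            ci += 1
            label = f"c{ci}"
            communities[label] = set(tr["members"])
            res_range[label] = (min(tr["res"]), max(tr["res"]))
            persistence[label] = len(tr["res"])

    summaries = _community_summaries(g, communities)
    return CommunityHierarchy(
        communities=communities,
        resolution_range=res_range,
        persistence=persistence,
        summaries=summaries,
    )


def _community_summaries(g: nx.Graph, communities: dict[str, set[str]]) -> pd.DataFrame:
    """Topology of the community-contracted graph (one node per community)."""
    if not communities:
        return pd.DataFrame()
    labels = sorted(communities)
    cg = nx.Graph()
    cg.add_nodes_from(labels)
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            if any(
                g.has_edge(u, v) for u in communities[la] for v in communities[lb]
            ):
                cg.add_edge(la, lb)
    betw = nx.betweenness_centrality(cg, normalized=True)
    stress = _stress_centrality(cg)
    ecc = {}
    for comp in nx.connected_components(cg):
        ecc.update(nx.eccentricity(cg.subgraph(comp)))
    return pd.DataFrame(
        {
            "size": [len(communities[la]) for la in labels],
            "betweenness": [betw[la] for la in labels],
            "stress": [stress[la] for la in labels],
            "eccentricity": [ecc[la] for la in labels],
        },
        index=pd.Index(labels, name="community"),
    )
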
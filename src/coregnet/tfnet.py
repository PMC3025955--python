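"""TF co-occurrence network: PCIT edge significance, hubs, filtered views.

TFs that share significantly many targets are linked into a network.  The
columns of the P-matrix are correlated (the phi coefficient, i.e. Pearson on
binary vectors) and the resulting similarity matrix is pruned with the PCIT
(partial correlation with information theory) rule: for every triad
(x, y, z) the three first-order partial correlations are computed, a local
tolerance epsilon is set to the mean of the three partial/direct ratios, and
the edge (x, y) is discarded if some z explains it — |r_xy| <= |eps * r_xz|
and |r_xy| <= |eps * r_yz|.  The triad rejection rule and mean-ratio
tolerance follow the published PCIT algorithm (Reverter & Chan 2008), which
this pipeline invokes by name; they are reference-derived, not invented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .promoterome import CrossProduct, PMatrix, cross_product

#: |r| at or above this is treated as a degenerate (duplicate-column) similarity
CLIP = 1.0 - 1e-12


def column_similarity(P: PMatrix) -> pd.DataFrame:
    """Pearson correlation between the binary TF columns of the P-matrix.

    On 0/1 vectors this is the phi coefficient of the 2x2 co-occurrence
    table.  Constant columns (all-0 or all-1) have undefined similarity and
    yield NaN rows/columns; the diagonal is 1.
    """
    if P.n_tfs < 3:
        raise ValueError("need >= 3 TFs (PCIT partial correlations need triads)")
    X = P.values.astype(float)
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X, rowvar=False)
    R = np.asarray(R)
    R[sd == 0, :] = np.nan
    R[:, sd == 0] = np.nan
    np.fill_diagonal(R, np.where(sd == 0, np.nan, 1.0))
    return pd.DataFrame(R, index=P.tfs, columns=P.tfs)


def pcit_edges(similarity: pd.DataFrame) -> set[tuple]:
    """Significant edges of a similarity matrix under the PCIT triad rule.

    For each pair (x, y), every third variable z defines first-order partial
    correlations r_ab.c = (r_ab - r_ac*r_bc) / sqrt((1-r_ac^2)(1-r_bc^2))
    and a triad tolerance eps = mean of the three |partial/direct| ratios;
    (x, y) is rejected when some z satisfies |r_xy| <= |eps * r_xz| and
    |r_xy| <= |eps * r_yz|.  Pairs with undefined similarity never become
    edges; |r| is clipped just below 1 before the partial-correlation
    division.  Returns unordered label pairs (x < y).
    """
    tfs = list(similarity.index)
    R = similarity.to_numpy(float).copy()
    n = len(tfs)
    if n < 3:
        raise ValueError("PCIT needs at least 3 variables")
    defined = ~np.isnan(R).all(axis=1)
    np.clip(R, -CLIP, CLIP, out=R)
    keep = np.ones((n, n), dtype=bool)
    idx_def = np.flatnonzero(defined)
    Rd = R[np.ix_(idx_def, idx_def)]
    m = len(idx_def)
    with np.errstate(invalid="ignore", divide="ignore"):
        for xi in range(m):
            for yi in range(xi + 1, m):
                r_xy = Rd[xi, yi]
                if np.isnan(r_xy):
                    keep[idx_def[xi], idx_def[yi]] = False
                    continue
                r_xz = Rd[xi, :]
                r_yz = Rd[yi, :]
                ok = ~(np.isnan(r_xz) | np.isnan(r_yz))
                ok[xi] = ok[yi] = False
                # z with a (near-)zero direct correlation to x or y carries no
                # information about the x-y edge and would blow up the
                # partial/direct ratio: skip it
                ok &= (np.abs(r_xz) > 1e-12) & (np.abs(r_yz) > 1e-12)
                if not ok.any():
                    continue
                xz, yz = r_xz[ok], r_yz[ok]
                den_xy = np.sqrt((1 - xz**2) * (1 - yz**2))
                p_xy_z = (r_xy - xz * yz) / den_xy
                p_xz_y = (xz - r_xy * yz) / np.sqrt((1 - r_xy**2) * (1 - yz**2))
                p_yz_x = (yz - r_xy * xz) / np.sqrt((1 - r_xy**2) * (1 - xz**2))
                eps = (np.abs(p_xy_z / r_xy) + np.abs(p_xz_y / xz) + np.abs(p_yz_x / yz)) / 3.0
                reject = (np.abs(r_xy) <= np.abs(eps * xz)) & (np.abs(r_xy) <= np.abs(eps * yz))
                if reject.any():
                    keep[idx_def[xi], idx_def[yi]] = False
    edges = set()
    for xi in range(n):
        if not defined[xi]:
            continue
        for yi in range(xi + 1, n):
            if defined[yi] and keep[xi, yi] and not np.isnan(similarity.iat[xi, yi]):
                edges.add(tuple(sorted((tfs[xi], tfs[yi]))))
    return edges


def build_network(P: PMatrix, corr_accessor=None,
                  module_of: dict | None = None,
                  similarity: pd.DataFrame | None = None,
                  X: CrossProduct | None = None) -> nx.Graph:
    """Assemble the TF network with node and edge attributes.

    Nodes are all TFs (module label and expressed flag as attributes); edges
    are the PCIT-significant co-occurrence pairs carrying the column
    similarity, the shared-target count and, when both TFs have expression
    data, their expression correlation and its sign.
    """
    if similarity is None:
        similarity = column_similarity(P)
    if X is None:
        X = cross_product(P)
    edges = pcit_edges(similarity)
    G = nx.Graph()
    module_of = module_of or {}
    for tf in P.tfs:
        G.add_node(tf, module=module_of.get(tf, ""), expressed=tf in P.expressed_tfs)
    for a, b in sorted(edges):
        attrs = {
            "similarity": float(similarity.loc[a, b]),
            "shared_targets": X.shared_targets(a, b),
        }
        if corr_accessor is not None and a in corr_accessor._index and b in corr_accessor._index:
            r = corr_accessor.r(a, b)
            if not np.isnan(r):
                attrs["r"] = float(r)
                attrs["sign"] = "positive" if r >= 0 else "negative"
        G.add_edge(a, b, **attrs)
    return G


@dataclass
class HubResult:
    hubs: list
    subnetwork: nx.Graph  # induced on hubs + their first neighbors
    tie_flag: bool  # a non-hub shares the cutoff degree
    min_degree: int


def hubs(G: nx.Graph, top_n: int = 10) -> HubResult:
    """Top-n nodes by degree, ties broken lexicographically, plus their
    first-neighborhood subnetwork."""
    if G.number_of_nodes() == 0:
        raise ValueError("empty network")
    ranked = sorted(G.degree, key=lambda kv: (-kv[1], kv[0]))
    chosen = ranked[:top_n]
    hub_names = [n for n, _ in chosen]
    min_deg = chosen[-1][1]
    tie = len(ranked) > top_n and ranked[top_n][1] == min_deg
    neighborhood = set(hub_names)
    for h in hub_names:
        neighborhood.update(G.neighbors(h))
    return HubResult(hub_names, G.subgraph(neighborhood).copy(), tie, min_deg)


def filter_subnetwork(G: nx.Graph, min_abs_r: float = 0.9,
                      min_shared: int = 100) -> nx.Graph:
    """Edges with |expression correlation| > min_abs_r AND shared targets >
    min_shared (strict inequalities); isolated nodes dropped."""
    H = nx.Graph()
    for a, b, attrs in G.edges(data=True):
        r = attrs.get("r")
        if r is None:
            continue
        if abs(r) > min_abs_r and attrs.get("shared_targets", 0) > min_shared:
            H.add_edge(a, b, **attrs)
    for node in H.nodes:
        H.nodes[node].update(G.nodes[node])
    return H


def path_query(G: nx.Graph, sources, target, max_hops: int = 3) -> dict:
    """All simple paths (<= max_hops edges) from each source TF to the target.

    Returns ``{source: [(path, [edge attrs along it]), ...]}``; unknown
    nodes raise.
    """
    if target not in G:
        raise KeyError(f"unknown node: {target!r}")
    out = {}
    for src in sources:
        if src not in G:
            raise KeyError(f"unknown node: {src!r}")
        paths = []
        for path in nx.all_simple_paths(G, src, target, cutoff=max_hops):
            attrs = [dict(G.edges[u, v]) for u, v in zip(path[:-1], path[1:])]
            paths.append((path, attrs))
        out[src] = paths
    return out


def write_edge_list_tsv(G: nx.Graph, path) -> None:
    rows = [(a, b, d.get("similarity"), d.get("shared_targets"), d.get("r"), d.get("sign"))
            for a, b, d in G.edges(data=True)]
    pd.DataFrame(rows, columns=["tf_a", "tf_b", "similarity", "shared_targets",
                                "r", "sign"]).to_csv(path, sep="\t", index=False)


def write_graphml(G: nx.Graph, path) -> None:
    H = G.copy()
    for _, d in H.nodes(data=True):  # graphml cannot hold None
        for k, v in list(d.items()):
            if v is None:
                d[k] = ""
    nx.write_graphml(H, path)
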
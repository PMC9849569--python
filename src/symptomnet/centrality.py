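"""Node centrality: strength and the three bridge indices.

Strength is the absolute sum of a node's edge weights. The bridge indices
quantify a node's role in connecting the depression and anxiety communities:

* bridge strength — absolute sum of a node's cross-community edge weights;
* bridge betweenness — how often a node lies as an intermediate on shortest
  paths between nodes of different communities (tied shortest paths counted
  fractionally by default);
* bridge closeness — inverse mean shortest-path distance to all nodes of the
  other community.

Edge length for shortest paths is 1/|w|, the convention of weighted
psychometric networks; negative edges enter through their magnitude.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pandas as pd

from .datamodel import SymptomNetwork


def strength_centrality(net: SymptomNetwork) -> pd.Series:
    """s_i = sum_j |w_ij|."""
    return pd.Series(np.abs(net.weights).sum(axis=1), index=list(net.nodes),
                     name="strength")


def _distance_graph(net: SymptomNetwork) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(net.nodes)
    p = net.p
    for i in range(p):
        for j in range(i + 1, p):
            w = net.weights[i, j]
            if w != 0:
                G.add_edge(net.nodes[i], net.nodes[j], length=1.0 / abs(w),
                           weight=abs(w))
    return G


def graph_distances(net: SymptomNetwork) -> pd.DataFrame:
    """All-pairs Dijkstra distances with edge length 1/|w|; inf if unreachable."""
    G = _distance_graph(net)
    labels = list(net.nodes)
    D = pd.DataFrame(np.inf, index=labels, columns=labels)
    for src, dists in nx.all_pairs_dijkstra_path_length(G, weight="length"):
        for dst, d in dists.items():
            D.loc[src, dst] = d
    np.fill_diagonal(D.values, 0.0)
    return D


def bridge_centrality(net: SymptomNetwork, fractional: bool = True) -> pd.DataFrame:
    """All four centralities plus z-standardized variants, one row per node.

    ``fractional=False`` switches bridge betweenness from the standard
    fractional tie split to counting every tied shortest path in full.
    A node unreachable from the entire other community gets bridge closeness
    0 and an entry in ``df.attrs['unreachable']``.
    """
    if net.partition is None:
        raise ValueError("bridge centrality requires a two-community partition")
    part = net.partition
    comms = part.communities
    members = {c: [n for n in net.nodes if part.community(n) == c]
               for c in comms}
    G = _distance_graph(net)
    D = graph_distances(net)

    strength = strength_centrality(net)
    idx = {lab: k for k, lab in enumerate(net.nodes)}
    bridge_strength = pd.Series(0.0, index=list(net.nodes))
    for node in net.nodes:
        other = [m for m in net.nodes
                 if part.community(m) != part.community(node)]
        bridge_strength[node] = float(
            np.abs(net.weights[idx[node], [idx[m] for m in other]]).sum()
        )

    betweenness = pd.Series(0.0, index=list(net.nodes))
    a, b = comms
    for s in members[a]:
        for t in members[b]:
            if not math.isfinite(D.loc[s, t]):
                continue
            paths = list(nx.all_shortest_paths(G, s, t, weight="length"))
            sigma = len(paths)
            for path in paths:
                for v in path[1:-1]:
                    betweenness[v] += 1.0 / sigma if fractional else 1.0

    closeness = pd.Series(0.0, index=list(net.nodes))
    unreachable: list[str] = []
    for node in net.nodes:
        other = [m for m in net.nodes
                 if part.community(m) != part.community(node)]
        dists = np.array([D.loc[node, m] for m in other])
        if not np.isfinite(dists).any():
            unreachable.append(node)
        mean = dists.mean()
        closeness[node] = 1.0 / mean if math.isfinite(mean) and mean > 0 else 0.0

    df = pd.DataFrame(
        {
            "strength": strength,
            "bridge_strength": bridge_strength,
            "bridge_betweenness": betweenness,
            "bridge_closeness": closeness,
        }
    )
    for col in list(df.columns):
        sd = df[col].std(ddof=1)
        df[f"z_{col}"] = (df[col] - df[col].mean()) / sd if sd > 0 else 0.0
    df.attrs["unreachable"] = unreachable
    return df
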
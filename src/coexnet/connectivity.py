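"""Differential connectivity (network rewiring) between two conditions.

Each condition's network is summarized by normalized connectivity: the
degree of every gene divided by the maximum degree of that network, so
K ranges over [0, 1].  The rewiring score of gene i is

    DK_i = K_CON(i) - K_RES(i),

z-standardized over the gene universe (union of both node sets by default);
genes with |z| >= 1.96 are called significantly rewired (p < 0.05 under the
normal reference).  Genes present in only one network get K = 0 in the
other -- they are maximally rewired -- unless ``drop_unshared`` is set.

The union ("central reference") network merges both condition networks and
tags every node and edge with its provenance (CON-only / RES-only / shared),
the input expected by rewiring visualizers.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "normalized_connectivity",
    "dk_scores",
    "union_network",
    "connectivity_gain",
]

DK_Z = 1.96


def normalized_connectivity(net: nx.Graph) -> pd.Series:
    """Degree divided by the maximum degree of the network."""
    if net.number_of_edges() == 0:
        raise ValueError("network has no edges; connectivity undefined")
    deg = pd.Series(dict(net.degree()), dtype=float)
    return (deg / deg.max()).rename("K")


def dk_scores(net_con: nx.Graph, net_res: nx.Graph, *,
              drop_unshared: bool = False, center: bool = True,
              z_threshold: float = DK_Z) -> pd.DataFrame:
    """Per-gene DK = K_CON - K_RES with z-scores and significance calls.

    ``center=False`` divides by the SD without subtracting the mean, the
    alternative reading of "transformed into a z-score".
    """
    k_con = normalized_connectivity(net_con)
    k_res = normalized_connectivity(net_res)
    if drop_unshared:
        universe = sorted(set(k_con.index) & set(k_res.index))
    else:
        universe = sorted(set(k_con.index) | set(k_res.index))
    if not universe:
        raise ValueError("no genes in common between the two networks")
    k1 = k_con.reindex(universe).fillna(0.0)
    k2 = k_res.reindex(universe).fillna(0.0)
    dk = k1 - k2
    sd = float(dk.std(ddof=1))
    if sd == 0:
        warnings.warn("DK has zero variance; no significant genes")
        z = pd.Series(0.0, index=dk.index)
    else:
        z = (dk - dk.mean()) / sd if center else dk / sd
    out = pd.DataFrame({
        "k_con_raw": pd.Series(dict(net_con.degree())).reindex(universe).fillna(0).astype(int),
        "k_res_raw": pd.Series(dict(net_res.degree())).reindex(universe).fillna(0).astype(int),
        "k_con": k1, "k_res": k2, "dk": dk, "z": z,
    })
    out["significant"] = out["z"].abs() >= z_threshold
    out.index.name = "gene"
    return out


def union_network(net_con: nx.Graph, net_res: nx.Graph) -> nx.Graph:
    """Edge/node union with CON-only / RES-only / shared provenance tags."""
    g = nx.Graph()
    con_nodes, res_nodes = set(net_con.nodes), set(net_res.nodes)
    for node in con_nodes | res_nodes:
        if node in con_nodes and node in res_nodes:
            prov = "shared"
        elif node in con_nodes:
            prov = "CON-only"
        else:
            prov = "RES-only"
        g.add_node(node, provenance=prov)
    con_edges = {frozenset(e) for e in net_con.edges}
    res_edges = {frozenset(e) for e in net_res.edges}
    for e in con_edges | res_edges:
        a, b = tuple(e)
        if e in con_edges and e in res_edges:
            prov = "shared"
        elif e in con_edges:
            prov = "CON-only"
        else:
            prov = "RES-only"
        src = net_con.edges[a, b] if e in con_edges else net_res.edges[a, b]
        if "weight" in src:
            g.add_edge(a, b, provenance=prov, weight=src["weight"])
        else:
            g.add_edge(a, b, provenance=prov)
    return g


def connectivity_gain(net_con: nx.Graph, net_res: nx.Graph) -> dict:
    """Which condition gained connectivity, plus degree CDF tables.

    Returns a dict with per-condition node/edge counts and mean degrees, the
    sign of the mean-degree difference ("CON", "RES" or "none"), and a tidy
    cumulative-distribution table of degrees per condition.
    """
    rows = []
    summary: dict = {}
    for label, net in (("CON", net_con), ("RES", net_res)):
        deg = np.array([d for _, d in net.degree()], dtype=float)
        mean_deg = float(deg.mean()) if deg.size else 0.0
        summary[label] = {
            "n_nodes": net.number_of_nodes(),
            "n_edges": net.number_of_edges(),
            "mean_degree": mean_deg,
        }
        if deg.size:
            ks = np.sort(np.unique(deg))
            cdf = np.searchsorted(np.sort(deg), ks, side="right") / deg.size
            rows += [{"condition": label, "degree": int(k), "cdf": float(c)}
                     for k, c in zip(ks, cdf)]
    diff = summary["CON"]["mean_degree"] - summary["RES"]["mean_degree"]
    summary["gain"] = "none" if diff == 0 else ("CON" if diff > 0 else "RES")
    summary["mean_degree_diff"] = diff
    summary["cdf"] = pd.DataFrame(rows, columns=["condition", "degree", "cdf"])
    return summary
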
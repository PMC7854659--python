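"""Co-expression network construction and topology statistics.

Builds undirected networks from a normalized expression matrix: Pearson
correlations are screened with PCIT, and surviving pairs with |r| above a
threshold (default 0.9) become edges weighted by the correlation.  Node
attributes record the tissue of maximal expression and DEG/TS/TF membership
flags for downstream coloring and filtering.

Topology statistics follow the usual network-analyzer conventions: degree
(connectivity), global average of local clustering coefficients, per-group
average degree, hubs at mean + 2 SD of the degree distribution, and a
scale-free fit as the R-squared of the log10 frequency vs log10 degree
regression.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .pcit import pcit_edges, pearson_matrix

__all__ = [
    "build_network",
    "network_stats",
    "call_hubs",
    "scale_free_fit",
    "NetworkStats",
]


@dataclass
class NetworkStats:
    degrees: pd.Series                       # per-node degree
    clustering: float                        # global average clustering
    group_mean_degree: pd.Series             # average degree per node group
    scale_free_r2: float                     # NaN when undefined
    hubs: list[str] = field(default_factory=list)
    n_nodes: int = 0
    n_edges: int = 0


def build_network(norm: pd.DataFrame, genes: Iterable[str] | None = None, *,
                  min_abs_r: float = 0.9,
                  threshold_on: str = "raw",
                  require_flag_genes: set[str] | None = None,
                  node_flags: Mapping[str, Mapping[str, bool]] | None = None,
                  node_tissue: Mapping[str, str] | None = None) -> nx.Graph:
    """PCIT-screened co-expression network.

    Parameters
    ----------
    norm : normalized expression, genes x samples.
    genes : subset to use (default: all rows).
    min_abs_r : edges require |correlation| strictly greater than this.
    threshold_on : ``"raw"`` thresholds the raw Pearson correlation of
        PCIT-surviving pairs (the default, standard usage); ``"partial"``
        thresholds the smallest-magnitude first-order partial correlation
        over all conditioning genes instead.
    require_flag_genes : if given, keep only edges touching at least one of
        these genes (the condition-network retention rule: an endpoint must
        be a DEG or TF).
    node_flags : per-gene attribute dict (e.g. is_deg/is_ts/is_tf).
    node_tissue : per-gene tissue of maximal expression, stored as a node
        attribute for coloring.
    """
    if genes is not None:
        genes = [g for g in genes]
        if not genes:
            raise ValueError("empty gene subset")
        missing = [g for g in genes if g not in norm.index]
        if missing:
            raise ValueError(f"gene(s) absent from matrix: {missing[:5]}")
        norm = norm.loc[genes]
    if threshold_on not in ("raw", "partial"):
        raise ValueError(f"threshold_on must be 'raw' or 'partial', got {threshold_on!r}")
    corr = pearson_matrix(norm)
    r = corr.to_numpy()
    mask = pcit_edges(r)
    if threshold_on == "partial":
        strength = _min_abs_partial(r)
    else:
        strength = np.abs(r)
    ids = corr.index.to_numpy()
    g = nx.Graph()
    g.add_nodes_from(ids)
    iu = np.triu_indices(len(ids), k=1)
    keep = mask[iu] & (strength[iu] > min_abs_r)
    for i, j in zip(iu[0][keep], iu[1][keep]):
        a, b = ids[i], ids[j]
        if require_flag_genes is not None and a not in require_flag_genes \
                and b not in require_flag_genes:
            continue
        g.add_edge(a, b, weight=float(r[i, j]))
    for node in g.nodes:
        attrs = dict(node_flags.get(node, {})) if node_flags else {}
        if node_tissue is not None:
            attrs["tissue"] = node_tissue.get(node)
        g.nodes[node].update(attrs)
    g.graph["min_abs_r"] = min_abs_r
    g.graph["threshold_on"] = threshold_on
    return g


def _min_abs_partial(r: np.ndarray) -> np.ndarray:
    """Minimum |first-order partial| of each pair over all conditioning genes."""
    n = r.shape[0]
    out = np.abs(r).copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        sq = np.sqrt(1.0 - r * r)
        for z in range(n):
            rz = r[:, z]
            dz = sq[:, z]
            p = np.abs((r - np.outer(rz, rz)) / (dz[:, None] * dz[None, :]))
            p[z, :] = np.inf
            p[:, z] = np.inf
            np.fill_diagonal(p, np.inf)
            np.fmin(out, p, out=out)
    return out


def network_stats(net: nx.Graph, groups: Mapping[str, str] | None = None,
                  hub_sd: float = 2.0) -> NetworkStats:
    """Degree, clustering, per-group connectivity, hubs and scale-free fit."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    deg = pd.Series(dict(net.degree()), name="degree").sort_index()
    clustering = float(nx.average_clustering(net)) if len(deg) else float("nan")
    if groups:
        grp = pd.Series({n: groups.get(n) for n in deg.index})
        group_mean = deg.groupby(grp).mean()
    else:
        group_mean = pd.Series(dtype=float)
    r2 = scale_free_fit(deg.to_numpy())
    hubs = call_hubs(deg, sd_mult=hub_sd)
    return NetworkStats(degrees=deg, clustering=clustering,
                        group_mean_degree=group_mean, scale_free_r2=r2,
                        hubs=hubs, n_nodes=net.number_of_nodes(),
                        n_edges=net.number_of_edges())


def call_hubs(degrees: pd.Series, sd_mult: float = 2.0) -> list[str]:
    """Nodes whose degree is at least mean + sd_mult * SD of all degrees."""
    if len(degrees) < 3:
        raise ValueError("need at least 3 nodes to call hubs")
    mu = float(degrees.mean())
    sd = float(degrees.std(ddof=1))
    if sd == 0:
        return []
    cut = mu + sd_mult * sd
    return sorted(degrees.index[degrees >= cut])


def scale_free_fit(degrees: np.ndarray | None = None, *,
                   histogram: Mapping[int, float] | None = None) -> float:
    """R-squared of the log10 P(k) on log10 k degree-distribution regression.

    Accepts either a degree sequence or a precomputed ``{degree: count}``
    histogram.  Degrees of zero are excluded (log undefined).  Returns NaN
    when fewer than three distinct positive degrees exist.
    """
    if histogram is None:
        if degrees is None:
            raise ValueError("provide degrees or histogram")
        histogram = Counter(int(k) for k in np.asarray(degrees).ravel())
    ks = np.array([k for k, c in histogram.items() if k > 0 and c > 0], dtype=float)
    cs = np.array([c for k, c in histogram.items() if k > 0 and c > 0], dtype=float)
    if len(ks) < 3:
        return float("nan")
    total = cs.sum()
    res = stats.linregress(np.log10(ks), np.log10(cs / total))
    return float(res.rvalue ** 2)
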
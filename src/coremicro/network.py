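"""Spearman co-occurrence networks and hub-taxon detection.

Edges connect OTU pairs whose relative abundances are strongly rank-
correlated across samples (|rho| > 0.5, p < 0.01 by default, the usual
criterion for "statistically robust" co-occurrence). Hubs are nodes lying in
the joint upper quantile of degree and betweenness centrality.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["build_network", "centralities", "detect_hubs", "edge_table", "node_table"]


def spearman_matrix(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Spearman rho (midrank ties) and two-sided t-approximation p.

    ``values`` is features x samples; returns (rho, p) square matrices.
    """
    n = values.shape[1]
    ranks = np.apply_along_axis(stats.rankdata, 1, values)
    rho = np.corrcoef(ranks)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    p[np.isnan(tstat)] = 0.0  # |rho| == 1 exactly
    return rho, p


def build_network(
    relab,
    rho_min: float = 0.5,
    p_max: float = 0.01,
    adjust: str | None = None,
    node_attrs: pd.DataFrame | None = None,
) -> nx.Graph:
    """Build the co-occurrence graph from a relative-abundance table.

    An undirected edge (i, j) is kept when |rho_ij| > ``rho_min`` and
    p_ij < ``p_max``; ``adjust="bh"`` applies Benjamini-Hochberg to the
    pairwise p-values first. Constant-abundance OTUs (rho undefined) are
    excluded with a warning. All correlatable OTUs appear as nodes whether or
    not they gain edges; ``node_attrs`` rows (e.g. is_core, mra) are copied
    onto the nodes.
    """
    from .diversity import _matrix

    otu_ids, sample_ids, values = _matrix(relab)
    if len(sample_ids) < 5:
        raise ValueError("need at least 5 samples for the p-value approximation")
    keep = ~np.all(values == values[:, :1], axis=1)
    if not keep.all():
        dropped = [o for o, k in zip(otu_ids, keep) if not k]
        warnings.warn(f"constant-abundance OTU(s) excluded: {dropped}")
        values = values[keep]
        otu_ids = [o for o, k in zip(otu_ids, keep) if k]

    rho, p = spearman_matrix(values)
    iu = np.triu_indices(len(otu_ids), k=1)
    rho_flat, p_flat = rho[iu], p[iu]
    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        p_flat = multipletests(p_flat, method="fdr_bh")[1]
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")

    ok = (np.abs(rho_flat) > rho_min) & (p_flat < p_max)
    g = nx.Graph()
    for o in otu_ids:
        g.add_node(o)
    if node_attrs is not None:
        for o in otu_ids:
            if o in node_attrs.index:
                g.nodes[o].update(node_attrs.loc[o].to_dict())
    for a, b, r, q in zip(iu[0][ok], iu[1][ok], rho_flat[ok], p_flat[ok]):
        g.add_edge(
            otu_ids[a], otu_ids[b], rho=float(r), p_value=float(q),
            sign="positive" if r > 0 else "negative",
        )
    return g


def centralities(net: nx.Graph) -> pd.DataFrame:
    """Degree and exact betweenness centrality (raw shortest-path pair counts)."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    degree = dict(net.degree())
    betweenness = nx.betweenness_centrality(net, normalized=False)
    return pd.DataFrame(
        {"degree": pd.Series(degree), "betweenness": pd.Series(betweenness)}
    ).rename_axis("otu_id")


def detect_hubs(net: nx.Graph, quantile: float = 0.95) -> list[str]:
    """Hub OTUs: nodes in the joint upper ``quantile`` of degree AND betweenness.

    A hub must be connected (degree >= 1) and actually lie on shortest paths
    (betweenness > 0): a clique has no hubs even though every node ties at
    the degree cutoff.
    """
    cent = centralities(net)
    deg_cut = cent["degree"].quantile(quantile)
    bet_cut = cent["betweenness"].quantile(quantile)
    hubs = cent[
        (cent["degree"] >= deg_cut)
        & (cent["degree"] >= 1)
        & (cent["betweenness"] >= bet_cut)
        & (cent["betweenness"] > 0)
    ]
    return sorted(hubs.index)


def edge_table(net: nx.Graph) -> pd.DataFrame:
    """Edge list as a tidy frame (source, target, rho, p_value, sign)."""
    rows = [
        (a, b, d.get("rho"), d.get("p_value"), d.get("sign"))
        for a, b, d in net.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["source", "target", "rho", "p_value", "sign"])


def node_table(net: nx.Graph) -> pd.DataFrame:
    """Node attributes joined with degree and betweenness."""
    attrs = pd.DataFrame.from_dict(dict(net.nodes(data=True)), orient="index")
    return attrs.join(centralities(net)).rename_axis("otu_id")
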
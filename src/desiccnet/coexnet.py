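"""Thresholded Pearson co-expression networks with dehydration-state
overlays.

Per tissue: genes are ranked by coefficient of variation (CV = SD/|mean|)
across all of the tissue's samples, the top-k (default 10,000) retained,
all pairwise Pearson correlations computed, and every unordered pair
with |r| strictly greater than the threshold (default 0.964) becomes an
edge. Nodes with no passing edge are excluded — the graph an edge-list
import into Cytoscape would produce. DEG results are overlaid as
per-state node statuses (up/down/unchanged), and state overlays are
compared via active-set sizes, active-subgraph components and Jaccard
similarity — the machinery behind the shoot/root network contrast,
where the root response at 40% RWC stands apart from 60% and <10% RWC.
"""

from __future__ import annotations

import logging
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["rank_by_cv", "select_top_k", "pearson_all_pairs",
           "build_network", "overlay_deg_states", "summarize_states",
           "export_network", "read_network"]

logger = logging.getLogger(__name__)

STATUSES = ("up", "down", "unchanged")


def rank_by_cv(expr: pd.DataFrame, samples: pd.DataFrame, tissue: str,
               eps: float = 1e-8) -> pd.DataFrame:
    """Rank a tissue's genes by coefficient of variation.

    CV is computed across ALL samples of the tissue (states pooled), so
    genes that move across the dehydration series rank high. Genes with
    |mean| < eps are excluded with a warning (CV unstable). Ties are
    broken lexicographically by gene ID; ranks are 1..n, CV descending.
    """
    cols = samples.loc[samples["tissue"] == tissue, "sample_id"].tolist()
    if len(cols) < 3:
        raise ValueError(f"tissue {tissue!r} has {len(cols)} samples; need >= 3")
    sub = expr[cols]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    unstable = mean.abs() < eps
    if unstable.any():
        logger.warning("excluding %d genes with |mean| < %g from CV ranking",
                       int(unstable.sum()), eps)
    ranking = pd.DataFrame({
        "gene": expr.index[~unstable],
        "mean": mean[~unstable].to_numpy(),
        "sd": sd[~unstable].to_numpy(),
    })
    ranking["cv"] = ranking["sd"] / ranking["mean"].abs()
    ranking = ranking.sort_values(["cv", "gene"], ascending=[False, True],
                                  kind="mergesort").reset_index(drop=True)
    ranking["rank"] = np.arange(1, len(ranking) + 1)
    return ranking


def select_top_k(ranking: pd.DataFrame, k: int = 10000) -> list:
    """The k highest-CV genes (all genes, with a warning, if fewer exist)."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > len(ranking):
        logger.warning("requested top %d genes but only %d available",
                       k, len(ranking))
    return ranking["gene"].head(k).tolist()


def pearson_all_pairs(expr_subset: pd.DataFrame) -> pd.DataFrame:
    """Sample Pearson correlation for every unordered gene pair.

    Returns the full symmetric genes x genes correlation matrix.

    Raises
    ------
    ValueError
        On fewer than 3 samples, or if a constant-valued gene (undefined
        correlation) reaches this stage — filter those out first.
    """
    if expr_subset.shape[1] < 3:
        raise ValueError(f"need >= 3 samples, got {expr_subset.shape[1]}")
    x = expr_subset.to_numpy(dtype=float)
    sd = x.std(axis=1)
    if (sd == 0).any():
        bad = expr_subset.index[sd == 0].tolist()
        raise ValueError(
            f"constant genes have undefined correlation: {bad[:5]}"
            + ("..." if len(bad) > 5 else ""))
    r = np.corrcoef(x)
    np.clip(r, -1.0, 1.0, out=r)
    return pd.DataFrame(r, index=expr_subset.index, columns=expr_subset.index)


def build_network(corr: pd.DataFrame, threshold: float = 0.964,
                  tissue: str | None = None) -> nx.Graph:
    """Edges are exactly the pairs with |r| strictly above the threshold.

    Isolated genes are excluded from the node set. The graph carries
    ``tissue`` and ``threshold`` attributes; each edge carries its
    Pearson ``r``.
    """
    # threshold 1.0 is legal and yields an empty network (|r| > 1 never holds)
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    g = nx.Graph(tissue=tissue, threshold=threshold)
    r = corr.to_numpy()
    genes = corr.index.to_numpy()
    iu, ju = np.triu_indices(len(genes), k=1)
    keep = np.abs(r[iu, ju]) > threshold
    g.add_edges_from(
        (genes[i], genes[j], {"r": float(r[i, j])})
        for i, j in zip(iu[keep], ju[keep])
    )
    return g


def overlay_deg_states(network: nx.Graph, deg_tables: dict) -> dict:
    """Per-state node statuses from DEG results.

    ``deg_tables`` maps state -> DEGTable (same tissue as the network).
    Nodes absent from a table, or present but not passing, are
    "unchanged". Returns ``{state: {node: status}}`` covering exactly
    the network's nodes.
    """
    tissue = network.graph.get("tissue")
    nodes = set(network.nodes)
    overlay = {}
    for state, table in deg_tables.items():
        if tissue is not None and len(table) and not (table["tissue"] == tissue).all():
            raise ValueError(
                f"DEG table for state {state!r} is not from tissue {tissue!r}")
        status = dict.fromkeys(nodes, "unchanged")
        hits = table[table["passes"] & table["gene"].isin(nodes)]
        for gene, direction in zip(hits["gene"], hits["direction"]):
            status[gene] = direction
        overlay[state] = status
    return overlay


def _active_sets(network: nx.Graph, status: dict):
    active_nodes = {n for n, s in status.items() if s != "unchanged"}
    active_edges = [(u, v) for u, v in network.edges
                    if status.get(u, "unchanged") == status.get(v, "unchanged")
                    and status.get(u, "unchanged") != "unchanged"]
    return active_nodes, active_edges


def summarize_states(network: nx.Graph, overlay: dict) -> dict:
    """State-wise activity summary of an overlaid network.

    For each state: counts of up/down nodes, active edges (both
    endpoints sharing a non-unchanged status), connected components of
    the active subgraph (isolated active nodes count as singleton
    components), and Jaccard similarity of active node sets between
    states (1.0 for two identical sets, including two empty ones).

    Returns ``{"per_state": DataFrame, "jaccard": DataFrame}``.
    """
    if not overlay:
        raise ValueError("overlay must cover at least one state")
    states = list(overlay)
    rows = []
    active = {}
    for state in states:
        status = overlay[state]
        nodes, edges = _active_sets(network, status)
        active[state] = nodes
        sub = nx.Graph()
        sub.add_nodes_from(nodes)
        sub.add_edges_from(edges)
        rows.append({
            "state": state,
            "n_up": sum(1 for s in status.values() if s == "up"),
            "n_down": sum(1 for s in status.values() if s == "down"),
            "n_active_edges": len(edges),
            "n_components_active": nx.number_connected_components(sub),
        })
    jac = pd.DataFrame(1.0, index=states, columns=states)
    for a, b in combinations(states, 2):
        union = active[a] | active[b]
        j = len(active[a] & active[b]) / len(union) if union else 1.0
        jac.loc[a, b] = jac.loc[b, a] = j
    return {"per_state": pd.DataFrame(rows), "jaccard": jac}


def export_network(network: nx.Graph, overlay: dict | None,
                   edge_list_path, graphml_path) -> None:
    """Write the network as a TSV edge list and as GraphML.

    The edge list has columns (gene_a, gene_b, r), sorted for
    deterministic output. The GraphML carries per-state node statuses
    as ``status_<state>`` attributes and the Pearson r per edge, and is
    loadable by standard graph viewers.
    """
    rows = sorted((min(u, v), max(u, v), d["r"])
                  for u, v, d in network.edges(data=True))
    with open(edge_list_path, "w") as fh:
        fh.write("gene_a\tgene_b\tr\n")
        for u, v, r in rows:
            fh.write(f"{u}\t{v}\t{r!r}\n")

    g = nx.Graph(**network.graph)
    g.add_nodes_from(sorted(network.nodes))
    g.add_edges_from((u, v, {"r": d["r"]})
                     for u, v, d in network.edges(data=True))
    if overlay:
        for state, status in overlay.items():
            nx.set_node_attributes(g, status, f"status_{state}")
    ok = {k: v for k, v in g.graph.items() if v is not None}
    g.graph.clear()
    g.graph.update(ok)
    nx.write_graphml(g, graphml_path)


def read_network(graphml_path) -> nx.Graph:
    """Read a network written by :func:`export_network` (lossless)."""
    g = nx.read_graphml(graphml_path)
    out = nx.Graph(**g.graph)
    if "threshold" in out.graph:
        out.graph["threshold"] = float(out.graph["threshold"])
    out.add_nodes_from(g.nodes(data=True))
    out.add_edges_from((u, v, {"r": float(d["r"])})
                       for u, v, d in g.edges(data=True))
    return out
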
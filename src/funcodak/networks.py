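"""Function-contribution-based microbial correlation networks.

Each taxon is described by the vector of its per-sample percent
contributions to every predicted function (from the independent-contributions
model); pairwise correlation of these vectors across taxa yields a network
whose positive edges link functionally synchronized microbes and negative
edges functionally antagonistic ones. Edges must pass both an absolute
correlation threshold and a multiplicity-adjusted significance threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from funcodak.globalmapper import ContributionMatrix


@dataclass
class NetworkParams:
    method: str = "spearman"
    rho_threshold: float = 0.6
    alpha: float = 0.05
    adjustment: str = "BH"

    def __post_init__(self) -> None:
        if self.method not in ("spearman", "pearson"):
            raise ValueError("method must be 'spearman' or 'pearson'")
        if not 0 <= self.rho_threshold <= 1:
            raise ValueError("rho_threshold must be in [0, 1]")
        if self.adjustment not in ("BH", "bonferroni", "none"):
            raise ValueError("adjustment must be 'BH', 'bonferroni' or 'none'")


@dataclass
class FunctionNetwork:
    """Undirected taxon network with correlation-annotated edges."""

    graph: nx.Graph
    params: NetworkParams
    excluded_taxa: list[str] = field(default_factory=list)  # constant rows

    @property
    def edges(self) -> pd.DataFrame:
        rows = [
            {
                "source": u,
                "target": v,
                "rho": d["rho"],
                "p_adj": d["p_adj"],
                "sign": d["sign"],
            }
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "rho", "p_adj", "sign"])


def contribution_matrix_stack(contrib: ContributionMatrix) -> pd.DataFrame:
    """Stack per-sample contribution matrices into taxa × (samples·functions).

    Each taxon's row is its percent contribution to every function in every
    sample, in a fixed (sample, function) column order; taxa missing from a
    sample contribute zeros. All-zero taxa are kept here and excluded later
    by correlation_network (a constant vector has no defined correlation).
    """
    samples = sorted(contrib.per_sample)
    if len(samples) < 3:
        raise ValueError("need at least 3 samples to correlate contributions")
    all_taxa = sorted({t for s in samples for t in contrib.per_sample[s].index})
    all_funcs = sorted({f for s in samples for f in contrib.per_sample[s].columns})
    blocks = []
    for s in samples:
        mat = contrib.per_sample[s].reindex(index=all_taxa, columns=all_funcs).fillna(0.0)
        mat.columns = pd.MultiIndex.from_product([[s], all_funcs])
        blocks.append(mat)
    return pd.concat(blocks, axis=1)


def correlation_network(
    matrix: pd.DataFrame,
    method: str = "spearman",
    rho_threshold: float = 0.6,
    alpha: float = 0.05,
    adjustment: str = "BH",
    phylum: dict[str, str] | None = None,
) -> FunctionNetwork:
    """Build the taxon correlation network from a stacked profile matrix.

    Pairwise Spearman (or Pearson) correlations over all taxon pairs with
    two-sided p-values; p-values are adjusted over all pairs; an edge is kept
    when |rho| >= rho_threshold and adjusted p <= alpha. Constant rows are
    excluded with a warning record. Node attributes carry phylum (when
    supplied) and degree on the kept edges.
    """
    params = NetworkParams(
        method=method, rho_threshold=rho_threshold, alpha=alpha, adjustment=adjustment
    )
    values = matrix.values.astype(float)
    taxa = list(matrix.index)
    keep = np.ptp(values, axis=1) > 0
    excluded = [t for t, k in zip(taxa, keep) if not k]
    taxa = [t for t, k in zip(taxa, keep) if k]
    values = values[keep]
    if len(taxa) < 2:
        raise ValueError("need at least 2 non-constant taxon rows")
    pairs = [(i, j) for i in range(len(taxa)) for j in range(i + 1, len(taxa))]
    rhos = np.empty(len(pairs))
    pvals = np.empty(len(pairs))
    for k, (i, j) in enumerate(pairs):
        if method == "spearman":
            rho, p = stats.spearmanr(values[i], values[j])
        else:
            rho, p = stats.pearsonr(values[i], values[j])
        rhos[k] = rho
        pvals[k] = p
    pvals = np.nan_to_num(pvals, nan=1.0)
    if adjustment == "BH":
        p_adj = multipletests(pvals, method="fdr_bh")[1]
    elif adjustment == "bonferroni":
        p_adj = np.minimum(pvals * len(pairs), 1.0)
    else:
        p_adj = pvals
    graph = nx.Graph()
    for t in taxa:
        graph.add_node(t, phylum=(phylum or {}).get(t, "Other"))
    for k, (i, j) in enumerate(pairs):
        if np.isnan(rhos[k]):
            continue
        if abs(rhos[k]) >= params.rho_threshold and p_adj[k] <= params.alpha:
            graph.add_edge(
                taxa[i],
                taxa[j],
                rho=float(rhos[k]),
                p_adj=float(p_adj[k]),
                sign="positive" if rhos[k] > 0 else "negative",
            )
    for node in graph.nodes:
        graph.nodes[node]["degree"] = graph.degree(node)
    return FunctionNetwork(graph=graph, params=params, excluded_taxa=excluded)


def network_summary(net: FunctionNetwork) -> dict:
    """Degree per node, density 2E/(n(n-1)), negative-edge count/fraction and
    the highest-degree node(s)."""
    g = net.graph
    n = g.number_of_nodes()
    e = g.number_of_edges()
    density = 0.0 if n < 2 else 2.0 * e / (n * (n - 1))
    degrees = {node: int(d) for node, d in g.degree()}
    n_negative = sum(1 for _, _, d in g.edges(data=True) if d["sign"] == "negative")
    max_deg = max(degrees.values(), default=0)
    hubs = sorted([t for t, d in degrees.items() if d == max_deg and max_deg > 0])
    return {
        "n_nodes": n,
        "n_edges": e,
        "density": density,
        "degrees": degrees,
        "n_negative_edges": n_negative,
        "negative_edge_fraction": (n_negative / e) if e else 0.0,
        "highest_degree_nodes": hubs,
    }


def write_cytoscape(net: FunctionNetwork, out_dir: str | Path, prefix: str = "network") -> list[Path]:
    """Cytoscape-ready exports: an edge table
    (`source  interaction  target  rho  p_adj`) and a node attribute table
    (`taxon  phylum  degree`), rows degree-sorted then name-sorted for a
    stable, deterministic order."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    edge_path = out_dir / f"{prefix}_edges.tsv"
    node_path = out_dir / f"{prefix}_nodes.tsv"
    edges = sorted(
        net.graph.edges(data=True), key=lambda e: tuple(sorted((e[0], e[1])))
    )
    with open(edge_path, "w", encoding="utf-8") as fh:
        fh.write("source\tinteraction\ttarget\trho\tp_adj\n")
        for u, v, d in edges:
            a, b = sorted((u, v))
            fh.write(f"{a}\t{d['sign']}\t{b}\t{d['rho']:.6f}\t{d['p_adj']:.6g}\n")
    nodes = sorted(
        net.graph.nodes(data=True), key=lambda n: (-n[1].get("degree", 0), n[0])
    )
    with open(node_path, "w", encoding="utf-8") as fh:
        fh.write("taxon\tphylum\tdegree\n")
        for t, d in nodes:
            fh.write(f"{t}\t{d.get('phylum', 'Other')}\t{d.get('degree', 0)}\n")
    return [edge_path, node_path]
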
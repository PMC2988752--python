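"""Hub-gene selection on a gene-interaction network.

Given a full interactome (undirected, simple; edges are direct
interactions such as regulation of expression, protein-protein binding or
promoter binding) and a list of top candidate genes, the candidates'
induced subnetwork is extracted and hubs are nominated by two criteria:

* subnetwork degree of at least ``min_degree`` (default 5), and
* local connectivity at least ``ratio_threshold`` (default 2) times the
  gene's overall connectivity, where local connectivity is
  ``degree_sub / (|sub| - 1)`` and overall connectivity is
  ``degree_full / (|full| - 1)`` — densities, so the two are comparable
  across network sizes.  Set ``normalized=False`` to compare raw degrees
  instead.

High-degree candidates that are disproportionately wired *within* the top
list have many downstream targets among the disease signature and are
nominated as putative drivers.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .synthetic import SyntheticTruth

__all__ = [
    "induce_subnetwork",
    "select_hubs",
    "hub_recovery_report",
]


def induce_subnetwork(net: nx.Graph, genes: Iterable[str]) -> nx.Graph:
    """Subnetwork induced by ``genes``, keeping only connected members.

    Nodes are the requested genes present in the network that retain at
    least one edge inside the gene set; edges are those with both
    endpoints in the set.
    """
    members = {str(g).upper() for g in genes} & set(net.nodes)
    sub = net.subgraph(members)
    connected = [n for n in sub.nodes if sub.degree(n) > 0]
    return nx.Graph(sub.subgraph(connected))


def select_hubs(
    sub: nx.Graph,
    full: nx.Graph,
    min_degree: int = 5,
    ratio_threshold: float = 2.0,
    normalized: bool = True,
) -> pd.DataFrame:
    """Apply the degree and connectivity-ratio rule to the subnetwork.

    Returns a DataFrame indexed by gene, sorted by subnetwork degree
    descending (ties by symbol), with columns ``degree_sub``,
    ``degree_full``, ``connectivity_ratio``.
    """
    if sub.number_of_nodes() == 0:
        return pd.DataFrame(
            columns=["degree_sub", "degree_full", "connectivity_ratio"]
        )
    if sub.number_of_nodes() < 2:
        raise ValueError("subnetwork must have >= 2 nodes")
    missing = set(sub.nodes) - set(full.nodes)
    if missing:
        raise ValueError(f"subnetwork nodes absent from full network: {sorted(missing)}")
    n_sub = sub.number_of_nodes()
    n_full = full.number_of_nodes()
    rows = []
    for gene in sub.nodes:
        d_sub = sub.degree(gene)
        d_full = full.degree(gene)
        if normalized:
            local = d_sub / (n_sub - 1)
            overall = d_full / (n_full - 1) if n_full > 1 else 0.0
        else:
            local, overall = float(d_sub), float(d_full)
        ratio = local / overall if overall > 0 else float("inf")
        if d_sub >= min_degree and ratio >= ratio_threshold:
            rows.append((gene, d_sub, d_full, ratio))
    df = pd.DataFrame(
        rows, columns=["gene", "degree_sub", "degree_full", "connectivity_ratio"]
    )
    df = df.sort_values(
        ["degree_sub", "gene"], ascending=[False, True], kind="mergesort"
    )
    return df.set_index("gene")


def hub_recovery_report(
    truth: SyntheticTruth, hubs: Sequence[str]
) -> dict[str, float | bool]:
    """Precision and recall of selected hubs against the planted hub set.

    An empty selection has undefined precision; it is reported as 0 with
    ``precision_defined = False``.
    """
    if not truth.hub_genes:
        raise ValueError("truth has no planted hubs")
    selected = {str(g).upper() for g in hubs}
    planted = set(truth.hub_genes)
    tp = len(selected & planted)
    precision_defined = bool(selected)
    return {
        "precision": tp / len(selected) if selected else 0.0,
        "recall": tp / len(planted),
        "n_selected": float(len(selected)),
        "n_planted": float(len(planted)),
        "precision_defined": precision_defined,
    }
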
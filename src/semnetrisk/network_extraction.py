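"""Significant-subnetwork extraction on a background protein network.

The background protein-interaction network (PIN) is restricted to edges
supported by at least two independent publications to limit false-positive
interactions. The subnetwork induced on genes with a gene-level association
p-value below alpha is extracted, its connected components are ranked, and
the size of the largest component is compared against a null distribution
obtained by shuffling the p-value labels across background nodes and
re-inducing the subnetwork.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ComponentStats:
    n_nodes: int
    n_edges: int
    members: frozenset[str]


@dataclass(frozen=True)
class PermutationNull:
    n_perm: int
    seed: int
    null_nodes: np.ndarray
    null_edges: np.ndarray
    observed_nodes: int
    observed_edges: int
    node_percentile: float
    edge_percentile: float


def build_background(edges: pd.DataFrame, min_pubs: int = 2) -> nx.Graph:
    """Publication-filtered, deduplicated undirected background PIN.

    *edges* needs columns ``protA``, ``protB``, ``n_pubs``. Self-loops are
    dropped; (A,B)/(B,A) duplicates collapse to one undirected edge keeping
    the maximum publication count. Only edges with at least *min_pubs*
    publications are retained, and only their endpoints become nodes.
    """
    required = {"protA", "protB", "n_pubs"}
    if not required <= set(edges.columns):
        raise ValueError(f"edge table missing columns: {sorted(required - set(edges.columns))}")
    bad = edges.index[edges["n_pubs"] < 1]
    if len(bad):
        raise ValueError(f"publication counts must be >= 1 (rows {list(bad[:5])})")
    g = nx.Graph()
    for row in edges.itertuples(index=False):
        a, b = str(row.protA), str(row.protB)
        if a == b:
            continue
        n_pubs = int(row.n_pubs)
        if g.has_edge(a, b):
            g[a][b]["n_pubs"] = max(g[a][b]["n_pubs"], n_pubs)
        else:
            g.add_edge(a, b, n_pubs=n_pubs)
    drop = [(a, b) for a, b, d in g.edges(data=True) if d["n_pubs"] < min_pubs]
    g.remove_edges_from(drop)
    g.remove_nodes_from(list(nx.isolates(g)))
    g.graph["min_pubs"] = min_pubs
    return g


def significant_subnetwork(
    background: nx.Graph, gene_p: Mapping[str, float], alpha: float = 0.05
) -> nx.Graph:
    """Induced subgraph on nodes with p strictly below *alpha*.

    Nodes without a p-value are treated as non-significant. Node attributes
    ``empirical_p`` and ``seed`` (significance flag) are set on the result.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    keep = [n for n in background.nodes if n in gene_p and gene_p[n] < alpha]
    sub = background.subgraph(keep).copy()
    for n in sub.nodes:
        sub.nodes[n]["empirical_p"] = float(gene_p[n])
        sub.nodes[n]["seed"] = True
    sub.graph["alpha"] = alpha
    return sub


def components(network: nx.Graph) -> list[ComponentStats]:
    """Connected components sorted by (n_nodes, n_edges) descending."""
    stats = []
    for comp in nx.connected_components(network):
        sub = network.subgraph(comp)
        stats.append(
            ComponentStats(
                n_nodes=sub.number_of_nodes(),
                n_edges=sub.number_of_edges(),
                members=frozenset(comp),
            )
        )
    stats.sort(key=lambda c: (-c.n_nodes, -c.n_edges, sorted(c.members)[0]))
    return stats


def _largest_component_size(adj: dict[str, list[str]], keep: set[str]) -> tuple[int, int]:
    """(nodes, edges) of the largest component of the subgraph induced on *keep*."""
    best = (0, 0)
    seen: set[str] = set()
    for start in keep:
        if start in seen:
            continue
        comp_nodes = 0
        degree_sum = 0
        stack = [start]
        seen.add(start)
        while stack:
            u = stack.pop()
            comp_nodes += 1
            for v in adj[u]:
                if v in keep:
                    degree_sum += 1
                    if v not in seen:
                        seen.add(v)
                        stack.append(v)
        cand = (comp_nodes, degree_sum // 2)
        if cand > best:
            best = cand
    return best


def permutation_test(
    background: nx.Graph,
    gene_p: Mapping[str, float],
    alpha: float = 0.05,
    n_perm: int = 1_000,
    seed: int = 0,
) -> PermutationNull:
    """Label-shuffling null for the largest significant component.

    Each permutation shuffles the observed p-values across all background
    nodes that have one, re-induces the significant subnetwork and records
    the largest component's node and edge counts. The observed percentile
    is ``100 * #{null strictly below observed} / n_perm``; ties count
    against significance.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    nodes_with_p = [n for n in background.nodes if n in gene_p]
    values = np.array([gene_p[n] for n in nodes_with_p], dtype=float)
    adj = {n: list(background.neighbors(n)) for n in background.nodes}

    obs_keep = {n for n, p in zip(nodes_with_p, values) if p < alpha}
    obs_nodes, obs_edges = _largest_component_size(adj, obs_keep)

    null_nodes = np.empty(n_perm, dtype=int)
    null_edges = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        perm = rng.permutation(values)
        keep = {n for n, p in zip(nodes_with_p, perm) if p < alpha}
        null_nodes[i], null_edges[i] = _largest_component_size(adj, keep)

    return PermutationNull(
        n_perm=n_perm,
        seed=seed,
        null_nodes=null_nodes,
        null_edges=null_edges,
        observed_nodes=obs_nodes,
        observed_edges=obs_edges,
        node_percentile=100.0 * float(np.count_nonzero(null_nodes < obs_nodes)) / n_perm,
        edge_percentile=100.0 * float(np.count_nonzero(null_edges < obs_edges)) / n_perm,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Read a PIN edge list TSV (protA, protB, n_pubs) with line-level checks."""
    rows = []
    errors = []
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t") if lines else []
    if header[:3] != ["protA", "protB", "n_pubs"]:
        raise ValueError(f"{path}: expected header protA\\tprotB\\tn_pubs")
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            errors.append(f"line {ln}: fewer than 3 columns")
            continue
        try:
            rows.append({"protA": parts[0], "protB": parts[1], "n_pubs": int(parts[2])})
        except ValueError:
            errors.append(f"line {ln}: non-integer publication count {parts[2]!r}")
    if errors:
        raise ValueError(f"{path}: malformed edge rows: " + "; ".join(errors[:10]))
    return pd.DataFrame(rows)


def write_edge_list(network: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protA\tprotB\tn_pubs\n")
        for a, b, d in sorted(network.edges(data=True)):
            fh.write(f"{a}\t{b}\t{d.get('n_pubs', 1)}\n")


def write_graphml(network: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(network, str(path))


def write_component_report(stats: list[ComponentStats], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"rank": i + 1, "n_nodes": c.n_nodes, "n_edges": c.n_edges,
             "members": ",".join(sorted(c.members))}
            for i, c in enumerate(stats)
        ]
    ).to_csv(path, sep="\t", index=False)


def write_permutation_summary(null: PermutationNull, tsv_path: str | Path, json_path: str | Path) -> None:
    pd.DataFrame(
        {"null_nodes": null.null_nodes, "null_edges": null.null_edges}
    ).to_csv(tsv_path, sep="\t", index=False)
    summary = {
        "n_perm": null.n_perm,
        "seed": null.seed,
        "observed_nodes": null.observed_nodes,
        "observed_edges": null.observed_edges,
        "node_percentile": null.node_percentile,
        "edge_percentile": null.edge_percentile,
    }
    Path(json_path).write_text(json.dumps(summary, indent=2) + "\n")
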
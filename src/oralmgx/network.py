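"""Per-condition species co-occurrence networks and their comparison.

Species passing a mean-relative-abundance floor (0.01%) within the
condition's samples are correlated all-against-all with Spearman's rho;
p-values (t-approximation, exact permutation below 10 samples) are BH
adjusted across all tested pairs, and an edge is kept when |rho| > 0.6
and q < 0.05, with its sign recorded. Node topology uses unweighted
shortest paths: degree, betweenness (fractional over equal-length paths,
endpoints excluded) and closeness defined as 1 / (summed distance to the
nodes reachable within the component); isolated nodes get closeness 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations as _permutations
from math import factorial

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

from .diffabund import bh_adjust

EXACT_MAX_N = 9  # exact Spearman permutation p below 10 samples


@dataclass
class CooccurrenceNetwork:
    condition: str
    graph: nx.Graph  # nodes carry mean_abundance; edges carry rho, q, sign
    n_samples: int

    @property
    def edges(self) -> pd.DataFrame:
        rows = [
            (a, b, d["rho"], d["q"], d["sign"])
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["species_a", "species_b", "rho", "q", "sign"])

    def edge_set(self) -> set:
        return {frozenset((a, b)) for a, b in self.graph.edges()}


def spearman_pvalue(x, y) -> tuple[float, float]:
    """Spearman rho and two-sided p; exact permutation null when n < 10,
    t-approximation otherwise. Constant inputs give (0, 1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return 0.0, 1.0
    n = len(x)
    if n <= EXACT_MAX_N:
        rx = rankdata(x) - (n + 1) / 2
        ry = rankdata(y) - (n + 1) / 2
        denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
        rho = float(rx @ ry / denom)
        count = 0
        for perm in _permutations(range(n)):
            if abs(rx[list(perm)] @ ry / denom) >= abs(rho) - 1e-12:
                count += 1
        return rho, count / factorial(n)
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def build_network(
    matrix: pd.DataFrame,
    condition_samples,
    condition: str = "",
    min_abundance: float = 1e-4,
    rho_min: float = 0.6,
    fdr_max: float = 0.05,
) -> CooccurrenceNetwork:
    """Co-occurrence network for one condition's samples.

    The abundance floor is applied to the *mean* relative abundance over
    the condition's samples. Every emitted edge satisfies |rho| > rho_min
    and BH q < fdr_max.
    """
    condition_samples = list(condition_samples)
    if len(condition_samples) < 5:
        raise ValueError("need at least 5 samples to build a network")
    sub = matrix[condition_samples]
    keep = sub.mean(axis=1) >= min_abundance
    sub = sub.loc[keep]
    species = list(sub.index)
    n_samples = sub.shape[1]
    X = sub.to_numpy(dtype=float)

    graph = nx.Graph()
    for sid, mean_ab in zip(species, sub.mean(axis=1)):
        graph.add_node(sid, mean_abundance=float(mean_ab))

    if len(species) >= 2:
        if n_samples > EXACT_MAX_N:
            constant = np.array([len(np.unique(row)) == 1 for row in X])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", stats.ConstantInputWarning)
                rho_mat, p_mat = stats.spearmanr(X.T)
            if np.ndim(rho_mat) == 0:  # scipy collapses the 2-variable case
                rho_mat = np.array([[1.0, rho_mat], [rho_mat, 1.0]])
                p_mat = np.array([[0.0, p_mat], [p_mat, 0.0]])
        iu = np.triu_indices(len(species), k=1)
        rows = []
        for i, j in zip(*iu):
            if n_samples > EXACT_MAX_N:
                if constant[i] or constant[j]:
                    rho, p = 0.0, 1.0
                else:
                    rho, p = float(rho_mat[i, j]), float(p_mat[i, j])
                    if np.isnan(p):
                        rho, p = 0.0, 1.0
            else:
                rho, p = spearman_pvalue(X[i], X[j])
            rows.append((species[i], species[j], rho, p))
        frame = pd.DataFrame(rows, columns=["a", "b", "rho", "p"])
        frame["q"] = bh_adjust(frame["p"].to_numpy())
        hits = frame[(frame["rho"].abs() > rho_min) & (frame["q"] < fdr_max)]
        for _, row in hits.iterrows():
            graph.add_edge(
                row["a"],
                row["b"],
                rho=float(row["rho"]),
                q=float(row["q"]),
                sign="positive" if row["rho"] > 0 else "negative",
            )
    return CooccurrenceNetwork(condition=condition, graph=graph, n_samples=n_samples)


def node_topology(net: CooccurrenceNetwork | nx.Graph) -> pd.DataFrame:
    """Degree, betweenness and closeness per node (conventions in the
    module docstring)."""
    graph = net.graph if isinstance(net, CooccurrenceNetwork) else net
    betweenness = nx.betweenness_centrality(graph, normalized=False)
    rows = []
    for node in graph.nodes():
        lengths = nx.single_source_shortest_path_length(graph, node)
        total = sum(d for d in lengths.values() if d > 0)
        closeness = 1.0 / total if total > 0 else 0.0
        rows.append((node, graph.degree(node), betweenness[node], closeness))
    return pd.DataFrame(
        rows, columns=["species_id", "degree", "betweenness", "closeness"]
    ).set_index("species_id")


def _genus(species_id: str) -> str:
    return str(species_id).split("_", 1)[0]


def compare_networks(
    net_a: CooccurrenceNetwork,
    net_b: CooccurrenceNetwork,
    main_cluster_min_nodes: int = 10,
    genus_map: dict | None = None,
) -> dict:
    """Compare two condition networks: shared-edge fraction relative to
    each network, rank-sum tests on the node-topology distributions, and
    the main connected components (> ``main_cluster_min_nodes`` nodes)
    summarised by their most frequent genera."""
    edges_a, edges_b = net_a.edge_set(), net_b.edge_set()
    shared = edges_a & edges_b
    report: dict = {
        "n_edges_a": len(edges_a),
        "n_edges_b": len(edges_b),
        "shared_fraction_a": len(shared) / len(edges_a) if edges_a else float("nan"),
        "shared_fraction_b": len(shared) / len(edges_b) if edges_b else float("nan"),
    }
    topo_a, topo_b = node_topology(net_a), node_topology(net_b)
    for metric in ("degree", "betweenness", "closeness"):
        va, vb = topo_a[metric].to_numpy(), topo_b[metric].to_numpy()
        if len(va) == 0 or len(vb) == 0:
            report[f"{metric}_p"] = float("nan")
        elif np.array_equal(np.sort(va), np.sort(vb)):
            report[f"{metric}_p"] = 1.0
        else:
            report[f"{metric}_p"] = float(
                stats.mannwhitneyu(va, vb, alternative="two-sided").pvalue
            )
    for name, net in (("a", net_a), ("b", net_b)):
        clusters = []
        for comp in nx.connected_components(net.graph):
            if len(comp) > main_cluster_min_nodes:
                genera = pd.Series(
                    [genus_map.get(s, _genus(s)) if genus_map else _genus(s) for s in comp]
                )
                clusters.append(
                    {
                        "n_nodes": len(comp),
                        "top_genera": genera.value_counts().head(5).index.tolist(),
                    }
                )
        report[f"main_clusters_{name}"] = clusters
    return report
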
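"""Molecular ecological networks (MENs) and their stability.

Networks are built per sample stratum from Spearman rank correlations
of taxon relative abundances: an edge joins two taxa whose correlation
magnitude reaches ``r_min`` with a p-value under ``p_max`` (both signs
kept, sign stored on the edge).  On top of the usual topological
attributes the module computes two stability measures:

* **Relative modularity** ``RM = (Q_emp - mean(Q_null)) / mean(Q_null)``
  where the nulls are Erdős–Rényi graphs with the empirical node and
  edge counts, scored by the same community detection.
* **Vulnerability** ``Vul = max_i (E - E_-i) / E`` — the worst-case
  relative loss of global efficiency when a single node is removed —
  tracked along an extinction simulation that removes growing random
  fractions of nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from aquassembly.io import AbundanceTable


@dataclass
class CorrelationScreen:
    """All-pairs rank correlations with two-sided p-values.

    Pairs involving a constant taxon have undefined correlation and are
    stored as NaN; they can never pass the edge thresholds.
    """

    taxon_ids: list[str]
    rho: np.ndarray
    p_value: np.ndarray
    method: str = "spearman"


@dataclass
class NetworkTopology:
    n: int
    L: int
    connectance: float
    mean_clustering: float
    n_components: int
    centralization_degree: float
    centralization_betweenness: float
    centralization_closeness: float
    modularity: float
    module_assignment: dict = field(default_factory=dict)
    n_modules: int = 0

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "L": self.L,
            "connectance": self.connectance,
            "mean_clustering": self.mean_clustering,
            "n_components": self.n_components,
            "centralization_degree": self.centralization_degree,
            "centralization_betweenness": self.centralization_betweenness,
            "centralization_closeness": self.centralization_closeness,
            "modularity": self.modularity,
            "n_modules": self.n_modules,
        }


@dataclass
class StabilityMetrics:
    relative_modularity: float
    vulnerability: float
    extinction_curve: list
    q_null: np.ndarray | None = None
    n_null: int = 0
    seed: int | None = None


def correlation_screen(
    table: AbundanceTable, method: str = "spearman"
) -> CorrelationScreen:
    """Pairwise Spearman correlation of taxa across samples.

    Uses midranks for ties and the large-sample t approximation for
    two-sided p-values.
    """
    if method != "spearman":
        raise ValueError("only the spearman method is supported")
    if table.n_samples < 4:
        raise ValueError("need at least 4 samples for a correlation screen")
    if table.n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    n = table.n_samples
    ranks = np.apply_along_axis(stats.rankdata, 0, table.abundance)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns yield NaN
        rho = np.corrcoef(ranks, rowvar=False)
        # two-sided p from the large-sample t approximation
        r = np.clip(rho, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(r) >= 1.0 - 1e-15] = 0.0
    p[np.isnan(rho)] = np.nan
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    return CorrelationScreen(list(table.taxon_ids), rho, p, method)


def build_network(
    screen: CorrelationScreen, r_min: float = 0.8, p_max: float = 0.05
) -> nx.Graph:
    """Threshold a correlation screen into a simple undirected graph.

    Edge iff ``|rho| >= r_min`` and ``p < p_max``; NaN correlations
    never qualify.  Isolated taxa stay in the graph as nodes.
    """
    if not (0 < r_min <= 1 and 0 < p_max <= 1):
        raise ValueError("thresholds must lie in (0, 1]")
    g = nx.Graph()
    g.add_nodes_from(screen.taxon_ids)
    rho, p = screen.rho, screen.p_value
    n = len(screen.taxon_ids)
    iu, ju = np.triu_indices(n, k=1)
    ok = (
        ~np.isnan(rho[iu, ju])
        & (np.abs(rho[iu, ju]) >= r_min)
        & (p[iu, ju] < p_max)
    )
    for i, j in zip(iu[ok], ju[ok]):
        g.add_edge(
            screen.taxon_ids[i],
            screen.taxon_ids[j],
            rho=float(rho[i, j]),
            p=float(p[i, j]),
        )
    return g


def detect_modules(g: nx.Graph, seed: int | None = None):
    """Greedy modularity maximization (Clauset–Newman–Moore).

    Deterministic for a given node order; the seed argument is accepted
    for interface uniformity but unused.  Returns ``(assignment, Q)``
    where the edgeless graph gets one singleton module per node and
    Q = 0 by convention.
    """
    del seed
    if g.number_of_edges() == 0:
        return {node: i for i, node in enumerate(g.nodes)}, 0.0
    communities = nx.community.greedy_modularity_communities(g)
    assignment = {
        node: idx for idx, comm in enumerate(communities) for node in comm
    }
    q = nx.community.modularity(g, communities)
    return assignment, float(q)


def _freeman_centralization(values: dict, denominator: float) -> float:
    if denominator <= 0:
        return 0.0
    vmax = max(values.values())
    return sum(vmax - v for v in values.values()) / denominator


def topology(g: nx.Graph, seed: int | None = None) -> NetworkTopology:
    """Standard topological attributes plus modules and modularity.

    Centralizations follow Freeman's normalization: the sum of
    differences from the most central node over the maximum that sum
    attains on any graph of the same size (a star for all three
    measures).  "Number of clusters" counts connected components, which
    is distinct from the number of modules.
    """
    n = g.number_of_nodes()
    if n < 1:
        raise ValueError("empty graph")
    L = g.number_of_edges()
    if n < 2:
        warnings.warn("centralization undefined for n < 2; reporting 0")
        assignment, q = detect_modules(g, seed)
        return NetworkTopology(n, L, 0.0, 0.0, n, 0.0, 0.0, 0.0, q,
                               assignment, len(set(assignment.values())))
    connectance = 2.0 * L / (n * (n - 1))
    clustering = nx.average_clustering(g) if n > 0 else 0.0
    ncomp = nx.number_connected_components(g)
    degree = dict(g.degree())
    c_deg = _freeman_centralization(degree, (n - 1) * (n - 2)) if n > 2 else 0.0
    betw = nx.betweenness_centrality(g, normalized=False)
    c_betw = (
        _freeman_centralization(betw, (n - 1) ** 2 * (n - 2) / 2.0)
        if n > 2
        else 0.0
    )
    clos = nx.closeness_centrality(g)
    c_clos = (
        _freeman_centralization(clos, (n - 1) * (n - 2) / (2.0 * n - 3.0))
        if n > 2
        else 0.0
    )
    assignment, q = detect_modules(g, seed)
    return NetworkTopology(
        n=n,
        L=L,
        connectance=connectance,
        mean_clustering=clustering,
        n_components=ncomp,
        centralization_degree=c_deg,
        centralization_betweenness=c_betw,
        centralization_closeness=c_clos,
        modularity=q,
        module_assignment=assignment,
        n_modules=len(set(assignment.values())),
    )


def relative_modularity(
    g: nx.Graph,
    n_null: int = 100,
    seed: int | None = None,
    null_model: str = "erdos-renyi",
) -> StabilityMetrics:
    """Empirical modularity against size-matched random-graph nulls.

    ``RM = (Q_emp - mean(Q_null)) / mean(Q_null)``.  The default null
    is G(n, L) with the empirical node and edge counts; a
    degree-preserving rewiring null is available via
    ``null_model='rewire'``.
    """
    L = g.number_of_edges()
    if L < 1:
        raise ValueError("relative modularity needs at least one edge")
    n = g.number_of_nodes()
    rng = np.random.default_rng(seed)
    q_null = np.empty(n_null)
    for k in range(n_null):
        sub = int(rng.integers(0, 2**31 - 1))
        if null_model == "erdos-renyi":
            null = nx.gnm_random_graph(n, L, seed=sub)
        elif null_model == "rewire":
            null = nx.Graph(g)
            nswap = max(1, 10 * L)
            try:
                nx.double_edge_swap(null, nswap=nswap, max_tries=50 * nswap,
                                    seed=sub)
            except nx.NetworkXError:
                pass  # too few swappable edges; score the graph as-is
        else:
            raise ValueError(f"unknown null model {null_model!r}")
        _, q_null[k] = detect_modules(null)
    mean_null = float(q_null.mean())
    if mean_null == 0:
        raise ValueError("degenerate null: mean null modularity is zero")
    _, q_emp = detect_modules(g)
    rm = (q_emp - mean_null) / mean_null
    return StabilityMetrics(
        relative_modularity=float(rm),
        vulnerability=float("nan"),
        extinction_curve=[],
        q_null=q_null,
        n_null=n_null,
        seed=seed,
    )


def global_efficiency(g: nx.Graph) -> float:
    """Mean over node pairs of reciprocal shortest-path length.

    Disconnected pairs contribute zero; 1 for a complete graph, 0 for
    an edgeless one.
    """
    if g.number_of_nodes() < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    return float(nx.global_efficiency(g))


def vulnerability(g: nx.Graph) -> float:
    """Worst-case relative efficiency loss from a single extinction.

    ``Vul = max_i (E - E_-i) / E``; raises if the network has zero
    efficiency to start with.  Zero for complete graphs (removal leaves
    a complete graph) and 1 when removing a cut hub disconnects
    everything, as in a star.
    """
    e0 = global_efficiency(g)
    if e0 == 0:
        raise ValueError("vulnerability undefined for zero-efficiency graph")
    worst = -np.inf
    for node in g.nodes:
        h = g.copy()
        h.remove_node(node)
        e = nx.global_efficiency(h) if h.number_of_nodes() >= 2 else 0.0
        worst = max(worst, (e0 - e) / e0)
    return float(worst)


def extinction_simulation(
    g: nx.Graph,
    fractions=None,
    n_repeats: int = 50,
    seed: int | None = None,
) -> list[dict]:
    """Vulnerability of the residual network under random extinctions.

    For each removal fraction, ``round(fraction * n)`` nodes are deleted
    uniformly at random and the vulnerability of what remains is
    recorded; draws whose residual efficiency is zero are skipped but
    counted.  Fraction 0 is the deterministic vulnerability of the
    intact network.
    """
    if fractions is None:
        fractions = [round(0.1 * k, 1) for k in range(10)]
    fractions = sorted(float(x) for x in fractions)
    if global_efficiency(g) == 0:
        raise ValueError("extinction simulation needs positive efficiency")
    rng = np.random.default_rng(seed)
    nodes = list(g.nodes)
    n = len(nodes)
    curve = []
    for frac in fractions:
        n_remove = int(round(frac * n))
        if n_remove == 0:
            v = vulnerability(g)
            curve.append({"fraction": frac, "mean": v, "sd": 0.0,
                          "n_repeats": n_repeats, "n_skipped": 0})
            continue
        vals = []
        skipped = 0
        for _ in range(n_repeats):
            drop = rng.choice(n, size=n_remove, replace=False)
            h = g.copy()
            h.remove_nodes_from(nodes[i] for i in drop)
            if h.number_of_nodes() < 2 or nx.global_efficiency(h) == 0:
                skipped += 1
                continue
            vals.append(vulnerability(h))
        entry = {"fraction": frac, "n_repeats": n_repeats, "n_skipped": skipped}
        if vals:
            entry["mean"] = float(np.mean(vals))
            entry["sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        else:
            entry["mean"] = None
            entry["sd"] = None
        curve.append(entry)
    return curve


def network_stability(
    g: nx.Graph,
    n_null: int = 100,
    n_repeats: int = 50,
    fractions=None,
    seed: int | None = None,
) -> StabilityMetrics:
    """Convenience wrapper: RM, Vul, and the extinction curve together."""
    rm = relative_modularity(g, n_null=n_null, seed=seed)
    rm.vulnerability = vulnerability(g)
    rm.extinction_curve = extinction_simulation(
        g, fractions=fractions, n_repeats=n_repeats,
        seed=None if seed is None else seed + 1,
    )
    return rm


def write_edge_list(g: nx.Graph, path) -> None:
    """Edge list TSV: node_a, node_b, rho, p."""
    import pandas as pd

    rows = [
        {"node_a": a, "node_b": b,
         "rho": data.get("rho"), "p": data.get("p")}
        for a, b, data in g.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["node_a", "node_b", "rho", "p"]).to_csv(
        path, sep="\t", index=False
    )
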
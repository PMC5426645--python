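"""Protein centrality measures and essential-protein evaluation.

Six centralities are registered: degree (DC), betweenness (BC), closeness
(CC, component-restricted with Wasserman–Faust scaling), eigenvector (EC),
subgraph centrality (SC, the diagonal of exp(A)) and the edge-clustering-
coefficient sum (NC).  NC sums, over a protein's incident edges, the edge
clustering coefficient ECC(u, v) = z(u, v) / min(d_u - 1, d_v - 1) where
z is the number of triangles through the edge (ECC = 0 when the
denominator vanishes).  Proteins are ranked by descending score, and
rankings are evaluated against a gold-standard essential set via top-k
counts, precision-recall points and the jackknife (cumulative hits) curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import networkx as nx
import numpy as np
import pandas as pd
import scipy.linalg

from .net_io import PPINetwork, ProteinList


def degree_centrality(g: nx.Graph) -> dict[str, float]:
    return {n: float(d) for n, d in g.degree()}


def betweenness(g: nx.Graph) -> dict[str, float]:
    return nx.betweenness_centrality(g, normalized=True)


def closeness(g: nx.Graph) -> dict[str, float]:
    # Wasserman–Faust: component-restricted closeness scaled by
    # (component size - 1) / (N - 1); finite on disconnected graphs.
    return nx.closeness_centrality(g, wf_improved=True)


def eigenvector(g: nx.Graph, tol: float = 1e-10, max_iter: int = 100000) -> dict[str, float]:
    """Principal-eigenvector centrality by power iteration, nonnegative
    (Perron) sign convention."""
    nodes = sorted(g.nodes)
    if not nodes:
        return {}
    a = nx.to_numpy_array(g, nodelist=nodes)
    v = np.full(len(nodes), 1.0 / np.sqrt(len(nodes)))
    for _ in range(max_iter):
        w = a @ v
        norm = np.linalg.norm(w)
        if norm == 0.0:  # empty graph
            return {n: 0.0 for n in nodes}
        w /= norm
        if np.abs(w - v).max() < tol:
            v = w
            break
        v = w
    v = np.abs(v)
    return {n: float(v[i]) for i, n in enumerate(nodes)}


def subgraph_centrality(g: nx.Graph) -> dict[str, float]:
    """SC(i) = sum_k (A^k)_ii / k! = [exp(A)]_ii via symmetric
    eigendecomposition of the adjacency matrix."""
    nodes = sorted(g.nodes)
    if not nodes:
        return {}
    a = nx.to_numpy_array(g, nodelist=nodes)
    lam, q = scipy.linalg.eigh(a)
    sc = (q**2) @ np.exp(lam)
    return {n: float(sc[i]) for i, n in enumerate(nodes)}


def edge_clustering_coefficient(g: nx.Graph, u: str, v: str) -> float:
    du, dv = g.degree(u), g.degree(v)
    denom = min(du - 1, dv - 1)
    if denom <= 0:
        return 0.0
    z = len(set(g[u]) & set(g[v]))
    return z / denom


def network_centrality(g: nx.Graph) -> dict[str, float]:
    """NC(u) = sum over neighbors v of ECC(u, v)."""
    return {
        u: sum(edge_clustering_coefficient(g, u, v) for v in g[u]) for u in g.nodes
    }


REGISTRY: dict[str, Callable[[nx.Graph], dict[str, float]]] = {
    "DC": degree_centrality,
    "BC": betweenness,
    "CC": closeness,
    "EC": eigenvector,
    "SC": subgraph_centrality,
    "NC": network_centrality,
}


def centrality(net: PPINetwork | nx.Graph, method: str) -> dict[str, float]:
    """Score every protein under one registered centrality measure."""
    if method not in REGISTRY:
        raise ValueError(
            f"unknown method {method!r}; registered: {sorted(REGISTRY)}"
        )
    g = net.to_networkx() if isinstance(net, PPINetwork) else net
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    return REGISTRY[method](g)


@dataclass
class CentralityRanking:
    """Descending ranking of proteins by centrality score.

    Ties are broken by lexicographic protein ID; ranks are 1-based."""

    method: str
    entries: list[tuple[str, float, int]]  # (protein, score, rank)
    tie_break: str = "lexicographic"

    def __post_init__(self) -> None:
        self._rank_of = {p: r for p, _s, r in self.entries}

    def rank_of(self, protein: str) -> int | None:
        return self._rank_of.get(protein)

    def top(self, k: int) -> list[str]:
        if k > len(self.entries):
            raise ValueError(f"cutoff {k} exceeds ranking length {len(self.entries)}")
        return [p for p, _s, _r in self.entries[:k]]

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["protein", "score", "rank"])


def rank(scores: dict[str, float], method: str = "") -> CentralityRanking:
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    entries = [(p, float(s), i + 1) for i, (p, s) in enumerate(ordered)]
    return CentralityRanking(method=method, entries=entries)


def rank_network(net: PPINetwork | nx.Graph, method: str) -> CentralityRanking:
    return rank(centrality(net, method), method=method)


def topk_essential_counts(
    ranking: CentralityRanking,
    essential: ProteinList | set[str],
    fractions: Iterable[float] = (0.05, 0.10, 0.15, 0.20),
) -> dict[float, int]:
    """Gold-standard essentials among the top floor(f * N) ranked proteins,
    for each fraction f in (0, 1]."""
    ess = essential.as_set() if isinstance(essential, ProteinList) else set(essential)
    n = len(ranking)
    out: dict[float, int] = {}
    for f in fractions:
        if not 0.0 < f <= 1.0:
            raise ValueError(f"fraction {f} outside (0, 1]")
        k = int(np.floor(f * n))
        out[f] = sum(1 for p in ranking.top(k) if p in ess)
    return out


def evaluation_curves(
    ranking: CentralityRanking, essential: ProteinList | set[str]
) -> pd.DataFrame:
    """Precision-recall and jackknife curve points at every rank cutoff.

    Columns: k, hits (jackknife), precision = hits/k, recall = hits/E with
    E the number of essentials present in the ranking."""
    ess = essential.as_set() if isinstance(essential, ProteinList) else set(essential)
    members = [p for p, _s, _r in ranking.entries]
    hits = np.cumsum([p in ess for p in members])
    total = int(hits[-1]) if len(hits) else 0
    k = np.arange(1, len(members) + 1)
    return pd.DataFrame(
        {
            "k": k,
            "hits": hits,
            "precision": hits / k,
            "recall": hits / total if total else np.zeros(len(k)),
        }
    )
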
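"""Random-walk link-prediction baselines: RWR and LRW.

Random Walk with Restart (RWR) propagates from a seed node x the vector

    p = (1 - c) * W p + c * e_x

with W the column-normalized adjacency and restart probability c; the
pair score is s(x, y) = p_x[y] + p_y[x].  Local Random Walk (LRW) scores
a pair from the t-step transition probabilities of the simple random walk,

    s(x, y) = q_x * pi_x(t)[y] + q_y * pi_y(t)[x],   q_x = d_x / (2|E|),

with an optional superposed variant summing over steps 1..t.  Additional
scorers implementing the same contract can be registered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import networkx as nx
import numpy as np

from .net_io import Pair, PPINetwork

logger = logging.getLogger(__name__)


@dataclass
class SimilarityMatrix:
    """Dense symmetric nonnegative pairwise scores over the node index."""

    method: str
    nodes: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self._index = {n: i for i, n in enumerate(self.nodes)}
        if not np.isfinite(self.matrix).all():
            raise ValueError("similarity matrix contains non-finite entries")

    def score(self, u: str, v: str) -> float:
        return float(self.matrix[self._index[u], self._index[v]])


def _adjacency(net: PPINetwork) -> tuple[list[str], np.ndarray]:
    nodes = sorted(net.nodes)
    a = nx.to_numpy_array(net.to_networkx(), nodelist=nodes)
    return nodes, a


def rwr_stationary(
    net: PPINetwork,
    restart: float = 0.8,
    tol: float = 1e-10,
    max_iter: int = 100000,
) -> tuple[list[str], np.ndarray]:
    """RWR stationary vectors for every seed (one column per seed).

    Iterates all seeds at once: P_{k+1} = (1-c) W P_k + c I, to L1 change
    below ``tol`` per column.  Mass leaving an isolated (dangling) node is
    returned to that column's seed, so every stationary vector sums to 1.
    """
    if not 0.0 < restart < 1.0:
        raise ValueError(f"restart must be in (0, 1), got {restart}")
    nodes, a = _adjacency(net)
    n = len(nodes)
    if n == 0:
        raise ValueError("empty network")
    deg = a.sum(axis=0)
    dangling = deg == 0
    if dangling.any():
        logger.info(
            "%d isolated node(s); dangling mass teleports back to the seed",
            int(dangling.sum()),
        )
    w = np.divide(a, deg, out=np.zeros_like(a), where=deg > 0)
    c = restart
    p = np.eye(n)
    for _ in range(max_iter):
        lost = p[dangling].sum(axis=0)  # mass at dangling nodes, per seed column
        p_next = (1 - c) * (w @ p) + c * np.eye(n)
        if dangling.any():
            p_next[np.arange(n), np.arange(n)] += (1 - c) * lost
        if np.abs(p_next - p).sum(axis=0).max() < tol:
            p = p_next
            break
        p = p_next
    return nodes, p


def rwr_scores(
    net: PPINetwork,
    restart: float = 0.8,
    tol: float = 1e-10,
    max_iter: int = 100000,
) -> SimilarityMatrix:
    """RWR pair scores s(x, y) = p_x[y] + p_y[x] from the stationary
    vectors of :func:`rwr_stationary`."""
    nodes, p = rwr_stationary(net, restart=restart, tol=tol, max_iter=max_iter)
    s = p + p.T
    np.fill_diagonal(s, 0.0)
    return SimilarityMatrix(method="rwr", nodes=nodes, matrix=s)


def lrw_scores(
    net: PPINetwork, steps: int = 3, superposed: bool = False
) -> SimilarityMatrix:
    """LRW scores from the t-step simple-random-walk transition matrix.

    ``superposed=True`` accumulates the score over steps 1..t (the
    superposed-random-walk variant); default is the exact-t walk.
    """
    if steps < 1:
        raise ValueError(f"steps must be >= 1, got {steps}")
    nodes, a = _adjacency(net)
    n = len(nodes)
    if n == 0:
        raise ValueError("empty network")
    deg = a.sum(axis=1)
    two_m = deg.sum()
    q = deg / two_m if two_m > 0 else np.zeros(n)
    # row-stochastic transition; isolated nodes keep zero rows (q = 0 anyway)
    p = np.divide(a, deg[:, None], out=np.zeros_like(a), where=deg[:, None] > 0)
    pt = np.eye(n)
    s = np.zeros((n, n))
    for _ in range(steps):
        pt = pt @ p
        if superposed:
            s += q[:, None] * pt
    if not superposed:
        s = q[:, None] * pt
    s = s + s.T
    np.fill_diagonal(s, 0.0)
    return SimilarityMatrix(method="lrw", nodes=nodes, matrix=s)


SCORERS: dict[str, Callable[..., SimilarityMatrix]] = {
    "rwr": rwr_scores,
    "lrw": lrw_scores,
}


def register_scorer(name: str, fn: Callable[..., SimilarityMatrix]) -> None:
    """Plug in a third-party scorer returning a :class:`SimilarityMatrix`."""
    SCORERS[name] = fn


def predict_by_proportion(
    sim: SimilarityMatrix, net: PPINetwork, proportion: float
) -> set[Pair]:
    """Top floor(proportion * |E|) unlinked pairs by score (descending;
    ties broken lexicographically on the canonical pair)."""
    if proportion <= 0:
        raise ValueError(f"proportion must be > 0, got {proportion}")
    want = int(np.floor(proportion * net.n_edges))
    scored = sorted(
        ((sim.score(u, v), (u, v)) for u, v in net.unlinked_pairs()),
        key=lambda t: (-t[0], t[1]),
    )
    if want > len(scored):
        logger.warning(
            "requested %d pairs but only %d unlinked pairs exist", want, len(scored)
        )
        want = len(scored)
    return {pair for _s, pair in scored[:want]}
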
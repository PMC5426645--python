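"""Reading, normalizing and writing PPI networks and related protein sets.

A protein-protein interaction (PPI) network is modelled as a simple
undirected graph over opaque protein identifiers.  Edges are stored
canonically (lexicographically smaller endpoint first) so that ``(u, v)``
and ``(v, u)`` compare equal everywhere in the package.  Self-interactions
and duplicate interactions are removed on input, mirroring the standard
clean-up applied to DIP-style yeast edge lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

logger = logging.getLogger(__name__)

Pair = tuple[str, str]


def canonical_pair(u: str, v: str) -> Pair:
    """Return the unordered pair ``{u, v}`` in canonical (sorted) order."""
    if u == v:
        raise ValueError(f"self-pair not allowed: {u!r}")
    return (u, v) if u < v else (v, u)


@dataclass
class PPINetwork:
    """Simple undirected graph of protein IDs with canonical edge storage."""

    nodes: set[str] = field(default_factory=set)
    edges: set[Pair] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.edges = {canonical_pair(u, v) for u, v in self.edges}
        for u, v in self.edges:
            self.nodes.add(u)
            self.nodes.add(v)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def has_edge(self, u: str, v: str) -> bool:
        return canonical_pair(u, v) in self.edges

    def degree(self, u: str) -> int:
        return sum(1 for e in self.edges if u in e)

    def unlinked_pairs(self) -> Iterator[Pair]:
        """All canonical node pairs that are not edges, in sorted order."""
        ordered = sorted(self.nodes)
        for i, u in enumerate(ordered):
            for v in ordered[i + 1 :]:
                if (u, v) not in self.edges:
                    yield (u, v)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(sorted(self.edges))
        return g

    def copy(self) -> "PPINetwork":
        return PPINetwork(nodes=set(self.nodes), edges=set(self.edges))


@dataclass
class ReferenceInteractionSet:
    """Confidence-scored interactions (STRING-like), keyed by canonical pair."""

    scores: dict[Pair, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (u, v), c in self.scores.items():
            if (u, v) != canonical_pair(u, v):
                raise ValueError(f"non-canonical pair {(u, v)!r}")
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"confidence {c} for {(u, v)!r} outside [0, 1]")

    def confidence(self, u: str, v: str) -> float | None:
        return self.scores.get(canonical_pair(u, v))

    def __len__(self) -> int:
        return len(self.scores)

    def __contains__(self, pair: Pair) -> bool:
        return canonical_pair(*pair) in self.scores


@dataclass
class ProteinList:
    """Ordered, duplicate-free list of protein IDs (e.g. essential gold standard)."""

    proteins: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        unique: list[str] = []
        for p in self.proteins:
            if p not in seen:
                seen.add(p)
                unique.append(p)
        self.proteins = unique
        self._set = seen

    def __contains__(self, p: str) -> bool:
        return p in self._set

    def __iter__(self) -> Iterator[str]:
        return iter(self.proteins)

    def __len__(self) -> int:
        return len(self.proteins)

    def as_set(self) -> set[str]:
        return set(self._set)


def _data_lines(path: str | Path) -> Iterator[tuple[int, str]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#") or line.startswith("!"):
                continue
            yield lineno, line


def read_edge_list(
    path: str | Path, dialect: str = "two-column"
) -> PPINetwork | ReferenceInteractionSet:
    """Read a TSV/SIF edge list.

    Parameters
    ----------
    path:
        File with one interaction per line, whitespace/tab separated.
        ``#`` comment lines are skipped.
    dialect:
        ``"two-column"`` yields a :class:`PPINetwork` (self-loops dropped,
        duplicates collapsed).  ``"scored-three-column"`` yields a
        :class:`ReferenceInteractionSet`; duplicate scored pairs keep the
        maximum confidence.
    """
    if dialect not in ("two-column", "scored-three-column"):
        raise ValueError(f"unknown dialect {dialect!r}")
    scored = dialect == "scored-three-column"

    edges: set[Pair] = set()
    nodes: set[str] = set()
    scores: dict[Pair, float] = {}
    dropped_self = 0
    dropped_dup = 0
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) < 2 or (scored and len(fields) < 3):
            raise ValueError(f"{path}: malformed line {lineno}: {line!r}")
        u, v = fields[0], fields[1]
        nodes.add(u)
        nodes.add(v)
        if u == v:
            dropped_self += 1
            continue
        pair = canonical_pair(u, v)
        if scored:
            try:
                conf = float(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed confidence on line {lineno}: {fields[2]!r}"
                ) from exc
            if not 0.0 <= conf <= 1.0:
                raise ValueError(
                    f"{path}: confidence {conf} outside [0, 1] on line {lineno}"
                )
            if pair in scores:
                dropped_dup += 1
                scores[pair] = max(scores[pair], conf)
            else:
                scores[pair] = conf
        else:
            if pair in edges:
                dropped_dup += 1
            edges.add(pair)
    if dropped_self or dropped_dup:
        logger.info(
            "%s: dropped %d self-interactions, collapsed %d duplicate lines",
            path,
            dropped_self,
            dropped_dup,
        )
    if scored:
        return ReferenceInteractionSet(scores=scores)
    return PPINetwork(nodes=nodes, edges=edges)


def write_edge_list(
    net: PPINetwork | ReferenceInteractionSet, path: str | Path
) -> None:
    """Write a network or scored reference set in the TSV dialect read back
    by :func:`read_edge_list` (canonical pairs, sorted, deterministic)."""
    with open(path, "w") as fh:
        if isinstance(net, ReferenceInteractionSet):
            for (u, v) in sorted(net.scores):
                fh.write(f"{u}\t{v}\t{net.scores[(u, v)]:.6g}\n")
        else:
            for u, v in sorted(net.edges):
                fh.write(f"{u}\t{v}\n")


def read_protein_list(path: str | Path) -> ProteinList:
    """Read one protein ID per line; blank lines and ``#`` comments allowed."""
    proteins = [line.split()[0] for _, line in _data_lines(path)]
    if not proteins:
        logger.warning("%s: empty protein list", path)
    return ProteinList(proteins=proteins)


def write_protein_list(plist: ProteinList | Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in plist:
            fh.write(f"{p}\n")


def augment_network(original: PPINetwork, predicted: Iterable[Pair]) -> PPINetwork:
    """Union of the original network with a disjoint set of predicted edges.

    Stage 1 only scores *unlinked* pairs, so a predicted pair already present
    in the original network indicates a bookkeeping error and raises.
    """
    predicted = {canonical_pair(u, v) for u, v in predicted}
    clash = predicted & original.edges
    if clash:
        raise ValueError(
            f"predicted pairs duplicate original edges: {sorted(clash)[:5]}"
        )
    return PPINetwork(
        nodes=set(original.nodes), edges=original.edges | predicted
    )
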
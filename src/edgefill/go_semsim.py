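"""Gene Ontology parsing and Wang-style semantic similarity.

The similarity of two proteins' functional annotations is the second
existence-likelihood index for an unlinked pair.  Following the Wang
measure, every ancestor ``t`` of an anchor term ``A`` receives a semantic
contribution (S-value)

    S_A(A) = 1
    S_A(t) = max{ w_e * S_A(c) : c is a child of t on a path toward A }

with edge weights ``w_e`` below 1 per relation type (defaults 0.8 for
``is_a``, 0.6 for ``part_of``), so contributions decay multiplicatively
with distance from the anchor.  Two term sets are compared by

    sim(u, v) = sum_{t in T_u ∩ T_v} (S_u(t) + S_v(t))
                / (sum_{t in T_u} S_u(t) + sum_{t in T_v} S_v(t))

where, at the protein level, ``T_u`` is by default the ancestor closure of
the protein's annotated terms and ``S_u(t)`` the maximum S-value over its
annotated anchors.  Proteins without annotation score 0 against everything.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import obonet
from Bio.UniProt import GOA

logger = logging.getLogger(__name__)

#: Default multiplicative decay per parent-link relation.
DEFAULT_WEIGHTS: dict[str, float] = {"is_a": 0.8, "part_of": 0.6}

#: GAF aspect letter -> sub-ontology name.
ASPECTS = {"P": "BP", "F": "MF", "C": "CC"}
NAMESPACES = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
}


@dataclass
class TermInfo:
    namespace: str
    parents: tuple[tuple[str, str], ...]  # (parent_id, relation)
    obsolete: bool = False
    name: str = ""


@dataclass
class GoDag:
    """Ontology DAG with typed parent links and per-relation decay weights."""

    terms: dict[str, TermInfo]
    alt_ids: dict[str, str] = field(default_factory=dict)
    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))

    def __post_init__(self) -> None:
        for rel, w in self.weights.items():
            if not 0.0 < w < 1.0:
                raise ValueError(f"weight for {rel!r} must be in (0, 1), got {w}")
        for tid, info in self.terms.items():
            for pid, rel in info.parents:
                if pid not in self.terms:
                    raise ValueError(f"{tid}: parent {pid} not in DAG")
        self._check_acyclic()
        self._svalue_cache: dict[str, dict[str, float]] = {}

    def _check_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for tid, info in self.terms.items():
            for pid, _rel in info.parents:
                g.add_edge(tid, pid)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return
        raise ValueError(f"ontology contains a cycle through {cycle[0][0]}")

    def resolve(self, term_id: str) -> str | None:
        """Map an (alt) ID to its primary term; None for obsolete/unknown."""
        tid = self.alt_ids.get(term_id, term_id)
        info = self.terms.get(tid)
        if info is None or info.obsolete:
            return None
        return tid

    def namespace(self, term_id: str) -> str:
        return self.terms[term_id].namespace

    def ancestors(self, term_id: str) -> set[str]:
        """All terms reachable via parent links (excluding the term itself)."""
        seen: set[str] = set()
        stack = [term_id]
        while stack:
            t = stack.pop()
            for pid, _rel in self.terms[t].parents:
                if pid not in seen:
                    seen.add(pid)
                    stack.append(pid)
        return seen

    def __contains__(self, term_id: str) -> bool:
        return self.alt_ids.get(term_id, term_id) in self.terms


@dataclass
class AnnotationMap:
    """Protein ID -> set of (resolved, non-obsolete) term IDs in one namespace."""

    annotations: dict[str, set[str]]
    namespace: str = "BP"

    def terms_for(self, protein: str) -> set[str]:
        return self.annotations.get(protein, set())

    def __contains__(self, protein: str) -> bool:
        return bool(self.annotations.get(protein))

    def __len__(self) -> int:
        return len(self.annotations)


def parse_obo(
    path: str | Path, weights: dict[str, float] | None = None
) -> GoDag:
    """Parse an OBO 1.2 ontology into a :class:`GoDag`.

    ``is_a`` and ``relationship: part_of`` links are kept (other relations,
    e.g. ``regulates``, are ignored); links crossing sub-ontologies are
    dropped; obsolete terms are retained but flagged so annotation reading
    can skip them; ``alt_id`` entries resolve to their primary term.
    """
    graph = obonet.read_obo(path, ignore_obsolete=False)
    kept_rels = set((weights or DEFAULT_WEIGHTS).keys())
    terms: dict[str, TermInfo] = {}
    alt_ids: dict[str, str] = {}
    for tid, data in graph.nodes(data=True):
        ns = NAMESPACES.get(data.get("namespace", ""), data.get("namespace", ""))
        obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        parents: list[tuple[str, str]] = []
        for pid in data.get("is_a", []):
            parents.append((pid, "is_a"))
        for relation in data.get("relationship", []):
            rel, _, target = relation.partition(" ")
            if rel in kept_rels and target:
                parents.append((target.strip(), rel))
        terms[tid] = TermInfo(
            namespace=ns,
            parents=tuple(parents),
            obsolete=obsolete,
            name=data.get("name", ""),
        )
        for alt in data.get("alt_id", []):
            alt_ids[alt] = tid
    # drop parent links to unknown terms or across namespaces
    for tid, info in terms.items():
        kept = tuple(
            (pid, rel)
            for pid, rel in info.parents
            if pid in terms and terms[pid].namespace == info.namespace
        )
        if len(kept) != len(info.parents):
            logger.debug("%s: dropped %d parent links", tid, len(info.parents) - len(kept))
        terms[tid] = TermInfo(info.namespace, kept, info.obsolete, info.name)
    return GoDag(terms=terms, alt_ids=alt_ids, weights=dict(weights or DEFAULT_WEIGHTS))


def read_gaf(
    path: str | Path,
    namespace: str,
    dag: GoDag,
    exclude_evidence: Iterable[str] = (),
) -> AnnotationMap:
    """Read a GAF 2.x annotation file restricted to one sub-ontology.

    NOT-qualified rows are dropped, alternate IDs mapped to primary terms,
    obsolete-term rows dropped (count logged).  A row that cannot be parsed
    is skipped with a warning rather than aborting the read.
    """
    if namespace not in ("BP", "CC", "MF"):
        raise ValueError(f"namespace must be BP, CC or MF, got {namespace!r}")
    exclude = set(exclude_evidence)
    annotations: dict[str, set[str]] = {}
    n_obsolete = 0
    n_bad = 0
    with open(path) as fh:
        for rec in GOA.gafiterator(fh):
            try:
                if ASPECTS.get(rec["Aspect"]) != namespace:
                    continue
                if any(q.startswith("NOT") for q in rec.get("Qualifier", [])):
                    continue
                if rec.get("Evidence") in exclude:
                    continue
                protein = rec["DB_Object_ID"]
                term = dag.resolve(rec["GO_ID"])
            except (KeyError, TypeError):
                n_bad += 1
                logger.warning("%s: skipped unparseable GAF row", path)
                continue
            if term is None:
                n_obsolete += 1
                continue
            annotations.setdefault(protein, set()).add(term)
    if n_obsolete:
        logger.info("%s: dropped %d rows with obsolete/unknown terms", path, n_obsolete)
    if n_bad:
        logger.warning("%s: skipped %d unparseable rows", path, n_bad)
    return AnnotationMap(annotations=annotations, namespace=namespace)


def svalues(anchor: str, dag: GoDag) -> dict[str, float]:
    """S-values of an anchor term and all its ancestors.

    One pass over the ancestor sub-DAG in topological order (children before
    parents), relaxing ``S(parent) = max(S(parent), w_rel * S(child))``.
    """
    primary = dag.resolve(anchor)
    if primary is None:
        raise KeyError(f"unknown or obsolete term {anchor!r}")
    cached = dag._svalue_cache.get(primary)
    if cached is not None:
        return dict(cached)

    closure = {primary} | dag.ancestors(primary)
    sub = nx.DiGraph()
    sub.add_nodes_from(closure)
    for t in closure:
        for pid, rel in dag.terms[t].parents:
            sub.add_edge(t, pid, relation=rel)
    s: dict[str, float] = {primary: 1.0}
    for t in nx.topological_sort(sub):
        st = s.get(t)
        if st is None:  # unreachable from anchor going up; cannot happen
            continue
        for _t, pid, data in sub.out_edges(t, data=True):
            cand = dag.weights[data["relation"]] * st
            if cand > s.get(pid, 0.0):
                s[pid] = cand
    dag._svalue_cache[primary] = dict(s)
    return s


def term_sim(a: str, b: str, dag: GoDag) -> float:
    """Wang similarity between two terms of the same sub-ontology."""
    pa, pb = dag.resolve(a), dag.resolve(b)
    if pa is None or pb is None:
        raise KeyError(f"unknown term in pair ({a!r}, {b!r})")
    if dag.namespace(pa) != dag.namespace(pb):
        raise ValueError(
            f"cross-namespace pair: {pa} is {dag.namespace(pa)}, {pb} is {dag.namespace(pb)}"
        )
    sa, sb = svalues(pa, dag), svalues(pb, dag)
    shared = sa.keys() & sb.keys()
    num = sum(sa[t] + sb[t] for t in shared)
    den = sum(sa.values()) + sum(sb.values())
    return num / den


def _protein_profile(
    protein: str, ann: AnnotationMap, dag: GoDag, include_ancestors: bool
) -> dict[str, float]:
    """Term -> S-value profile of one protein (max over annotated anchors)."""
    profile: dict[str, float] = {}
    for anchor in sorted(ann.terms_for(protein)):
        if include_ancestors:
            for t, s in svalues(anchor, dag).items():
                if s > profile.get(t, 0.0):
                    profile[t] = s
        else:
            profile[anchor] = 1.0
    return profile


def protein_go_sim(
    u: str,
    v: str,
    ann: AnnotationMap,
    dag: GoDag,
    include_ancestors: bool = True,
) -> float:
    """Semantic similarity between two proteins' annotation sets, in [0, 1].

    Either protein lacking annotation scores 0 (the zero-similarity rule for
    unannotated proteins).  With ``include_ancestors=False`` the term sets
    are the directly annotated terms only, which reduces the measure to a
    Dice overlap of annotation sets.
    """
    if u not in ann or v not in ann:
        return 0.0
    pu = _protein_profile(u, ann, dag, include_ancestors)
    pv = _protein_profile(v, ann, dag, include_ancestors)
    shared = pu.keys() & pv.keys()
    num = sum(pu[t] + pv[t] for t in shared)
    den = sum(pu.values()) + sum(pv.values())
    if den == 0.0:
        return 0.0
    return min(1.0, num / den)
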
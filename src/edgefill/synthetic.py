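"""Seeded synthetic scenarios: a planted truth network with hidden edges.

The generator emulates the data a two-stage run consumes: an observed PPI
network obtained by hiding a fraction of a "truth" network's edges,
expression profiles in which hidden-edge pairs co-express through shared
latent factors, a toy ontology DAG whose deep terms are planted along the
hidden edges, an essential set (top truth-degree decile) and a
confidence-scored reference interaction set derived from the truth network.
Every draw comes from one seeded generator, so a fixed config + seed yields
byte-identical files.

Two hiding modes are provided.  ``"matching"`` (default) hides a random
matching — each protein loses at most one edge, so every hidden pair's
co-expression is driven by its own latent factor.  ``"hub"`` preferentially
hides most edges around a few designated essential proteins, producing the
stage-2 situation where an essential protein is under-ranked in the
observed network purely because its interactions are missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .expression import ExpressionMatrix
from .go_semsim import AnnotationMap, GoDag, TermInfo
from .net_io import (
    Pair,
    PPINetwork,
    ProteinList,
    ReferenceInteractionSet,
    canonical_pair,
    write_edge_list,
    write_protein_list,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of the synthetic benchmark.

    Defaults mirror the real-data setting at desk scale: 36 expression
    samples, 10% of edges hidden, near-deterministic co-expression along
    hidden edges (rho_edge = 0.99) against an uncorrelated background, and
    annotation overlap planted along hidden edges for 90% of proteins.
    """

    n_nodes: int = 300
    model: str = "scale-free"  # or "ER"
    attachment: int = 3  # scale-free: edges per new node; ER: mean degree / 2
    hide_fraction: float = 0.10
    n_samples: int = 36
    rho_edge: float = 0.99
    rho_background: float = 0.0
    dag_depth: int = 6
    dag_branching: int = 3
    annotation_overlap: float = 0.9
    reference_false_negative: float = 0.1
    decoy_fraction: float = 0.5
    essential_fraction: float = 0.10
    hide_mode: str = "matching"  # or "hub"
    n_hubs: int = 5
    hub_hide_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.hide_fraction < 1.0:
            raise ValueError("hide_fraction must be in (0, 1)")
        if not self.rho_background <= self.rho_edge <= 1.0:
            raise ValueError("need rho_background <= rho_edge <= 1")
        if self.model not in ("scale-free", "ER"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.hide_mode not in ("matching", "hub"):
            raise ValueError(f"unknown hide_mode {self.hide_mode!r}")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")


@dataclass
class SyntheticScenario:
    """One generated benchmark instance (see module docstring)."""

    config: SyntheticConfig
    truth: PPINetwork
    observed: PPINetwork
    hidden: set[Pair]
    expression: ExpressionMatrix
    dag: GoDag
    annotations: AnnotationMap
    reference: ReferenceInteractionSet
    essential: ProteinList
    components: list[tuple[str, ...]] = field(default_factory=list)

    def write_files(self, out_dir: str | Path) -> dict[str, Path]:
        """Write every input in the standard dialects the other modules read."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "observed": out / "observed_network.tsv",
            "truth": out / "truth_network.tsv",
            "hidden": out / "hidden_edges.tsv",
            "expression": out / "expression.tsv",
            "obo": out / "ontology.obo",
            "gaf": out / "annotations.gaf",
            "essential": out / "essential.txt",
            "reference": out / "reference.tsv",
            "config": out / "scenario.yaml",
        }
        write_edge_list(self.observed, paths["observed"])
        write_edge_list(self.truth, paths["truth"])
        with open(paths["hidden"], "w") as fh:
            for u, v in sorted(self.hidden):
                fh.write(f"{u}\t{v}\n")
        self.expression.to_tsv(paths["expression"])
        _write_obo(self.dag, paths["obo"])
        _write_gaf(self.annotations, paths["gaf"])
        write_protein_list(self.essential, paths["essential"])
        write_edge_list(self.reference, paths["reference"])
        with open(paths["config"], "w") as fh:
            yaml.safe_dump(asdict(self.config), fh, sort_keys=True)
        return paths


def _node_id(i: int) -> str:
    return f"P{i:04d}"


def _truth_network(cfg: SyntheticConfig, rng: np.random.Generator) -> PPINetwork:
    seed = int(rng.integers(2**31 - 1))
    if cfg.model == "scale-free":
        g = nx.barabasi_albert_graph(cfg.n_nodes, cfg.attachment, seed=seed)
    else:
        p = min(1.0, 2 * cfg.attachment / (cfg.n_nodes - 1))
        g = nx.gnp_random_graph(cfg.n_nodes, p, seed=seed)
    edges = {canonical_pair(_node_id(u), _node_id(v)) for u, v in g.edges}
    return PPINetwork(
        nodes={_node_id(i) for i in range(cfg.n_nodes)}, edges=edges
    )


def _essential_set(truth: PPINetwork, cfg: SyntheticConfig) -> ProteinList:
    n_ess = max(1, int(np.floor(cfg.essential_fraction * truth.n_nodes)))
    deg = {n: 0 for n in truth.nodes}
    for u, v in truth.edges:
        deg[u] += 1
        deg[v] += 1
    ordered = sorted(deg, key=lambda n: (-deg[n], n))
    return ProteinList(proteins=ordered[:n_ess])


def _hide_edges(
    truth: PPINetwork,
    essential: ProteinList,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
) -> set[Pair]:
    target = int(np.floor(cfg.hide_fraction * truth.n_edges))
    deg = {n: truth.degree(n) for n in truth.nodes}
    remaining = dict(deg)
    hidden: set[Pair] = set()
    used: set[str] = set()

    def try_hide(u: str, v: str, *, allow_reuse: set[str] = frozenset()) -> bool:
        pair = canonical_pair(u, v)
        if pair in hidden:
            return False
        if remaining[u] <= 1 or remaining[v] <= 1:
            return False
        if (u in used and u not in allow_reuse) or (v in used and v not in allow_reuse):
            return False
        hidden.add(pair)
        remaining[u] -= 1
        remaining[v] -= 1
        used.add(u)
        used.add(v)
        return True

    if cfg.hide_mode == "hub":
        # hubs: the lowest-degree members of the essential set (still well
        # connected, but removable edges actually move their rank)
        ess_sorted = sorted(essential, key=lambda n: (deg[n], n))
        hubs = ess_sorted[: cfg.n_hubs]
        hub_set = set(hubs)
        for hub in hubs:
            incident = sorted(
                (v if u == hub else u) for u, v in truth.edges if hub in (u, v)
            )
            rng.shuffle(incident)
            quota = int(np.floor(cfg.hub_hide_fraction * deg[hub]))
            taken = 0
            for partner in incident:
                if taken >= quota or len(hidden) >= target:
                    break
                if partner in hub_set:
                    continue
                if try_hide(hub, partner, allow_reuse={hub}):
                    taken += 1

    edge_order = sorted(truth.edges)
    rng.shuffle(edge_order)
    for u, v in edge_order:
        if len(hidden) >= target:
            break
        try_hide(u, v)
    if len(hidden) < target:
        # the matching is exhausted; relax to arbitrary hidden components
        # (the expression model is per-component, so correlations still hold)
        for u, v in edge_order:
            if len(hidden) >= target:
                break
            try_hide(u, v, allow_reuse={u, v})
    if len(hidden) < target:
        raise ValueError(
            f"infeasible config: could only hide {len(hidden)} of {target} edges "
            "without isolating a node"
        )
    return hidden


def _hidden_components(hidden: set[Pair]) -> list[tuple[str, ...]]:
    g = nx.Graph()
    g.add_edges_from(hidden)
    comps = [tuple(sorted(c)) for c in nx.connected_components(g)]
    return sorted(comps)


def _expression(
    truth: PPINetwork,
    components: list[tuple[str, ...]],
    cfg: SyntheticConfig,
    rng: np.random.Generator,
) -> ExpressionMatrix:
    nodes = sorted(truth.nodes)
    member_of: dict[str, int] = {}
    for i, comp in enumerate(components):
        for n in comp:
            member_of[n] = i
    factors = rng.standard_normal((len(components), cfg.n_samples))
    background = rng.standard_normal(cfg.n_samples)
    rows = np.empty((len(nodes), cfg.n_samples))
    for i, n in enumerate(nodes):
        noise = rng.standard_normal(cfg.n_samples)
        if n in member_of:
            rho = cfg.rho_edge
            rows[i] = np.sqrt(rho) * factors[member_of[n]] + np.sqrt(1 - rho) * noise
        elif cfg.rho_background > 0:
            rho = cfg.rho_background
            rows[i] = np.sqrt(rho) * background + np.sqrt(1 - rho) * noise
        else:
            rows[i] = noise
    df = pd.DataFrame(
        rows, index=nodes, columns=[f"s{j:02d}" for j in range(cfg.n_samples)]
    )
    df.index.name = "gene"
    return ExpressionMatrix(data=df)


def _toy_dag(cfg: SyntheticConfig) -> tuple[GoDag, list[str]]:
    """Complete b-ary tree of depth ``dag_depth`` rooted at one BP term;
    every fifth parent link is ``part_of``, the rest ``is_a``."""
    terms: dict[str, TermInfo] = {}
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"SYN:{counter:06d}"

    root = new_id()
    terms[root] = TermInfo(namespace="BP", parents=())
    frontier = [root]
    link_no = 0
    for _depth in range(cfg.dag_depth):
        nxt: list[str] = []
        for parent in frontier:
            for _b in range(cfg.dag_branching):
                tid = new_id()
                link_no += 1
                rel = "part_of" if link_no % 5 == 0 else "is_a"
                terms[tid] = TermInfo(namespace="BP", parents=((parent, rel),))
                nxt.append(tid)
        frontier = nxt
    return GoDag(terms=terms), frontier  # frontier = leaves


def _annotations(
    truth: PPINetwork,
    components: list[tuple[str, ...]],
    leaves: list[str],
    cfg: SyntheticConfig,
    rng: np.random.Generator,
) -> AnnotationMap:
    ann: dict[str, set[str]] = {}
    for n in sorted(truth.nodes):
        ann[n] = {leaves[int(rng.integers(len(leaves)))]}
    for comp in components:
        i, j = rng.integers(len(leaves)), rng.integers(len(leaves))
        while j == i:
            j = rng.integers(len(leaves))
        shared = {leaves[int(i)], leaves[int(j)]}
        for n in comp:
            if rng.random() < cfg.annotation_overlap:
                ann[n] |= shared
    return AnnotationMap(annotations=ann, namespace="BP")


def _reference(
    truth: PPINetwork, cfg: SyntheticConfig, rng: np.random.Generator
) -> ReferenceInteractionSet:
    scores: dict[Pair, float] = {}
    for pair in sorted(truth.edges):
        if rng.random() < cfg.reference_false_negative:
            scores[pair] = float(rng.uniform(0.0, 0.7))
        else:
            scores[pair] = float(rng.uniform(0.7, 1.0))
    nodes = sorted(truth.nodes)
    n_decoys = int(np.floor(cfg.decoy_fraction * truth.n_edges))
    added = 0
    while added < n_decoys:
        i, j = rng.integers(len(nodes), size=2)
        if i == j:
            continue
        pair = canonical_pair(nodes[int(i)], nodes[int(j)])
        if pair in truth.edges or pair in scores:
            continue
        scores[pair] = float(rng.uniform(0.0, 0.7))
        added += 1
    return ReferenceInteractionSet(scores=scores)


def generate(config: SyntheticConfig | None = None, **overrides) -> SyntheticScenario:
    """Generate one scenario; deterministic for a fixed config (incl. seed)."""
    if config is None:
        config = SyntheticConfig(**overrides)
    elif overrides:
        config = SyntheticConfig(**{**asdict(config), **overrides})
    rng = np.random.default_rng(config.seed)
    truth = _truth_network(config, rng)
    essential = _essential_set(truth, config)
    hidden = _hide_edges(truth, essential, config, rng)
    observed = PPINetwork(nodes=set(truth.nodes), edges=truth.edges - hidden)
    components = _hidden_components(hidden)
    expression = _expression(truth, components, config, rng)
    dag, leaves = _toy_dag(config)
    annotations = _annotations(truth, components, leaves, config, rng)
    reference = _reference(truth, config, rng)
    return SyntheticScenario(
        config=config,
        truth=truth,
        observed=observed,
        hidden=hidden,
        expression=expression,
        dag=dag,
        annotations=annotations,
        reference=reference,
        essential=essential,
        components=components,
    )


def truth_precision(
    predicted: set[Pair], scenario: SyntheticScenario
) -> tuple[float | None, float]:
    """Precision and recall of predicted edges against the hidden truth set.

    Precision is ``None`` (undefined) for an empty prediction."""
    predicted = {canonical_pair(u, v) for u, v in predicted}
    tp = len(predicted & scenario.hidden)
    recall = tp / len(scenario.hidden) if scenario.hidden else 0.0
    if not predicted:
        logger.warning("empty prediction; precision undefined")
        return None, recall
    return tp / len(predicted), recall


def _write_obo(dag: GoDag, path: Path) -> None:
    ns_long = {"BP": "biological_process", "CC": "cellular_component", "MF": "molecular_function"}
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: syn\n")
        for tid in sorted(dag.terms):
            info = dag.terms[tid]
            fh.write(f"\n[Term]\nid: {tid}\nname: synthetic term {tid}\n")
            fh.write(f"namespace: {ns_long.get(info.namespace, info.namespace)}\n")
            for pid, rel in info.parents:
                if rel == "is_a":
                    fh.write(f"is_a: {pid}\n")
                else:
                    fh.write(f"relationship: {rel} {pid}\n")
            if info.obsolete:
                fh.write("is_obsolete: true\n")


def _write_gaf(ann: AnnotationMap, path: Path) -> None:
    aspect = {"BP": "P", "MF": "F", "CC": "C"}[ann.namespace]
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.1\n")
        for protein in sorted(ann.annotations):
            for term in sorted(ann.annotations[protein]):
                cols = [
                    "SYN", protein, protein, "", term, "SYN_REF:0000001", "IDA",
                    "", aspect, "", "", "protein", "taxon:4932", "20160305",
                    "SYN", "", "",
                ]
                fh.write("\t".join(cols) + "\n")
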
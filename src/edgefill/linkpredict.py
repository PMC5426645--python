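"""Stage 1: score unlinked pairs and predict missing interactions.

An unlinked pair is predicted as a missing edge when its expression
correlation passes the PCC threshold and — when the GO filter is enabled —
its GO semantic similarity passes the GO threshold.  Both comparisons are
inclusive (>=).  GO similarity is only evaluated for pairs that already
pass the PCC gate, the same two-stage filter order used to build the
augmented networks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .expression import ExpressionMatrix, pair_pcc_for_network
from .go_semsim import AnnotationMap, GoDag, protein_go_sim
from .net_io import Pair, PPINetwork


@dataclass(frozen=True)
class ThresholdConfig:
    """Operating point of the stage-1 filter.

    ``go_threshold = 0`` disables the GO filter (PCC-only network)."""

    pcc_threshold: float
    go_threshold: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.pcc_threshold < 1.0:
            raise ValueError(f"pcc_threshold must be in (0, 1), got {self.pcc_threshold}")
        if not 0.0 <= self.go_threshold <= 1.0:
            raise ValueError(f"go_threshold must be in [0, 1], got {self.go_threshold}")


@dataclass
class ScoredPairTable:
    """Scores of unlinked candidate pairs; ``go_sim`` is NaN where it was
    never needed (pair failed the PCC gate or the GO filter was off)."""

    table: pd.DataFrame  # columns: u, v, pcc, go_sim

    def passing(self, cfg: ThresholdConfig) -> set[Pair]:
        df = self.table
        mask = df["pcc"] >= cfg.pcc_threshold
        if cfg.go_threshold > 0:
            mask &= df["go_sim"] >= cfg.go_threshold
        return {(u, v) for u, v in df.loc[mask, ["u", "v"]].itertuples(index=False)}


def score_pairs(
    net: PPINetwork,
    expr: ExpressionMatrix,
    ann: AnnotationMap | None,
    dag: GoDag | None,
    pcc_gate: float,
    need_go: bool,
    include_ancestors: bool = True,
) -> ScoredPairTable:
    """Score all unlinked pairs: PCC for every pair, GO similarity lazily
    for pairs with ``pcc >= pcc_gate`` when the GO filter is in use."""
    pcc_map = pair_pcc_for_network(net, expr)
    pairs = sorted(pcc_map)
    rows = {
        "u": [p[0] for p in pairs],
        "v": [p[1] for p in pairs],
        "pcc": [pcc_map[p] for p in pairs],
    }
    go_col: list[float] = []
    for (u, v), r in zip(pairs, (pcc_map[p] for p in pairs)):
        if need_go and r >= pcc_gate:
            if ann is None or dag is None:
                raise ValueError("GO filter requested but annotations/DAG missing")
            go_col.append(protein_go_sim(u, v, ann, dag, include_ancestors))
        else:
            go_col.append(float("nan"))
    rows["go_sim"] = go_col
    return ScoredPairTable(table=pd.DataFrame(rows))


def predict_links(
    net: PPINetwork,
    expr: ExpressionMatrix,
    ann: AnnotationMap | None,
    dag: GoDag | None,
    cfg: ThresholdConfig,
    include_ancestors: bool = True,
) -> tuple[set[Pair], ScoredPairTable]:
    """Predict missing edges at one operating point.

    Returns the predicted canonical pair set and the scored-pair table.
    Deterministic for fixed inputs.
    """
    scored = score_pairs(
        net,
        expr,
        ann,
        dag,
        pcc_gate=cfg.pcc_threshold,
        need_go=cfg.go_threshold > 0,
        include_ancestors=include_ancestors,
    )
    return scored.passing(cfg), scored


def added_proportion(predicted: Iterable[Pair], original: PPINetwork) -> float:
    """|predicted| / |original edges| — the added-links proportion."""
    predicted = set(predicted)
    if original.n_edges == 0:
        raise ValueError("original network has no edges")
    if predicted & original.edges:
        raise ValueError("predicted pairs overlap original edges")
    return len(predicted) / original.n_edges


def proportion_table(
    net: PPINetwork,
    expr: ExpressionMatrix,
    ann: AnnotationMap | None,
    dag: GoDag | None,
    grid: list[ThresholdConfig],
    include_ancestors: bool = True,
) -> pd.DataFrame:
    """Added-links proportion for each operating point in ``grid``.

    Scoring is shared across the grid: GO similarity is computed once for
    every pair passing the loosest PCC gate that has the GO filter enabled.
    """
    if not grid:
        raise ValueError("empty threshold grid")
    go_gates = [c.pcc_threshold for c in grid if c.go_threshold > 0]
    need_go = bool(go_gates)
    gate = min(go_gates) if need_go else 1.0
    scored = score_pairs(
        net, expr, ann, dag, pcc_gate=gate, need_go=need_go,
        include_ancestors=include_ancestors,
    )
    rows = []
    for cfg in grid:
        predicted = scored.passing(cfg)
        rows.append(
            {
                "pcc_threshold": cfg.pcc_threshold,
                "go_threshold": cfg.go_threshold,
                "n_predicted": len(predicted),
                "proportion": added_proportion(predicted, net),
            }
        )
    return pd.DataFrame(rows)
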
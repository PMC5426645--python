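"""Stage 2: differential ranking analysis, candidate selection, validation.

After stage 1 builds two augmented networks (network 1: PCC-only filter;
network 2: PCC + GO filter), centrality rankings on the original and
augmented networks are compared at a top-K cutoff.  Essential proteins
that enter the top K only on both augmented networks — and in particular
the "deep-ranked" ones whose original-network rank exceeds a threshold R
under all considered methods — point at predicted edges that changed the
topology meaningfully.  The predicted edges incident to those deep-ranked
candidates are the "selected" group, validated against a confidence-scored
reference interaction set at a minimum confidence (default 0.7).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .centrality import CentralityRanking
from .net_io import Pair, ProteinList, ReferenceInteractionSet, canonical_pair

logger = logging.getLogger(__name__)


@dataclass
class SetDifferenceRow:
    """Top-K overlap/difference counts between two rankings, split by
    gold-standard essentiality."""

    method: str
    k: int
    intersection_essential: int
    new_only_essential: int
    ori_only_essential: int
    intersection_nonessential: int
    new_only_nonessential: int
    ori_only_nonessential: int

    @property
    def intersection(self) -> int:
        return self.intersection_essential + self.intersection_nonessential

    @property
    def new_only(self) -> int:
        return self.new_only_essential + self.new_only_nonessential

    @property
    def ori_only(self) -> int:
        return self.ori_only_essential + self.ori_only_nonessential


def set_difference_table(
    rank_ori: CentralityRanking,
    rank_new: CentralityRanking,
    k: int,
    essential: ProteinList | set[str],
) -> SetDifferenceRow:
    """Intersection and set differences of the two top-K protein sets."""
    if k > len(rank_ori) or k > len(rank_new):
        raise ValueError(f"cutoff {k} exceeds a ranking length")
    ess = essential.as_set() if isinstance(essential, ProteinList) else set(essential)
    top_ori = set(rank_ori.top(k))
    top_new = set(rank_new.top(k))
    inter = top_ori & top_new
    new_only = top_new - top_ori
    ori_only = top_ori - top_new
    return SetDifferenceRow(
        method=rank_new.method or rank_ori.method,
        k=k,
        intersection_essential=len(inter & ess),
        new_only_essential=len(new_only & ess),
        ori_only_essential=len(ori_only & ess),
        intersection_nonessential=len(inter - ess),
        new_only_nonessential=len(new_only - ess),
        ori_only_nonessential=len(ori_only - ess),
    )


@dataclass
class Candidate:
    protein: str
    ori_ranks: dict[str, int]
    deep_ranked: bool


def select_candidates(
    rank_ori: Mapping[str, CentralityRanking],
    rank_new1: Mapping[str, CentralityRanking],
    rank_new2: Mapping[str, CentralityRanking],
    essential: ProteinList | set[str],
    k: int = 200,
    rank_threshold: int = 1000,
    topk_quantifier: str = "any",
    deep_quantifier: str = "all",
) -> list[Candidate]:
    """Essential proteins rescued into the top K only by the augmented
    networks, flagged "deep-ranked" when their original rank exceeds
    ``rank_threshold`` under every method.

    A protein qualifies iff it (a) is gold-standard essential, (b) appears
    in the top K under at least one method (``topk_quantifier="any"``; set
    ``"all"`` to demand every method) in *both* augmented networks, and
    (c) is absent from the top K under every method on the original
    network.  A protein ranked in an augmented network but missing from
    the original ranking would count as rank infinity (cannot occur when
    node sets match).  Output order: sorted protein ID; invariant to the
    order the rankings are supplied in.
    """
    if rank_threshold < k:
        raise ValueError("rank_threshold must be >= k")
    methods = sorted(rank_ori)
    if sorted(rank_new1) != methods or sorted(rank_new2) != methods:
        raise ValueError("the three ranking sets must cover the same methods")
    if topk_quantifier not in ("any", "all") or deep_quantifier not in ("any", "all"):
        raise ValueError("quantifiers must be 'any' or 'all'")
    ess = essential.as_set() if isinstance(essential, ProteinList) else set(essential)

    top_ori = {m: set(rank_ori[m].top(k)) for m in methods}
    top_new1 = {m: set(rank_new1[m].top(k)) for m in methods}
    top_new2 = {m: set(rank_new2[m].top(k)) for m in methods}
    quant = {"any": any, "all": all}

    candidates: list[Candidate] = []
    universe = sorted(set().union(*top_new1.values()) & set().union(*top_new2.values()))
    for p in universe:
        if p not in ess:
            continue
        if not quant[topk_quantifier](p in top_new1[m] for m in methods):
            continue
        if not quant[topk_quantifier](p in top_new2[m] for m in methods):
            continue
        if any(p in top_ori[m] for m in methods):
            continue
        ori_ranks = {
            m: rank_ori[m].rank_of(p) if rank_ori[m].rank_of(p) is not None else 10**9
            for m in methods
        }
        deep = quant[deep_quantifier](r > rank_threshold for r in ori_ranks.values())
        candidates.append(Candidate(protein=p, ori_ranks=ori_ranks, deep_ranked=deep))
    return candidates


def incident_predicted_edges(
    candidates: Iterable[str], predicted: Iterable[Pair]
) -> set[Pair]:
    """Predicted edges with at least one endpoint in the candidate set."""
    cand = set(candidates)
    if not cand:
        logger.warning("empty candidate set; no edges selected")
        return set()
    return {
        canonical_pair(u, v) for u, v in predicted if u in cand or v in cand
    }


@dataclass
class ValidationReport:
    """Outcome of confirming an edge group against the reference set."""

    n: int
    confirmed: int
    fraction: float
    confirmed_edges: set[Pair] = field(default_factory=set)


def validate_edges(
    edges: Iterable[Pair],
    ref: ReferenceInteractionSet,
    min_conf: float = 0.7,
) -> ValidationReport:
    """Confirm edges present in the reference set at confidence >= min_conf."""
    if not 0.0 <= min_conf <= 1.0:
        raise ValueError(f"min_conf {min_conf} outside [0, 1]")
    edges = {canonical_pair(u, v) for u, v in edges}
    confirmed = {
        e for e in edges if (c := ref.scores.get(e)) is not None and c >= min_conf
    }
    n = len(edges)
    if n == 0:
        logger.warning("validating an empty edge group; fraction reported as 0")
        return ValidationReport(n=0, confirmed=0, fraction=0.0)
    return ValidationReport(
        n=n,
        confirmed=len(confirmed),
        fraction=len(confirmed) / n,
        confirmed_edges=confirmed,
    )


@dataclass
class StageTwoReport:
    """Full stage-2 outcome for one run (per augmented network where noted)."""

    candidates: list[Candidate]
    deep_ranked: list[str]
    set_difference: dict[str, dict[str, SetDifferenceRow]]  # network -> method -> row
    selected_edges: dict[str, set[Pair]]  # network label -> edges
    selected_validation: dict[str, ValidationReport]
    total_validation: dict[str, ValidationReport]
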
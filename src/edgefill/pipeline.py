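"""Orchestration of the full two-stage run.

One config drives: stage-1 prediction at the two canonical operating
points (network 1: PCC-only; network 2: PCC + GO), network augmentation,
centrality ranking of the original and both augmented networks,
set-difference tables, candidate selection, incident-edge selection,
reference validation, and the random-walk baselines at the matched
proportion.  Every intermediate is written to disk and the run report is
a deterministic JSON-serializable dict.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

from . import baselines as bl
from .centrality import CentralityRanking, rank_network
from .expression import ExpressionMatrix
from .go_semsim import AnnotationMap, GoDag, parse_obo, read_gaf
from .linkpredict import ThresholdConfig, predict_links
from .net_io import (
    PPINetwork,
    ProteinList,
    ReferenceInteractionSet,
    augment_network,
    read_edge_list,
    read_protein_list,
    write_edge_list,
)
from .stage2 import (
    StageTwoReport,
    incident_predicted_edges,
    select_candidates,
    set_difference_table,
    validate_edges,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the artifacts
    completed before the failure."""

    def __init__(self, stage: str, manifest: list[str], cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest


@dataclass
class TwoStageParams:
    """Method parameters of a two-stage run (paper-scale defaults)."""

    thresholds1: ThresholdConfig = field(
        default_factory=lambda: ThresholdConfig(0.98, 0.0)
    )
    thresholds2: ThresholdConfig = field(
        default_factory=lambda: ThresholdConfig(0.95, 0.5)
    )
    methods: tuple[str, ...] = ("DC", "NC", "SC")
    k: int = 200
    rank_threshold: int = 1000
    topk_quantifier: str = "any"
    deep_quantifier: str = "all"
    min_conf: float = 0.7
    baseline_methods: tuple[str, ...] = ("rwr", "lrw")
    rwr_restart: float = 0.8
    lrw_steps: int = 3
    include_ancestors: bool = True


@dataclass
class RunConfig:
    """File-level configuration: input paths + method parameters."""

    network: str
    expression: str
    obo: str
    gaf: str
    essential: str
    reference: str
    out_dir: str
    namespace: str = "BP"
    params: TwoStageParams = field(default_factory=TwoStageParams)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        params_raw = raw.pop("params", {})
        t1 = params_raw.pop("thresholds1", None)
        t2 = params_raw.pop("thresholds2", None)
        params = TwoStageParams(**params_raw)
        if t1:
            params.thresholds1 = ThresholdConfig(**t1)
        if t2:
            params.thresholds2 = ThresholdConfig(**t2)
        for key in ("methods", "baseline_methods"):
            setattr(params, key, tuple(getattr(params, key)))
        return cls(params=params, **raw)


def run_two_stage(
    observed: PPINetwork,
    expr: ExpressionMatrix,
    ann: AnnotationMap | None,
    dag: GoDag | None,
    essential: ProteinList | set[str],
    reference: ReferenceInteractionSet,
    params: TwoStageParams | None = None,
) -> tuple[dict[str, Any], dict[str, Any]]:
    """Run the two-stage method on in-memory objects.

    Returns ``(report, artifacts)``: the report is a JSON-serializable
    summary (counts, proportions, validation fractions); the artifacts dict
    holds the intermediate objects (predictions, networks, rankings,
    candidates, selections, baseline scores).
    """
    params = params or TwoStageParams()
    art: dict[str, Any] = {}
    manifest: list[str] = []

    def stage(name: str):
        def deco(fn):
            try:
                fn()
                manifest.append(name)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - report the failing stage
                raise StageError(name, manifest, exc) from exc

        return deco

    @stage("predict")
    def _predict() -> None:
        pred1, scored1 = predict_links(
            observed, expr, ann, dag, params.thresholds1,
            include_ancestors=params.include_ancestors,
        )
        pred2, scored2 = predict_links(
            observed, expr, ann, dag, params.thresholds2,
            include_ancestors=params.include_ancestors,
        )
        art.update(predicted1=pred1, predicted2=pred2, scored1=scored1, scored2=scored2)

    @stage("augment")
    def _augment() -> None:
        art["network1"] = augment_network(observed, art["predicted1"])
        art["network2"] = augment_network(observed, art["predicted2"])

    @stage("rank")
    def _rank() -> None:
        for label, net in (
            ("ori", observed),
            ("new1", art["network1"]),
            ("new2", art["network2"]),
        ):
            art[f"rank_{label}"] = {
                m: rank_network(net, m) for m in params.methods
            }

    @stage("set_difference")
    def _setdiff() -> None:
        k = min(params.k, observed.n_nodes)
        art["set_difference"] = {
            label: {
                m: set_difference_table(
                    art["rank_ori"][m], art[f"rank_{label}"][m], k, essential
                )
                for m in params.methods
            }
            for label in ("new1", "new2")
        }

    @stage("select_candidates")
    def _candidates() -> None:
        k = min(params.k, observed.n_nodes)
        art["candidates"] = select_candidates(
            art["rank_ori"],
            art["rank_new1"],
            art["rank_new2"],
            essential,
            k=k,
            rank_threshold=max(params.rank_threshold, k),
            topk_quantifier=params.topk_quantifier,
            deep_quantifier=params.deep_quantifier,
        )
        art["deep_ranked"] = sorted(
            c.protein for c in art["candidates"] if c.deep_ranked
        )

    @stage("select_edges")
    def _edges() -> None:
        for label in ("1", "2"):
            art[f"selected{label}"] = incident_predicted_edges(
                art["deep_ranked"], art[f"predicted{label}"]
            )

    @stage("validate")
    def _validate() -> None:
        for label in ("1", "2"):
            art[f"total_validation{label}"] = validate_edges(
                art[f"predicted{label}"], reference, params.min_conf
            )
            art[f"selected_validation{label}"] = validate_edges(
                art[f"selected{label}"], reference, params.min_conf
            )

    @stage("baselines")
    def _baselines() -> None:
        proportion = (
            len(art["predicted1"]) / observed.n_edges if observed.n_edges else 0.0
        )
        art["baseline"] = {}
        if proportion <= 0:
            return
        for method in params.baseline_methods:
            if method == "rwr":
                sim = bl.rwr_scores(observed, restart=params.rwr_restart)
            elif method == "lrw":
                sim = bl.lrw_scores(observed, steps=params.lrw_steps)
            else:
                sim = bl.SCORERS[method](observed)
            predicted = bl.predict_by_proportion(sim, observed, proportion)
            art["baseline"][method] = {
                "predicted": predicted,
                "validation": validate_edges(predicted, reference, params.min_conf),
            }

    empty_ref = len(reference) == 0

    def frac(v) -> float | None:
        return None if empty_ref else v.fraction

    report: dict[str, Any] = {
        "n_nodes": observed.n_nodes,
        "n_edges": observed.n_edges,
        "thresholds": {
            "network1": {"pcc": params.thresholds1.pcc_threshold,
                         "go": params.thresholds1.go_threshold},
            "network2": {"pcc": params.thresholds2.pcc_threshold,
                         "go": params.thresholds2.go_threshold},
        },
        "predicted": {
            "network1": len(art["predicted1"]),
            "network2": len(art["predicted2"]),
        },
        "added_proportion": {
            "network1": len(art["predicted1"]) / observed.n_edges,
            "network2": len(art["predicted2"]) / observed.n_edges,
        },
        "set_difference": {
            label: {
                m: asdict(row) for m, row in art["set_difference"][label].items()
            }
            for label in ("new1", "new2")
        },
        "candidates": [
            {"protein": c.protein, "ori_ranks": c.ori_ranks, "deep_ranked": c.deep_ranked}
            for c in art["candidates"]
        ],
        "deep_ranked": art["deep_ranked"],
        "validation": {
            f"network{label}": {
                "total": {
                    "n": art[f"total_validation{label}"].n,
                    "confirmed": art[f"total_validation{label}"].confirmed,
                    "fraction": frac(art[f"total_validation{label}"]),
                },
                "selected": {
                    "n": art[f"selected_validation{label}"].n,
                    "confirmed": art[f"selected_validation{label}"].confirmed,
                    "fraction": frac(art[f"selected_validation{label}"]),
                },
            }
            for label in ("1", "2")
        },
        "baselines": {
            m: {
                "predicted": len(d["predicted"]),
                "confirmed": d["validation"].confirmed,
                "fraction": frac(d["validation"]),
            }
            for m, d in art["baseline"].items()
        },
    }
    art["stage_two_report"] = StageTwoReport(
        candidates=art["candidates"],
        deep_ranked=art["deep_ranked"],
        set_difference=art["set_difference"],
        selected_edges={"network1": art["selected1"], "network2": art["selected2"]},
        selected_validation={
            "network1": art["selected_validation1"],
            "network2": art["selected_validation2"],
        },
        total_validation={
            "network1": art["total_validation1"],
            "network2": art["total_validation2"],
        },
    )
    return report, art


def run(config: RunConfig) -> dict[str, Any]:
    """Run the two-stage pipeline from files, writing every intermediate.

    Deterministic: identical config (and seed, for synthetic inputs built
    upstream) gives byte-identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    net = read_edge_list(config.network, dialect="two-column")
    expr = ExpressionMatrix.from_tsv(config.expression)
    dag = parse_obo(config.obo)
    ann = read_gaf(config.gaf, config.namespace, dag)
    essential = read_protein_list(config.essential)
    reference = read_edge_list(config.reference, dialect="scored-three-column")

    report, art = run_two_stage(
        net, expr, ann, dag, essential, reference, config.params
    )

    for label in ("1", "2"):
        with open(out / f"predicted_network{label}.tsv", "w") as fh:
            for u, v in sorted(art[f"predicted{label}"]):
                fh.write(f"{u}\t{v}\n")
        write_edge_list(art[f"network{label}"], out / f"network{label}.tsv")
        with open(out / f"selected_network{label}.tsv", "w") as fh:
            for u, v in sorted(art[f"selected{label}"]):
                fh.write(f"{u}\t{v}\n")
    for label in ("ori", "new1", "new2"):
        for m, ranking in art[f"rank_{label}"].items():
            ranking.to_frame().to_csv(
                out / f"ranking_{label}_{m}.tsv", sep="\t", index=False
            )
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info(
        "run complete: %d + %d predicted edges, %d candidates (%d deep-ranked)",
        report["predicted"]["network1"],
        report["predicted"]["network2"],
        len(report["candidates"]),
        len(report["deep_ranked"]),
    )
    return report
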
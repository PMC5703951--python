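"""End-to-end orchestration: enrich → train → cross-validate → predict for
every ADR in a graph, with deterministic seeding and auditable logging."""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd

from .enrich import EnrichmentError, NoModel, select_predictors
from .evaluate import assign_confidence, edge_deletion_cv
from .graph import ADR, GraphError, KnowledgeGraph, load_graph
from .model import ModelError, predict_new, train_model

log = logging.getLogger("adrkg")

EXIT_OK = 0
EXIT_INPUT = 2
EXIT_NO_MODELS = 3


@dataclasses.dataclass
class RunConfig:
    """Flat configuration for a full pipeline run; JSON round-trips losslessly."""

    graph_path: str = ""
    out_dir: str = "adrkg_out"
    obs_path: str | None = None
    alpha: float = 0.05
    grid_step: float = 0.05
    k_folds: int = 10
    n_iter: int = 100_000
    seed: int = 0
    min_causes: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.grid_step <= 1:
            raise ValueError("grid_step must lie in (0, 1]")
        if self.k_folds < 2:
            raise ValueError("k_folds must be at least 2")
        if self.n_iter < 1 or self.seed < 0:
            raise ValueError("n_iter must be positive and seed non-negative")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def run_full_pipeline(cfg: RunConfig) -> int:
    """For every ADR with known causes: select predictors, train, cross-validate
    and predict; write per-ADR model JSON, a predictions table and a CV summary.

    Per-ADR failures (no predictors of every type, degenerate labels) are
    logged and skipped. Returns 0 on success, 2 on unreadable/empty input,
    3 if no ADR could be modelled.
    """
    try:
        g = load_graph(cfg.graph_path)
    except (OSError, GraphError, pd.errors.EmptyDataError) as exc:
        log.error("cannot load graph %s: %s", cfg.graph_path, exc)
        return EXIT_INPUT
    if not g.drugs:
        log.error("graph %s contains no edges", cfg.graph_path)
        return EXIT_INPUT

    out = Path(cfg.out_dir)
    (out / "models").mkdir(parents=True, exist_ok=True)
    adrs = sorted(g.nodes_of_type(ADR))
    reports, pred_rows, n_trained = [], [], 0
    for adr in adrs:
        causes = g.neighbors(adr)
        if len(causes) < cfg.min_causes or len(causes) >= len(g.drugs):
            continue
        try:
            ps = select_predictors(g, adr, cfg.alpha)
        except EnrichmentError as exc:
            log.info("%s: skipped (%s)", adr.identifier, exc)
            continue
        if isinstance(ps, NoModel):
            log.info("%s: skipped (%s)", adr.identifier, ps.reason)
            continue
        try:
            model = train_model(g, ps, cfg.grid_step)
        except ModelError as exc:
            log.info("%s: skipped (%s)", adr.identifier, exc)
            continue
        n_trained += 1
        new = predict_new(model, g)
        log.info(
            "%s: causes=%d predictors=%s J=%.3f threshold=%.4f new=%d",
            adr.identifier,
            len(causes),
            {t: len(ps.predictors[t]) for t in ps.feature_types},
            model.j,
            model.threshold,
            len(new),
        )
        model.save(out / "models" / f"{adr.identifier}.json")
        report = edge_deletion_cv(
            g, adr, cfg.k_folds, cfg.seed, alpha=cfg.alpha, grid_step=cfg.grid_step
        )
        reports.append(report)
        for drug, score in sorted(model.scores.items()):
            is_new = drug in new
            if score > model.threshold or g.has_edge(drug, adr):
                pred_rows.append(
                    {
                        "adr_id": adr.identifier,
                        "drug_id": drug.identifier,
                        "score": round(score, 10),
                        "threshold": round(model.threshold, 10),
                        "is_new": int(is_new),
                    }
                )

    if n_trained == 0:
        log.error("no ADR in the graph admitted a model")
        return EXIT_NO_MODELS

    assign_confidence(reports)
    bins = {r.adr.identifier: r.confidence_bin for r in reports}
    for row in pred_rows:
        row["confidence_bin"] = bins.get(row["adr_id"], "low")
    cols = ["adr_id", "drug_id", "score", "threshold", "confidence_bin", "is_new"]
    pd.DataFrame(pred_rows, columns=cols).to_csv(out / "predictions.tsv", sep="\t", index=False)
    with open(out / "cv_summary.json", "w") as fh:
        json.dump([r.to_dict() for r in reports], fh, indent=2)
    cfg.to_file(out / "config.json")
    return EXIT_OK
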
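"""Seeded generators for knowledge graphs with planted enrichment structure.

The generator emulates the structure the prediction method assumes: a
multipartite drug graph where the known causes of one target ADR share a
small set of over-represented properties (targets, indications, other
ADRs). Background edges are independent Bernoulli draws at a low rate;
cause drugs link to the planted properties at an elevated rate, planting a
recoverable enrichment signal. A matching observation-table generator
produces externally "observed" drug–ADR associations with controllable
sensitivity and noise, standing in for an EHR-derived table.

Default condition: 200 drugs, 100 ADRs, 50 targets, 50 indications,
background edge probability 0.05, planted signal probability 0.6, 15 cause
drugs, 3 planted properties per type — small enough for sub-minute tests,
large enough for stable enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .evaluate import ObservationTable
from .graph import ADR, DRUG, FEATURE_TYPES, INDICATION, TARGET, KnowledgeGraph, NodeRef, filter_complete_drugs


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedSpec:
    """Parameters of one simulated study condition."""

    n_drugs: int = 200
    n_adrs: int = 100
    n_targets: int = 50
    n_indications: int = 50
    background_p: float = 0.05
    signal_p: float = 0.6
    n_causes: int = 15
    n_planted_per_type: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.background_p <= self.signal_p <= 1:
            raise SimulationError("need 0 <= background_p <= signal_p <= 1")
        if not 0 < self.n_causes < self.n_drugs:
            raise SimulationError("n_causes must lie strictly between 0 and n_drugs")
        if self.n_planted_per_type >= min(self.n_adrs, self.n_targets, self.n_indications):
            raise SimulationError("n_planted_per_type too large for the node pools")

    def null(self) -> "PlantedSpec":
        """The matched null condition: same sizes, no planted signal."""
        return replace(self, signal_p=self.background_p)


@dataclass
class GroundTruth:
    """What was planted: the cause drugs, the target ADR, the enriched properties."""

    target_adr: NodeRef
    causes: set[NodeRef]
    planted: dict[str, set[NodeRef]]
    spec: PlantedSpec
    all_causes: set[NodeRef] = field(default_factory=set)  # before drug filtering


def _ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(n)]


def generate_graph(spec: PlantedSpec) -> tuple[KnowledgeGraph, GroundTruth]:
    """Sample a planted-signal knowledge graph; identical seeds give identical graphs.

    Every drug–property edge is Bernoulli(background_p) except cause →
    planted-property edges, drawn at signal_p, and cause → target-ADR edges,
    always present. Non-cause drugs never link to the target ADR, so the
    planted cause set is exactly the label. The sampled graph is passed
    through :func:`filter_complete_drugs`, which can drop sparse drugs
    (including the occasional cause); the ground truth records the causes
    that survive.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    drugs = [NodeRef(DRUG, i) for i in _ids("D", spec.n_drugs)]
    pools = {
        ADR: [NodeRef(ADR, i) for i in _ids("A", spec.n_adrs)],
        INDICATION: [NodeRef(INDICATION, i) for i in _ids("I", spec.n_indications)],
        TARGET: [NodeRef(TARGET, i) for i in _ids("T", spec.n_targets)],
    }
    target_adr = pools[ADR][0]
    cause_idx = rng.choice(spec.n_drugs, size=spec.n_causes, replace=False)
    causes = {drugs[i] for i in cause_idx}
    planted: dict[str, set[NodeRef]] = {}
    for t in FEATURE_TYPES:
        candidates = [p for p in pools[t] if p != target_adr]
        pick = rng.choice(len(candidates), size=spec.n_planted_per_type, replace=False)
        planted[t] = {candidates[i] for i in pick}

    g = KnowledgeGraph()
    for t in FEATURE_TYPES:
        props = [p for p in pools[t] if p != target_adr]
        prob = np.full((spec.n_drugs, len(props)), spec.background_p)
        planted_cols = [j for j, p in enumerate(props) if p in planted[t]]
        prob[np.ix_(cause_idx, planted_cols)] = spec.signal_p
        hits = rng.random((spec.n_drugs, len(props))) < prob
        for i, j in zip(*np.nonzero(hits)):
            g.add_edge(drugs[i], props[j])
    for drug in sorted(causes):
        g.add_edge(drug, target_adr)

    g = filter_complete_drugs(g)
    surviving = causes & g.drugs
    return g, GroundTruth(target_adr, surviving, planted, spec, all_causes=causes)


def hold_out_causes(
    g: KnowledgeGraph, truth: GroundTruth, fraction: float, seed: int
) -> tuple[KnowledgeGraph, set[NodeRef]]:
    """Remove the target-ADR edge for a seeded random subset of causes.

    The held-out drugs remain in the graph as nodes (mirroring the
    edge-deletion cross-validation semantics) and are returned for recovery
    scoring. At least one cause is held out and at least one retained.
    """
    if not 0 < fraction < 1:
        raise SimulationError("fraction must lie strictly between 0 and 1")
    causes = sorted(truth.causes & g.drugs)
    n_out = max(1, round(fraction * len(causes)))
    if n_out >= len(causes):
        raise SimulationError("fraction would remove every cause; model untrainable")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    held = {causes[i] for i in rng.choice(len(causes), size=n_out, replace=False)}
    g2 = g.copy()
    for drug in sorted(held):
        g2.remove_edge(drug, truth.target_adr)
    return g2, held


def generate_observations(
    g: KnowledgeGraph,
    truth: GroundTruth,
    sensitivity: float,
    noise_rate: float,
    seed: int,
) -> ObservationTable:
    """Simulate an external observation table for the target ADR.

    Every drug in ``g`` is eligible. True (cause, target-ADR) pairs are
    observed with probability ``sensitivity``; every other pair with
    probability ``noise_rate``.
    """
    if not (0 <= sensitivity <= 1 and 0 <= noise_rate <= 1):
        raise SimulationError("rates must lie in [0, 1]")
    import pandas as pd

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    drugs = sorted(g.drugs)
    is_cause = np.array([d in truth.causes for d in drugs])
    p = np.where(is_cause, sensitivity, noise_rate)
    observed = rng.random(len(drugs)) < p
    df = pd.DataFrame(
        {
            "drug_id": [d.identifier for d in drugs],
            "adr_id": truth.target_adr.identifier,
            "observed": observed,
        }
    )
    return ObservationTable(df)


def derive_seeds(seed: int, n: int = 3) -> list[int]:
    """Split one global seed into independent per-stage seeds (< 2**31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]
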
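"""Enrichment-based predictor selection for a single ADR.

For the ADR being modelled, every candidate property node (another ADR, an
indication or a protein target) is tested for over-representation among the
ADR's known causes versus all other drugs in the graph, with a one-sided
Fisher exact test. p-values are Benjamini–Hochberg adjusted and properties
with q < alpha become the predictors of that feature type. A model can only
be trained if every feature type retains at least one predictor; otherwise
the outcome is :class:`NoModel`.

The modelled ADR node itself is never tested and never appears among
predictors: its adjacency is the label being predicted, so including it
would leak the label into the features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .graph import ADR, FEATURE_TYPES, GraphError, KnowledgeGraph, NodeRef


class EnrichmentError(ValueError):
    pass


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table for one (ADR, property) pair.

    a: known causes with the property; b: known causes without;
    c: other drugs with the property; d: other drugs without.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise EnrichmentError(f"negative cell in contingency table {self}")

    @property
    def n_causes(self) -> int:
        return self.a + self.b

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class EnrichmentResult:
    property: NodeRef
    feature_type: str
    table: ContingencyTable
    p_value: float
    q_value: float


@dataclass
class PredictorSet:
    """Significantly enriched properties for one ADR, grouped by feature type."""

    adr: NodeRef
    predictors: dict[str, list[EnrichmentResult]]

    def predictor_nodes(self, feature_type: str) -> set[NodeRef]:
        return {r.property for r in self.predictors.get(feature_type, [])}

    @property
    def feature_types(self) -> list[str]:
        return [t for t in FEATURE_TYPES if self.predictors.get(t)]

    @property
    def is_complete(self) -> bool:
        return all(self.predictors.get(t) for t in FEATURE_TYPES)

    def to_dict(self) -> dict:
        return {
            "adr": self.adr.identifier,
            "predictors": {
                t: [
                    {
                        "property": r.property.identifier,
                        "node_type": r.property.node_type,
                        "table": [r.table.a, r.table.b, r.table.c, r.table.d],
                        "p_value": r.p_value,
                        "q_value": r.q_value,
                    }
                    for r in rs
                ]
                for t, rs in self.predictors.items()
            },
        }


@dataclass(frozen=True)
class NoModel:
    """Distinguished outcome: some feature type had no significant predictor."""

    adr: NodeRef
    reason: str
    missing_types: tuple[str, ...] = field(default=())


def build_contingency(g: KnowledgeGraph, adr: NodeRef, prop: NodeRef) -> ContingencyTable:
    """Count the 2x2 table of ``prop`` over known causes of ``adr`` vs all other drugs."""
    if prop == adr:
        raise EnrichmentError("the modelled ADR cannot be its own candidate property")
    causes = g.neighbors(adr)  # raises GraphError if absent
    if not causes:
        raise EnrichmentError(f"{adr} has no known causes")
    with_prop = g.neighbors(prop) if g.has_node(prop) else set()
    n_drugs = len(g.drugs)
    a = len(causes & with_prop)
    b = len(causes) - a
    c = len(with_prop) - a
    d = n_drugs - len(causes) - c
    return ContingencyTable(a, b, c, d)


def fisher_exact_one_sided(t: ContingencyTable) -> float:
    """Right-tail Fisher exact p: P(X >= a), X ~ Hypergeom(a+b+c+d, a+c, a+b)."""
    return float(hypergeom.sf(t.a - 1, t.total, t.a + t.c, t.n_causes))


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values, positionally aligned with the input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise EnrichmentError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _candidate_tables(
    g: KnowledgeGraph,
    adr: NodeRef,
    feature_type: str,
    causes: set[NodeRef],
    *,
    test_all_candidates: bool,
) -> list[tuple[NodeRef, ContingencyTable]]:
    """Candidate universe and tables for one feature type.

    By default only properties adjacent to >=1 known cause are tested:
    a table with a = 0 can never be significant one-sided, but skipping
    those properties does change the number of hypotheses m entering BH.
    ``test_all_candidates`` widens the universe to every node of the type.
    """
    n_drugs = len(g.drugs)
    n_causes = len(causes)
    if test_all_candidates:
        candidates = g.nodes_of_type(feature_type)
    else:
        candidates = set()
        for drug in causes:
            candidates.update(g.neighbors(drug, feature_type))
    candidates.discard(adr)
    out = []
    for prop in sorted(candidates):
        with_prop = g.neighbors(prop)
        a = len(causes & with_prop)
        c = len(with_prop) - a
        out.append((prop, ContingencyTable(a, n_causes - a, c, n_drugs - n_causes - c)))
    return out


def select_predictors(
    g: KnowledgeGraph,
    adr: NodeRef,
    alpha: float = 0.05,
    *,
    pooled_fdr: bool = False,
    test_all_candidates: bool = False,
) -> PredictorSet | NoModel:
    """Select enriched predictor properties of every feature type for ``adr``.

    BH correction is applied within each feature type by default (the three
    predictor families are selected independently); ``pooled_fdr`` pools all
    tests into one family instead. Retention rule is strict: q < alpha.

    Returns :class:`NoModel` when any feature type has no surviving
    predictor; raises on an absent or causeless ADR node.
    """
    if not g.has_node(adr):
        raise GraphError(f"ADR {adr} not in graph")
    causes = g.neighbors(adr)
    if not causes:
        raise EnrichmentError(f"{adr} has no known causes")

    tables: dict[str, list[tuple[NodeRef, ContingencyTable]]] = {
        t: _candidate_tables(g, adr, t, causes, test_all_candidates=test_all_candidates)
        for t in FEATURE_TYPES
    }
    pvals = {
        t: np.array([fisher_exact_one_sided(tab) for _, tab in cand]) for t, cand in tables.items()
    }
    if pooled_fdr:
        pooled = np.concatenate([pvals[t] for t in FEATURE_TYPES]) if any(
            len(v) for v in pvals.values()
        ) else np.array([])
        qall = fdr_adjust(pooled) if pooled.size else pooled
        qvals, start = {}, 0
        for t in FEATURE_TYPES:
            qvals[t] = qall[start : start + len(pvals[t])]
            start += len(pvals[t])
    else:
        qvals = {t: fdr_adjust(p) if p.size else p for t, p in pvals.items()}

    predictors: dict[str, list[EnrichmentResult]] = {}
    for t in FEATURE_TYPES:
        results = [
            EnrichmentResult(prop, t, tab, float(p), float(q))
            for (prop, tab), p, q in zip(tables[t], pvals[t], qvals[t])
            if q < alpha
        ]
        results.sort(key=lambda r: (r.q_value, r.p_value, r.property))
        predictors[t] = results

    missing = tuple(t for t in FEATURE_TYPES if not predictors[t])
    if missing:
        return NoModel(adr, f"no significant predictors of type(s): {', '.join(missing)}", missing)
    return PredictorSet(adr, predictors)
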
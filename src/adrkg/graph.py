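"""Data model and I/O for the drug knowledge graph.

The graph is multipartite: drug nodes sit at exactly one end of every edge,
and the other end is an ADR, indication or target node. The edge type
(``has_adr``, ``has_indication``, ``has_target``) is implied by the type of
the non-drug endpoint, so edges are stored simply as (drug, property) pairs.

Identifier conventions follow the source databases — PubChem CID for drugs,
UMLS CUI for ADRs and indications, UniProt accession for targets — but
identifiers are treated as opaque case-sensitive strings and never validated
against an external ontology.
"""

from __future__ import annotations

import json
from typing import Iterable, Iterator, NamedTuple

import pandas as pd

DRUG = "drug"
ADR = "adr"
INDICATION = "indication"
TARGET = "target"

#: non-drug node types, in canonical column order
FEATURE_TYPES: tuple[str, ...] = (ADR, INDICATION, TARGET)

#: edge type implied by the non-drug endpoint
EDGE_TYPE_OF: dict[str, str] = {
    ADR: "has_adr",
    INDICATION: "has_indication",
    TARGET: "has_target",
}


class NodeRef(NamedTuple):
    """A typed node reference; hashable and totally ordered."""

    node_type: str
    identifier: str

    def __repr__(self) -> str:  # compact, e.g. drug:CID123
        return f"{self.node_type}:{self.identifier}"


class GraphError(ValueError):
    """Malformed input or an operation on a node absent from the graph."""


class KnowledgeGraph:
    """Multipartite drug knowledge graph backed by adjacency sets.

    Invariants: every edge joins one drug node to one non-drug node, there
    are no duplicate edges, and a node exists iff it has at least one edge.
    """

    def __init__(self, edges: Iterable[tuple[NodeRef, NodeRef]] = ()) -> None:
        self._fwd: dict[NodeRef, set[NodeRef]] = {}  # drug -> properties
        self._rev: dict[NodeRef, set[NodeRef]] = {}  # property -> drugs
        for drug, prop in edges:
            self.add_edge(drug, prop)

    # -- mutation ---------------------------------------------------------

    def add_edge(self, drug: NodeRef, prop: NodeRef) -> None:
        if drug.node_type != DRUG:
            raise GraphError(f"edge must start at a drug node, got {drug}")
        if prop.node_type not in EDGE_TYPE_OF:
            raise GraphError(f"unknown property node type: {prop}")
        if not drug.identifier or not prop.identifier:
            raise GraphError("empty identifier")
        self._fwd.setdefault(drug, set()).add(prop)
        self._rev.setdefault(prop, set()).add(drug)

    def remove_edge(self, drug: NodeRef, prop: NodeRef) -> None:
        try:
            self._fwd[drug].remove(prop)
            self._rev[prop].remove(drug)
        except KeyError:
            raise GraphError(f"edge {drug} -- {prop} not in graph") from None
        if not self._fwd[drug]:
            del self._fwd[drug]
        if not self._rev[prop]:
            del self._rev[prop]

    def copy(self) -> "KnowledgeGraph":
        g = KnowledgeGraph()
        g._fwd = {d: set(ps) for d, ps in self._fwd.items()}
        g._rev = {p: set(ds) for p, ds in self._rev.items()}
        return g

    # -- queries ----------------------------------------------------------

    @property
    def drugs(self) -> set[NodeRef]:
        return set(self._fwd)

    def nodes_of_type(self, node_type: str) -> set[NodeRef]:
        if node_type == DRUG:
            return self.drugs
        return {p for p in self._rev if p.node_type == node_type}

    @property
    def nodes(self) -> set[NodeRef]:
        return set(self._fwd) | set(self._rev)

    def has_node(self, node: NodeRef) -> bool:
        return node in self._fwd or node in self._rev

    def has_edge(self, drug: NodeRef, prop: NodeRef) -> bool:
        return prop in self._fwd.get(drug, ())

    def neighbors(self, node: NodeRef, node_type: str | None = None) -> set[NodeRef]:
        """All neighbors of ``node``, optionally restricted to one node type."""
        if node.node_type == DRUG:
            if node not in self._fwd:
                raise GraphError(f"node {node} not in graph")
            nbrs = self._fwd[node]
        else:
            if node not in self._rev:
                raise GraphError(f"node {node} not in graph")
            nbrs = self._rev[node]
        if node_type is None:
            return set(nbrs)
        return {n for n in nbrs if n.node_type == node_type}

    def degree(self, node: NodeRef) -> int:
        return len(self.neighbors(node))

    def edges(self) -> Iterator[tuple[NodeRef, NodeRef]]:
        for drug in self._fwd:
            for prop in self._fwd[drug]:
                yield drug, prop

    @property
    def n_edges(self) -> int:
        return sum(len(ps) for ps in self._fwd.values())

    @property
    def n_nodes(self) -> int:
        return len(self._fwd) + len(self._rev)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, KnowledgeGraph) and self._fwd == other._fwd

    def __repr__(self) -> str:
        return f"<KnowledgeGraph: {len(self._fwd)} drugs, {self.n_nodes} nodes, {self.n_edges} edges>"

    def to_networkx(self):
        """Export to a ``networkx.Graph`` with node/edge type attributes."""
        import networkx as nx

        g = nx.Graph()
        for node in self.nodes:
            g.add_node(node, node_type=node.node_type)
        for drug, prop in self.edges():
            g.add_edge(drug, prop, edge_type=EDGE_TYPE_OF[prop.node_type])
        return g


# -- I/O -------------------------------------------------------------------

_COLUMNS = ("drug_id", "node_id", "node_type")


def load_graph(
    source,
    *,
    drug_col: str = "drug_id",
    node_col: str = "node_id",
    type_col: str = "node_type",
    type_map: dict[str, str] | None = None,
    sep: str = "\t",
) -> KnowledgeGraph:
    """Load a knowledge graph from an edge-list table.

    ``source`` is a path to a delimited text file with a header, or a
    ``pandas.DataFrame``. Rows may repeat; the result is deduplicated and
    independent of row order. ``type_map`` optionally translates the file's
    node-type vocabulary onto {adr, indication, target}.

    Raises
    ------
    GraphError
        On a missing column, an empty identifier (named by line number), or
        an unrecognised node type.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep=sep, dtype=str, keep_default_na=False)
    for col in (drug_col, node_col, type_col):
        if col not in df.columns:
            raise GraphError(f"missing required column {col!r}")
    g = KnowledgeGraph()
    types = df[type_col].to_numpy()
    drugs = df[drug_col].to_numpy()
    nodes = df[node_col].to_numpy()
    for i in range(len(df)):
        line = i + 2  # 1-based, after the header line
        d, n, t = str(drugs[i]).strip(), str(nodes[i]).strip(), str(types[i]).strip()
        if type_map is not None:
            t = type_map.get(t, t)
        if not d or not n:
            raise GraphError(f"line {line}: empty identifier")
        if t not in EDGE_TYPE_OF:
            raise GraphError(f"line {line}: unknown node_type {t!r}")
        g.add_edge(NodeRef(DRUG, d), NodeRef(t, n))
    return g


def save_graph(g: KnowledgeGraph, path) -> None:
    """Write the canonical edge-list TSV (sorted, so round-trips are byte-identical)."""
    rows = sorted((d.identifier, p.identifier, p.node_type) for d, p in g.edges())
    df = pd.DataFrame(rows, columns=list(_COLUMNS))
    df.to_csv(path, sep="\t", index=False)


# -- filtering and summaries ----------------------------------------------


def filter_complete_drugs(g: KnowledgeGraph) -> KnowledgeGraph:
    """Retain only drugs with at least one ADR, one indication and one target edge.

    Non-drug nodes left without any edge are dropped with them, so node
    counts on the result refer to the connected graph. Idempotent.
    """
    out = KnowledgeGraph()
    for drug in g.drugs:
        nbrs = g.neighbors(drug)
        present = {p.node_type for p in nbrs}
        if all(t in present for t in FEATURE_TYPES):
            for prop in nbrs:
                out.add_edge(drug, prop)
    return out


def adjacency_count(g: KnowledgeGraph, drug: NodeRef, properties: set[NodeRef]) -> int:
    """Number of nodes in ``properties`` adjacent to ``drug`` (unscaled feature)."""
    if drug not in g._fwd:
        raise GraphError(f"drug {drug} not in graph")
    if not properties:
        return 0
    return len(g._fwd[drug] & properties)


def summarize_graph(g: KnowledgeGraph, top_k: int = 10) -> dict:
    """Per-type node/edge counts, degree medians, ADR prevalence leaders.

    Prevalence of an ADR is the fraction of drugs adjacent to it. On an
    empty graph all counts are zero and medians are reported as ``None``.
    """
    import statistics

    n_drugs = len(g.drugs)
    per_type = {}
    for t in FEATURE_TYPES:
        nodes = g.nodes_of_type(t)
        per_type[t] = {
            "n_nodes": len(nodes),
            "n_edges": sum(len(g._rev[p]) for p in nodes),
        }
    adrs = g.nodes_of_type(ADR)
    causes_per_adr = sorted(len(g._rev[a]) for a in adrs)
    adrs_per_drug = sorted(len(g.neighbors(d, ADR)) for d in g.drugs)
    top = sorted(adrs, key=lambda a: (-len(g._rev[a]), a.identifier))[:top_k]
    return {
        "n_drugs": n_drugs,
        "n_nodes": g.n_nodes,
        "n_edges": g.n_edges,
        "per_type": per_type,
        "median_causes_per_adr": statistics.median(causes_per_adr) if causes_per_adr else None,
        "median_adrs_per_drug": statistics.median(adrs_per_drug) if adrs_per_drug else None,
        "top_adrs_by_prevalence": [
            {
                "adr": a.identifier,
                "n_causes": len(g._rev[a]),
                "prevalence": len(g._rev[a]) / n_drugs if n_drugs else 0.0,
            }
            for a in top
        ],
        "fraction_single_cause_adrs": (
            sum(1 for n in causes_per_adr if n == 1) / len(causes_per_adr) if causes_per_adr else None
        ),
    }


def save_summary(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2)
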
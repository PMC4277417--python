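"""Project-specific trimming of an enriched GO-term set.

GO enrichment scores are highly redundant across hierarchy levels: a term
and its ancestors often carry the same signal because annotation is
inherited upward. Rather than using a predefined GO-slim, the trim keeps
the terms that appear primarily responsible for the enrichment in their
own sub-DAG:

* if an ancestor scores better (smaller p) than a term, the term's
  enrichment is inherited from above and the term is dropped;
* if a descendant scores strictly better than a term, the effect lives
  below and the term is dropped (it sees the signal in diluted form).

A term is kept iff neither displacement applies within the enriched set
(p below the threshold). Ties along a chain resolve in favor of the more
ancestral (more general) term. Relations are the transitive closure of
is_a and part_of edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx

RELATIONS = {"is_a", "part_of"}


@dataclass
class GoNode:
    """A GO term: identity, parents and an optional enrichment p-value."""

    term_id: str
    name: str = ""
    parents: list[tuple[str, str]] = field(default_factory=list)
    p_value: Optional[float] = None

    def __post_init__(self) -> None:
        for _, rel in self.parents:
            if rel not in RELATIONS:
                raise ValueError(
                    f"{self.term_id}: unsupported relation '{rel}'")
        if self.p_value is not None and not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"{self.term_id}: p-value outside [0,1]")


@dataclass
class TrimResult:
    kept: list[GoNode]
    #: term_id -> term_id of the node that displaced it
    displaced: dict[str, str]

    @property
    def kept_ids(self) -> list[str]:
        return [n.term_id for n in self.kept]


class GoDag:
    """A DAG of GO terms with enrichment scores."""

    def __init__(self, nodes: Iterable[GoNode]):
        self.nodes: dict[str, GoNode] = {}
        self.graph = nx.DiGraph()  # edges child -> parent
        for n in nodes:
            if n.term_id in self.nodes:
                raise ValueError(f"duplicate term {n.term_id}")
            self.nodes[n.term_id] = n
            self.graph.add_node(n.term_id)
        for n in self.nodes.values():
            for parent_id, _ in n.parents:
                self.graph.add_node(parent_id)
                if parent_id not in self.nodes:
                    self.nodes[parent_id] = GoNode(parent_id)
                self.graph.add_edge(n.term_id, parent_id)
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("GO relations contain a cycle")

    def ancestors(self, term_id: str) -> set[str]:
        return nx.descendants(self.graph, term_id)  # edges point upward

    def descendants(self, term_id: str) -> set[str]:
        return nx.ancestors(self.graph, term_id)

    # ---- construction -----------------------------------------------------

    @classmethod
    def from_tsv(cls, edges_path, scores_path) -> "GoDag":
        """Build from a 3-column edge TSV (child, parent, relation) and a
        2-column score TSV (term, p_value). Header rows optional."""
        parents: dict[str, list[tuple[str, str]]] = {}
        ids: list[str] = []
        with open(edges_path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ValueError(
                        f"{edges_path} line {lineno}: expected 3 columns")
                child, parent, rel = parts
                if lineno == 1 and rel not in RELATIONS:
                    continue  # header row
                parents.setdefault(child, []).append((parent, rel))
                for t in (child, parent):
                    if t not in ids:
                        ids.append(t)
        scores: dict[str, float] = {}
        with open(scores_path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(
                        f"{scores_path} line {lineno}: expected 2 columns")
                term, p = parts
                try:
                    scores[term] = float(p)
                except ValueError:
                    if lineno == 1:
                        continue  # header row
                    raise
                if term not in ids:
                    ids.append(term)
        return cls(GoNode(t, parents=parents.get(t, []),
                          p_value=scores.get(t)) for t in ids)

    @classmethod
    def from_obo(cls, path, scores: Optional[dict[str, float]] = None,
                 ) -> "GoDag":
        """Build from an OBO ontology file (is_a and part_of edges only)."""
        import obonet

        g = obonet.read_obo(str(path))
        scores = scores or {}
        nodes = []
        for term_id, data in g.nodes(data=True):
            parents: list[tuple[str, str]] = []
            for _, parent, key in g.out_edges(term_id, keys=True):
                if key in RELATIONS:
                    parents.append((parent, key))
            nodes.append(GoNode(term_id, name=data.get("name", ""),
                                parents=parents,
                                p_value=scores.get(term_id)))
        return cls(nodes)


def trim_go_terms(dag: GoDag, threshold: float = 0.001) -> TrimResult:
    """Trim the enriched set to its non-redundant members.

    A term n (p < threshold) is kept iff no enriched proper descendant has
    a strictly smaller p AND no enriched proper ancestor has p <= p(n).
    Non-kept enriched terms are reported with the term that displaced them.
    Output sorted by p ascending (term id breaks ties).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    enriched = {tid: n.p_value for tid, n in dag.nodes.items()
                if n.p_value is not None and n.p_value < threshold}
    kept: list[GoNode] = []
    displaced: dict[str, str] = {}
    for tid, p in enriched.items():
        winner = None
        for anc in dag.ancestors(tid):
            if anc in enriched and enriched[anc] <= p:
                if winner is None or enriched[anc] < enriched[winner]:
                    winner = anc
        if winner is None:
            for desc in dag.descendants(tid):
                if desc in enriched and enriched[desc] < p:
                    if winner is None or enriched[desc] < enriched[winner]:
                        winner = desc
        if winner is None:
            kept.append(dag.nodes[tid])
        else:
            displaced[tid] = winner
    kept.sort(key=lambda n: (n.p_value, n.term_id))
    return TrimResult(kept, displaced)
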
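"""Data model and I/O for UMLS-style predication knowledge graphs.

A predication is a directed subject--predicate--object assertion extracted
from biomedical literature (e.g. ``piroxicam TREATS osteoarthritis``).  Nodes
are UMLS-style concepts identified by a CUI (``C`` + 7 digits) and carry a
4-letter semantic-type code (PHSU, DSYN, GNGM, ...).  Edges carry a
``support_count``: the number of sentence-level predications aggregated into
the triple.

The on-disk interchange format is a header-bearing delimited text file
("SemMedDB-lite") with columns ``subject_cui, subject_name, subject_semtype,
predicate, object_cui, object_name, object_semtype[, support_count]``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

CUI_PATTERN = re.compile(r"^C\d{7}$")
SEMTYPE_PATTERN = re.compile(r"^[A-Z]{4}$")

TRIPLE_COLUMNS = [
    "subject_cui",
    "subject_name",
    "subject_semtype",
    "predicate",
    "object_cui",
    "object_name",
    "object_semtype",
]


class TripleFormatError(ValueError):
    """Raised when a triple file violates the interchange format."""


@dataclass(frozen=True)
class ConceptNode:
    """A UMLS-style concept: CUI, preferred name, semantic-type code."""

    cui: str
    name: str
    semtype: str

    def __post_init__(self) -> None:
        if not CUI_PATTERN.match(self.cui):
            raise ValueError(f"malformed CUI {self.cui!r}: expected C followed by 7 digits")
        if not SEMTYPE_PATTERN.match(self.semtype):
            raise ValueError(
                f"malformed semantic type {self.semtype!r}: expected 4 uppercase letters"
            )


@dataclass(frozen=True)
class Predication:
    """A directed subject--predicate--object edge with aggregated support."""

    subject_cui: str
    predicate: str
    object_cui: str
    support_count: int = 1

    def __post_init__(self) -> None:
        if self.subject_cui == self.object_cui:
            raise ValueError(f"self-loop predication on {self.subject_cui}")
        if self.support_count < 1:
            raise ValueError("support_count must be >= 1")


class KnowledgeGraph:
    """Typed multigraph of concept nodes joined by predication edges.

    At most one edge exists per ``(subject, predicate, object)``; duplicates
    aggregate their support counts.  Self-loops are rejected.  Direction is
    kept as given; traversal direction is a concern of the metapath layer.
    """

    def __init__(self) -> None:
        self._g = nx.MultiDiGraph()

    # -- construction -------------------------------------------------

    def add_node(self, node: ConceptNode) -> None:
        existing = self._g.nodes.get(node.cui)
        if existing is not None:
            if existing["semtype"] != node.semtype:
                raise ValueError(
                    f"conflicting semtype for {node.cui}: "
                    f"{existing['semtype']} vs {node.semtype}"
                )
            return
        self._g.add_node(node.cui, name=node.name, semtype=node.semtype)

    def add_edge(self, pred: Predication) -> None:
        """Insert a predication; duplicates aggregate ``support_count``."""
        for cui in (pred.subject_cui, pred.object_cui):
            if cui not in self._g:
                raise KeyError(f"edge endpoint {cui} not in graph")
        if self._g.has_edge(pred.subject_cui, pred.object_cui, key=pred.predicate):
            self._g[pred.subject_cui][pred.object_cui][pred.predicate][
                "support_count"
            ] += pred.support_count
        else:
            self._g.add_edge(
                pred.subject_cui,
                pred.object_cui,
                key=pred.predicate,
                support_count=pred.support_count,
            )

    # -- inspection ---------------------------------------------------

    def __contains__(self, cui: str) -> bool:
        return cui in self._g

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def node(self, cui: str) -> ConceptNode:
        try:
            data = self._g.nodes[cui]
        except KeyError:
            raise KeyError(f"unknown CUI {cui}") from None
        return ConceptNode(cui=cui, name=data["name"], semtype=data["semtype"])

    def semtype_of(self, cui: str) -> str:
        try:
            return self._g.nodes[cui]["semtype"]
        except KeyError:
            raise KeyError(f"unknown CUI {cui}") from None

    def name_of(self, cui: str) -> str:
        return self._g.nodes[cui]["name"]

    def nodes(self) -> Iterator[ConceptNode]:
        for cui in sorted(self._g.nodes):
            yield self.node(cui)

    def edges(self) -> Iterator[Predication]:
        for s, o, p, data in sorted(self._g.edges(keys=True, data=True)):
            yield Predication(
                subject_cui=s, predicate=p, object_cui=o,
                support_count=data["support_count"],
            )

    @property
    def semtype_index(self) -> dict[str, list[str]]:
        """Mapping semtype -> sorted CUIs; partitions the node set."""
        index: dict[str, list[str]] = {}
        for cui in self._g.nodes:
            index.setdefault(self._g.nodes[cui]["semtype"], []).append(cui)
        return {st: sorted(cuis) for st, cuis in sorted(index.items())}

    @property
    def semtypes(self) -> set[str]:
        return {data["semtype"] for _, data in self._g.nodes(data=True)}

    @property
    def predicate_vocabulary(self) -> set[str]:
        return {p for _, _, p in self._g.edges(keys=True)}

    def nodes_of_semtype(self, semtype: str) -> list[str]:
        """Sorted CUIs of a semantic type (empty list if none)."""
        return sorted(
            cui for cui, data in self._g.nodes(data=True) if data["semtype"] == semtype
        )

    def degree(self, cui: str) -> int:
        """Incident predication count, ignoring direction and support."""
        if cui not in self._g:
            raise KeyError(f"unknown CUI {cui}")
        return self._g.in_degree(cui) + self._g.out_degree(cui)

    def isolated_nodes(self) -> list[str]:
        return sorted(cui for cui in self._g.nodes if self.degree(cui) == 0)

    def step_edges(
        self, predicate: str, from_semtype: str, to_semtype: str, reverse: bool = False
    ) -> Iterator[tuple[str, str, int]]:
        """Yield ``(from_node, to_node, support)`` for one metapath step.

        ``reverse=True`` walks object->subject.
        """
        for s, o, p, data in self._g.edges(keys=True, data=True):
            if p != predicate:
                continue
            if reverse:
                s, o = o, s
            if (
                self._g.nodes[s]["semtype"] == from_semtype
                and self._g.nodes[o]["semtype"] == to_semtype
            ):
                yield s, o, data["support_count"]

    def adjacency_index(self) -> dict[str, list[tuple[str, str, bool, str]]]:
        """Per-node incident-edge index for fast traversal.

        Maps each CUI to a sorted list of ``(neighbor, predicate,
        traversal_is_reverse, neighbor_semtype)``; one forward and one
        reverse entry per predication.  Built in one pass over the edges.
        """
        index: dict[str, list[tuple[str, str, bool, str]]] = {
            cui: [] for cui in self._g.nodes
        }
        for s, o, p in self._g.edges(keys=True):
            index[s].append((o, p, False, self._g.nodes[o]["semtype"]))
            index[o].append((s, p, True, self._g.nodes[s]["semtype"]))
        for entries in index.values():
            entries.sort()
        return index

    def successors(self, cui: str, predicate: str, reverse: bool = False) -> list[str]:
        """Neighbors reachable along one predicate (subject->object, or reversed)."""
        if reverse:
            return sorted(
                s for s, _, p in self._g.in_edges(cui, keys=True) if p == predicate
            )
        return sorted(
            o for _, o, p in self._g.out_edges(cui, keys=True) if p == predicate
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnowledgeGraph):
            return NotImplemented
        return list(self.nodes()) == list(other.nodes()) and list(self.edges()) == list(
            other.edges()
        )

    def copy(self) -> "KnowledgeGraph":
        out = KnowledgeGraph()
        out._g = self._g.copy()
        return out


def read_triples(
    source: str | Path | IO[str],
    dialect: str = "tsv",
    nodes_sidecar: str | Path | IO[str] | None = None,
) -> KnowledgeGraph:
    """Parse a SemMedDB-lite triple file into a :class:`KnowledgeGraph`.

    Duplicate ``(s, p, o)`` rows have their support counts summed; self-loop
    rows are dropped with a logged warning.  Raises
    :class:`TripleFormatError` on a missing column, a malformed CUI (with the
    1-based data row number) or an empty file.

    ``nodes_sidecar`` optionally names a (cui, name, semtype) file carrying
    nodes with no predications, which the triple format cannot represent.
    """
    sep = {"tsv": "\t", "csv": ","}[dialect]
    df = pd.read_csv(source, sep=sep, dtype=str)
    missing = [c for c in TRIPLE_COLUMNS if c not in df.columns]
    if missing:
        raise TripleFormatError(f"missing mandatory column(s): {', '.join(missing)}")
    if "support_count" not in df.columns:
        df["support_count"] = "1"
    if len(df) == 0:
        raise TripleFormatError("no predications")

    graph = KnowledgeGraph()
    n_dropped = 0
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            subj = ConceptNode(row.subject_cui, row.subject_name, row.subject_semtype)
            obj = ConceptNode(row.object_cui, row.object_name, row.object_semtype)
        except ValueError as exc:
            raise TripleFormatError(f"row {i}: {exc}") from exc
        graph.add_node(subj)
        graph.add_node(obj)
        if row.subject_cui == row.object_cui:
            n_dropped += 1
            logger.warning("row %d: dropped self-loop on %s", i, row.subject_cui)
            continue
        graph.add_edge(
            Predication(
                subject_cui=row.subject_cui,
                predicate=row.predicate,
                object_cui=row.object_cui,
                support_count=int(row.support_count),
            )
        )
    if n_dropped:
        logger.warning("dropped %d self-loop row(s) at load", n_dropped)
    if nodes_sidecar is not None:
        side = pd.read_csv(nodes_sidecar, sep=sep, dtype=str)
        for row in side.itertuples(index=False):
            graph.add_node(ConceptNode(row.cui, row.name, row.semtype))
    return graph


def write_triples(graph: KnowledgeGraph, sink: str | Path | IO[str]) -> int:
    """Serialize edges in deterministic (subject, predicate, object) order.

    Returns the number of data rows written.  Isolated nodes are not
    representable in the triple format (use :func:`write_nodes` for a
    node sidecar).
    """
    rows = []
    for e in graph.edges():
        s, o = graph.node(e.subject_cui), graph.node(e.object_cui)
        rows.append(
            {
                "subject_cui": s.cui,
                "subject_name": s.name,
                "subject_semtype": s.semtype,
                "predicate": e.predicate,
                "object_cui": o.cui,
                "object_name": o.name,
                "object_semtype": o.semtype,
                "support_count": e.support_count,
            }
        )
    df = pd.DataFrame(rows, columns=TRIPLE_COLUMNS + ["support_count"])
    df.to_csv(sink, sep="\t", index=False)
    return len(df)


def write_nodes(graph: KnowledgeGraph, sink: str | Path | IO[str]) -> int:
    """Write the node sidecar (cui, name, semtype); returns row count."""
    rows = [
        {"cui": n.cui, "name": n.name, "semtype": n.semtype} for n in graph.nodes()
    ]
    pd.DataFrame(rows, columns=["cui", "name", "semtype"]).to_csv(
        sink, sep="\t", index=False
    )
    return len(rows)


def filter_by_semtype(graph: KnowledgeGraph, allowed: Iterable[str]) -> KnowledgeGraph:
    """Induced subgraph on nodes whose semtype is in ``allowed``.

    Edges survive iff both endpoints do.  An unknown semtype in ``allowed``
    is a warning, not an error; an empty ``allowed`` set is a ValueError.
    """
    allowed = set(allowed)
    if not allowed:
        raise ValueError("allowed semtype set must be non-empty")
    unknown = allowed - graph.semtypes
    if unknown:
        logger.warning("semtype(s) not present in graph: %s", ", ".join(sorted(unknown)))
    out = KnowledgeGraph()
    for node in graph.nodes():
        if node.semtype in allowed:
            out.add_node(node)
    for edge in graph.edges():
        if edge.subject_cui in out and edge.object_cui in out:
            out.add_edge(edge)
    return out
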
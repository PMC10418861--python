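"""Metapath enumeration, path counting and degree-weighted path counts.

A metapath is a type-level template: an alternating sequence of semantic
types and (predicate, direction) steps, e.g.::

    PHSU-[AFFECTS>]-GNGM-[ASSOCIATED_WITH>]-DSYN

``>`` marks forward traversal (subject -> object) and ``<`` reverse.  A
concrete *instance* of a metapath is a node sequence whose consecutive pairs
are joined by edges of the step's predicate in the step's direction.
Predications are directed but relevance is not, so reverse steps are
first-class.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .kg import KnowledgeGraph

FORWARD = "forward"
REVERSE = "reverse"


@dataclass(frozen=True, order=True)
class MetaPathStep:
    from_semtype: str
    predicate: str
    to_semtype: str
    direction: str = FORWARD

    def __post_init__(self) -> None:
        if self.direction not in (FORWARD, REVERSE):
            raise ValueError(f"direction must be forward/reverse, got {self.direction!r}")

    @property
    def is_reverse(self) -> bool:
        return self.direction == REVERSE

    def reversed(self) -> "MetaPathStep":
        return MetaPathStep(
            from_semtype=self.to_semtype,
            predicate=self.predicate,
            to_semtype=self.from_semtype,
            direction=REVERSE if self.direction == FORWARD else FORWARD,
        )


@dataclass(frozen=True)
class MetaPath:
    """Ordered, type-compatible sequence of steps."""

    steps: tuple[MetaPathStep, ...]

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("a metapath needs at least one step")
        for a, b in zip(self.steps, self.steps[1:]):
            if a.to_semtype != b.from_semtype:
                raise ValueError(
                    f"type-incompatible steps: ...{a.to_semtype} then {b.from_semtype}..."
                )

    @property
    def length(self) -> int:
        return len(self.steps)

    @property
    def source_semtype(self) -> str:
        return self.steps[0].from_semtype

    @property
    def target_semtype(self) -> str:
        return self.steps[-1].to_semtype

    def reversed(self) -> "MetaPath":
        return MetaPath(tuple(s.reversed() for s in reversed(self.steps)))

    def concat(self, other: "MetaPath") -> "MetaPath":
        return MetaPath(self.steps + other.steps)

    def __str__(self) -> str:
        return format_metapath(self)

    def sort_key(self) -> tuple:
        return (
            self.length,
            tuple((s.from_semtype, s.predicate, s.direction, s.to_semtype) for s in self.steps),
        )


_STEP_RE = re.compile(r"-\[(<?)([A-Z_]+)(>?)\]-")


def format_metapath(mp: MetaPath) -> str:
    """Render the text notation, e.g. ``PHSU-[AFFECTS>]-GNGM``."""
    parts = [mp.steps[0].from_semtype]
    for step in mp.steps:
        arrow = f"-[{step.predicate}>]-" if not step.is_reverse else f"-[<{step.predicate}]-"
        parts.append(arrow)
        parts.append(step.to_semtype)
    return "".join(parts)


def parse_metapath(text: str) -> MetaPath:
    """Inverse of :func:`format_metapath`; raises ValueError on bad syntax."""
    tokens = _STEP_RE.split(text)
    # split yields: semtype, (lt, pred, gt, semtype)*
    if len(tokens) < 5 or (len(tokens) - 1) % 4 != 0:
        raise ValueError(f"cannot parse metapath notation: {text!r}")
    steps = []
    cur = tokens[0]
    for i in range(1, len(tokens), 4):
        lt, pred, gt, nxt = tokens[i : i + 4]
        if (lt == "<") == (gt == ">"):
            raise ValueError(f"step needs exactly one of '<'/'>' in {text!r}")
        steps.append(
            MetaPathStep(
                from_semtype=cur,
                predicate=pred,
                to_semtype=nxt,
                direction=REVERSE if lt == "<" else FORWARD,
            )
        )
        cur = nxt
    return MetaPath(tuple(steps))


def enumerate_metapaths(
    graph: KnowledgeGraph,
    source_semtypes: Iterable[str],
    target_cui: str,
    max_len: int = 3,
) -> list[MetaPath]:
    """Every type-level metapath with a concrete simple-path instance ending
    exactly at ``target_cui`` and starting at one of ``source_semtypes``.

    Walks backward from the target over concrete edges (both directions),
    keeping instances node-distinct, and records the type-level signature of
    each.  Output is deduplicated and sorted by (length, step descriptors).
    """
    if not 1 <= max_len <= 4:
        raise ValueError(f"max_len must be in [1, 4], got {max_len}")
    if target_cui not in graph:
        raise KeyError(f"target {target_cui} not in graph")
    source_semtypes = set(source_semtypes)
    adjacency = graph.adjacency_index()
    node_semtype = {cui: graph.semtype_of(cui) for cui in adjacency}

    found: set[tuple[MetaPathStep, ...]] = set()

    def extend(node: str, visited: frozenset[str], suffix: tuple[MetaPathStep, ...]):
        if len(suffix) >= max_len:
            return
        for nbr, predicate, is_reverse, nbr_semtype in adjacency[node]:
            if nbr in visited:
                continue
            # step oriented nbr -> node: traversing backward flips direction
            step = MetaPathStep(
                from_semtype=nbr_semtype,
                predicate=predicate,
                to_semtype=node_semtype[node],
                direction=FORWARD if is_reverse else REVERSE,
            )
            new_suffix = (step,) + suffix
            if nbr_semtype in source_semtypes:
                found.add(new_suffix)
            extend(nbr, visited | {nbr}, new_suffix)

    extend(target_cui, frozenset({target_cui}), ())
    return sorted((MetaPath(s) for s in found), key=MetaPath.sort_key)


def _iter_instances(
    graph: KnowledgeGraph,
    s: str,
    t: str,
    mp: MetaPath,
    allow_revisits: bool,
):
    """Yield concrete instances (node tuples, endpoints included) of ``mp``
    from ``s`` to ``t``."""

    def walk(node: str, depth: int, path: tuple[str, ...]):
        if depth == mp.length:
            if node == t:
                yield path
            return
        step = mp.steps[depth]
        if graph.semtype_of(node) != step.from_semtype:
            return
        for nbr in graph.successors(node, step.predicate, reverse=step.is_reverse):
            if graph.semtype_of(nbr) != step.to_semtype:
                continue
            if not allow_revisits and nbr in path:
                continue
            yield from walk(nbr, depth + 1, path + (nbr,))

    yield from walk(s, 0, (s,))


def _check_endpoints(graph: KnowledgeGraph, s: str, t: str, mp: MetaPath) -> None:
    for cui, semtype, role in (
        (s, mp.source_semtype, "source"),
        (t, mp.target_semtype, "target"),
    ):
        actual = graph.semtype_of(cui)
        if actual != semtype:
            raise ValueError(
                f"{role} {cui} has semtype {actual}, metapath expects {semtype}"
            )


def count_paths(
    graph: KnowledgeGraph,
    s: str,
    t: str,
    mp: MetaPath,
    allow_revisits: bool = False,
) -> int:
    """Number of concrete instances of ``mp`` from ``s`` to ``t``.

    By default instances are simple paths (no node revisited); set
    ``allow_revisits`` for walk semantics, which is what the matrix HeteSim
    formulation counts.
    """
    _check_endpoints(graph, s, t, mp)
    return sum(1 for _ in _iter_instances(graph, s, t, mp, allow_revisits))


def dwpc(
    graph: KnowledgeGraph,
    s: str,
    t: str,
    mp: MetaPath,
    w: float = 0.4,
    allow_revisits: bool = False,
) -> float:
    """Degree-weighted path count: sum over instances of the product of
    ``degree(node)**(-w)`` over every node on the instance, endpoints
    included.

    ``w = 0`` reduces exactly to :func:`count_paths`.  Larger ``w`` damps
    paths through promiscuous hub nodes; endpoint inclusion additionally
    penalizes promiscuous source drugs.  Degrees are whole-graph undirected
    predication counts.
    """
    if not (w >= 0 and w == w):
        raise ValueError("damping exponent w must be finite and >= 0")
    _check_endpoints(graph, s, t, mp)
    total = 0.0
    for inst in _iter_instances(graph, s, t, mp, allow_revisits):
        prod = 1.0
        for node in inst:
            prod *= graph.degree(node) ** (-w)
        total += prod
    return total
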
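"""HeteSim relevance along metapaths on a typed predication graph.

HeteSim measures how related a source and a target node are along a
metapath: walk probability mass from both ends toward the path midpoint and
take the cosine similarity of the two midpoint distributions.  The score is
normalized to [0, 1]; 1 means the two nodes reach the midpoint with
identical relative probabilities, 0 means at least one side cannot reach it
at all.

For an odd-length metapath there is no midpoint node layer, so the middle
step's *edges* are materialized as instance nodes (each connected to the
edge's two endpoints) and the even rule is applied there — the standard
HeteSim construction.

Semantics are walk-based (row-stochastic transition-matrix products).  A
brute-force walk enumerator with no matrix algebra is provided as an
independent oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np
from scipy import sparse

from .kg import KnowledgeGraph
from .metapaths import MetaPath, MetaPathStep

logger = logging.getLogger(__name__)

ROW_STOCHASTIC_TOL = 1e-12


@dataclass(frozen=True)
class HeteSimScore:
    source_cui: str
    target_cui: str
    metapath: Union[MetaPath, str]
    value: float

    def __post_init__(self) -> None:
        if not -1e-9 <= self.value <= 1 + 1e-9:
            raise ValueError(f"HeteSim score out of [0, 1]: {self.value}")


@dataclass(frozen=True)
class TransitionOperator:
    """Row-stochastic map from instances of one semtype to another.

    Rows with no out-edge are all-zero; every nonzero row sums to 1 within
    1e-12.
    """

    step: MetaPathStep
    from_nodes: tuple[str, ...]
    to_nodes: tuple[str, ...]
    matrix: sparse.csr_matrix


def _row_normalize(mat: sparse.csr_matrix) -> sparse.csr_matrix:
    sums = np.asarray(mat.sum(axis=1)).ravel()
    inv = np.divide(1.0, sums, out=np.zeros_like(sums, dtype=float), where=sums > 0)
    return sparse.diags(inv) @ mat


def transition_operator(
    graph: KnowledgeGraph, step: MetaPathStep, weighted: bool = False
) -> TransitionOperator:
    """Build the row-stochastic operator for one metapath step.

    Unweighted (default): uniform over out-neighbors.  Weighted: edge mass
    proportional to ``support_count`` before normalization.
    """
    from_nodes = tuple(graph.nodes_of_semtype(step.from_semtype))
    to_nodes = tuple(graph.nodes_of_semtype(step.to_semtype))
    if not from_nodes or not to_nodes:
        raise ValueError(
            f"no nodes of semtype {step.from_semtype if not from_nodes else step.to_semtype}"
        )
    fi = {c: i for i, c in enumerate(from_nodes)}
    ti = {c: i for i, c in enumerate(to_nodes)}
    rows, cols, vals = [], [], []
    for u, v, support in graph.step_edges(
        step.predicate, step.from_semtype, step.to_semtype, reverse=step.is_reverse
    ):
        rows.append(fi[u])
        cols.append(ti[v])
        vals.append(float(support) if weighted else 1.0)
    mat = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(from_nodes), len(to_nodes))
    )
    if mat.nnz == 0:
        logger.warning("step %s has no edges; operator is all-zero", step)
    return TransitionOperator(
        step=step, from_nodes=from_nodes, to_nodes=to_nodes, matrix=_row_normalize(mat)
    )


class OperatorCache:
    """Memoizes transition operators per (step, weighted) for one graph."""

    def __init__(self, graph: KnowledgeGraph, weighted: bool = False) -> None:
        self.graph = graph
        self.weighted = weighted
        self._ops: dict[MetaPathStep, TransitionOperator] = {}
        self._middles: dict[MetaPathStep, tuple] = {}

    def get(self, step: MetaPathStep) -> TransitionOperator:
        if step not in self._ops:
            self._ops[step] = transition_operator(self.graph, step, self.weighted)
        return self._ops[step]

    def middle(self, step: MetaPathStep) -> tuple:
        if step not in self._middles:
            self._middles[step] = _middle_edge_operators(self.graph, step, self.weighted)
        return self._middles[step]


def _middle_edge_operators(
    graph: KnowledgeGraph, step: MetaPathStep, weighted: bool
) -> tuple[sparse.csr_matrix, sparse.csr_matrix, tuple[str, ...], tuple[str, ...]]:
    """Half-step operators onto the middle step's edge-instance nodes.

    Returns (H_left, H_right, from_nodes, to_nodes): H_left maps
    from_semtype nodes onto edges, H_right maps to_semtype nodes onto edges;
    both row-normalized.
    """
    from_nodes = tuple(graph.nodes_of_semtype(step.from_semtype))
    to_nodes = tuple(graph.nodes_of_semtype(step.to_semtype))
    fi = {c: i for i, c in enumerate(from_nodes)}
    ti = {c: i for i, c in enumerate(to_nodes)}
    edges = sorted(
        graph.step_edges(
            step.predicate, step.from_semtype, step.to_semtype, reverse=step.is_reverse
        )
    )
    lr, lc, lv, rr, rc, rv = [], [], [], [], [], []
    for j, (u, v, support) in enumerate(edges):
        mass = float(support) if weighted else 1.0
        lr.append(fi[u]); lc.append(j); lv.append(mass)
        rr.append(ti[v]); rc.append(j); rv.append(mass)
    n_e = len(edges)
    h_left = _row_normalize(
        sparse.csr_matrix((lv, (lr, lc)), shape=(len(from_nodes), n_e))
    )
    h_right = _row_normalize(
        sparse.csr_matrix((rv, (rr, rc)), shape=(len(to_nodes), n_e))
    )
    return h_left, h_right, from_nodes, to_nodes


def _midpoint_operators(
    graph: KnowledgeGraph, mp: MetaPath, cache: OperatorCache | None, weighted: bool
) -> tuple[sparse.csr_matrix, sparse.csr_matrix, tuple[str, ...], tuple[str, ...]]:
    """(L, R, source_nodes, target_nodes) with L mapping source nodes and R
    mapping target nodes onto the common midpoint space."""
    if cache is None:
        cache = OperatorCache(graph, weighted)
    k = mp.length // 2
    left = None
    for step in mp.steps[:k]:
        op = cache.get(step)
        left = op.matrix if left is None else left @ op.matrix
    src_nodes = cache.get(mp.steps[0]).from_nodes if k else ()
    right = None
    for step in reversed(mp.steps[k + (mp.length % 2):]):
        op = cache.get(step.reversed())
        right = op.matrix if right is None else right @ op.matrix
    tgt_nodes = cache.get(mp.steps[-1].reversed()).from_nodes

    if mp.length % 2 == 1:
        h_left, h_right, mid_from, mid_to = cache.middle(mp.steps[k])
        left = h_left if left is None else left @ h_left
        right = h_right if right is None else right @ h_right
        if mp.length == 1:
            src_nodes, tgt_nodes = mid_from, mid_to
    return left.tocsr(), right.tocsr(), src_nodes, tgt_nodes


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.clip(a @ b / (na * nb), 0.0, 1.0))


def hetesim_score(
    graph: KnowledgeGraph,
    s: str,
    t: str,
    mp: MetaPath,
    weighted: bool = False,
    cache: OperatorCache | None = None,
) -> HeteSimScore:
    """HeteSim relevance of ``s`` to ``t`` along metapath ``mp``.

    Cosine similarity of the two midpoint reachability distributions; 0 when
    either endpoint cannot reach the midpoint.  Raises ValueError when an
    endpoint's semtype does not match the metapath.
    """
    for cui, want, role in ((s, mp.source_semtype, "source"), (t, mp.target_semtype, "target")):
        actual = graph.semtype_of(cui)
        if actual != want:
            raise ValueError(f"{role} {cui} is {actual}, metapath expects {want}")
    left, right, src_nodes, tgt_nodes = _midpoint_operators(graph, mp, cache, weighted)
    lv = np.asarray(left[src_nodes.index(s)].todense()).ravel()
    rv = np.asarray(right[tgt_nodes.index(t)].todense()).ravel()
    return HeteSimScore(source_cui=s, target_cui=t, metapath=mp, value=_cosine(lv, rv))


def hetesim_profile(
    graph: KnowledgeGraph,
    t: str,
    mp: MetaPath,
    weighted: bool = False,
    cache: OperatorCache | None = None,
) -> dict[str, float]:
    """HeteSim of *every* node of the metapath's source semtype against ``t``.

    Equivalent to calling :func:`hetesim_score` per source, but computed with
    one matrix product; used by the simulation layer.
    """
    if graph.semtype_of(t) != mp.target_semtype:
        raise ValueError(f"target {t} is {graph.semtype_of(t)}, metapath expects {mp.target_semtype}")
    left, right, src_nodes, tgt_nodes = _midpoint_operators(graph, mp, cache, weighted)
    rv = np.asarray(right[tgt_nodes.index(t)].todense()).ravel()
    rn = np.linalg.norm(rv)
    if rn == 0.0:
        return {c: 0.0 for c in src_nodes}
    dots = np.asarray((left @ rv)).ravel()
    row_norms = np.sqrt(np.asarray(left.multiply(left).sum(axis=1)).ravel())
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(row_norms > 0, dots / (row_norms * rn), 0.0)
    scores = np.clip(scores, 0.0, 1.0)
    return dict(zip(src_nodes, scores.tolist()))


# ---------------------------------------------------------------------------
# brute-force oracle: explicit walk enumeration, no matrix algebra
# ---------------------------------------------------------------------------

class WalkBudgetExceeded(RuntimeError):
    """The brute-force enumerator refused a graph too large to walk."""


def _spread(
    graph: KnowledgeGraph,
    dist: dict[str, float],
    step: MetaPathStep,
    weighted: bool,
    budget: list[int],
) -> dict[str, float]:
    out: dict[str, float] = {}
    for node, p in dist.items():
        nbrs = [
            n
            for n in graph.successors(node, step.predicate, reverse=step.is_reverse)
            if graph.semtype_of(n) == step.to_semtype
        ]
        if not nbrs:
            continue
        if weighted:
            weights = {}
            for u, v, support in graph.step_edges(
                step.predicate, step.from_semtype, step.to_semtype, reverse=step.is_reverse
            ):
                if u == node:
                    weights[v] = support
            total = sum(weights.values())
            shares = {n: weights[n] / total for n in nbrs}
        else:
            shares = {n: 1.0 / len(nbrs) for n in nbrs}
        for n in nbrs:
            budget[0] -= 1
            if budget[0] < 0:
                raise WalkBudgetExceeded(
                    "walk-extension budget exceeded; use the matrix implementation"
                )
            out[n] = out.get(n, 0.0) + p * shares[n]
    return out


def _spread_to_edges(
    graph: KnowledgeGraph,
    dist: dict[str, float],
    step: MetaPathStep,
    from_side: bool,
    weighted: bool,
) -> dict[tuple, float]:
    out: dict[tuple, float] = {}
    incident: dict[str, list[tuple]] = {}
    masses: dict[tuple, float] = {}
    for u, v, support in graph.step_edges(
        step.predicate, step.from_semtype, step.to_semtype, reverse=step.is_reverse
    ):
        key = (u, v)
        masses[key] = float(support) if weighted else 1.0
        incident.setdefault(u if from_side else v, []).append(key)
    for node, p in dist.items():
        edges = incident.get(node, [])
        total = sum(masses[e] for e in edges)
        for e in edges:
            out[e] = out.get(e, 0.0) + p * masses[e] / total
    return out


def hetesim_brute_force(
    graph: KnowledgeGraph,
    s: str,
    t: str,
    mp: MetaPath,
    weighted: bool = False,
    max_extensions: int = 10**6,
) -> HeteSimScore:
    """HeteSim by explicit walk enumeration and midpoint accumulation.

    Independent of the matrix implementation (dict arithmetic only); refuses
    graphs that would need more than ``max_extensions`` walk extensions.
    """
    for cui, want, role in ((s, mp.source_semtype, "source"), (t, mp.target_semtype, "target")):
        if graph.semtype_of(cui) != want:
            raise ValueError(f"{role} {cui} is {graph.semtype_of(cui)}, metapath expects {want}")
    budget = [max_extensions]
    k = mp.length // 2
    left: dict = {s: 1.0}
    for step in mp.steps[:k]:
        left = _spread(graph, left, step, weighted, budget)
    right: dict = {t: 1.0}
    for step in reversed(mp.steps[k + (mp.length % 2):]):
        right = _spread(graph, right, step.reversed(), weighted, budget)
    if mp.length % 2 == 1:
        mid = mp.steps[k]
        left = _spread_to_edges(graph, left, mid, from_side=True, weighted=weighted)
        right = _spread_to_edges(graph, right, mid, from_side=False, weighted=weighted)
    keys = sorted(set(left) | set(right))
    a = np.array([left.get(x, 0.0) for x in keys])
    b = np.array([right.get(x, 0.0) for x in keys])
    value = _cosine(a, b) if keys else 0.0
    return HeteSimScore(source_cui=s, target_cui=t, metapath=mp, value=value)


def aggregate_hetesim(
    graph: KnowledgeGraph,
    s: str,
    targets: Sequence[str],
    metapaths: Sequence[MetaPath],
    weighted: bool = False,
    cache: OperatorCache | None = None,
) -> HeteSimScore:
    """Mean HeteSim of ``s`` over all metapaths, then over all targets.

    A metapath whose source semtype does not match ``s`` (or with no
    instance) contributes 0, so the score stays a mean over the same
    denominator for every candidate of a simulation.
    """
    if not metapaths:
        raise ValueError("metapath list must be non-empty")
    for t in targets:
        if t not in graph:
            raise KeyError(f"target {t} not in graph")
    if cache is None:
        cache = OperatorCache(graph, weighted)
    s_type = graph.semtype_of(s)
    per_target = []
    for t in targets:
        t_type = graph.semtype_of(t)
        vals = []
        for mp in metapaths:
            if mp.source_semtype != s_type or mp.target_semtype != t_type:
                vals.append(0.0)
            else:
                vals.append(hetesim_score(graph, s, t, mp, weighted, cache).value)
        per_target.append(float(np.mean(vals)))
    return HeteSimScore(
        source_cui=s,
        target_cui=",".join(targets),
        metapath="aggregate",
        value=float(np.mean(per_target)),
    )
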
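"""One relevance "simulation": rank candidate source nodes against targets.

A simulation fixes one or more target concepts and a set of allowed source
semantic types, enumerates every metapath from those types to each target,
scores every candidate by mean HeteSim (or by a degree-weighted path count),
min-max normalizes the scores, and returns a deterministic ranking.
Normalization is per-simulation so that scores are comparable across
simulations run on different targets.

Also houses unsupervised rank aggregation: combining several ranked lists
into one consensus without labels, either by mean rank or by an iteratively
reweighted scheme that down-weights rankers far from the consensus.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .hetesim import OperatorCache, hetesim_profile
from .kg import KnowledgeGraph, write_triples
from .metapaths import MetaPath, enumerate_metapaths, format_metapath

logger = logging.getLogger(__name__)

SCORING_MODES = ("hetesim", "dwpc")


@dataclass(frozen=True)
class SimulationSpec:
    """Configuration of one ranking run.

    ``scoring='dwpc'`` replaces the per-metapath HeteSim by a walk-based
    degree-weighted path count with damping exponent ``dwpc_damping``
    (endpoint degrees included), a correction that keeps promiscuous
    high-degree nodes from dominating on raw connectivity.
    """

    name: str
    target_cuis: tuple[str, ...]
    source_semtypes: frozenset[str]
    max_metapath_length: int = 3
    predicate_allowlist: frozenset[str] | None = None
    aggregation: str = "mean_hetesim"  # or "rank_aggregation"
    normalization: str = "minmax"  # or "none"
    scoring: str = "hetesim"
    dwpc_damping: float = 0.4
    weighted: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.target_cuis:
            raise ValueError("at least one target CUI required")
        if not self.source_semtypes:
            raise ValueError("at least one source semtype required")
        if not 1 <= self.max_metapath_length <= 4:
            raise ValueError("max_metapath_length must be in [1, 4]")
        if self.scoring not in SCORING_MODES:
            raise ValueError(f"scoring must be one of {SCORING_MODES}")
        if self.aggregation not in ("mean_hetesim", "rank_aggregation"):
            raise ValueError("aggregation must be mean_hetesim or rank_aggregation")
        if self.normalization not in ("minmax", "none"):
            raise ValueError("normalization must be minmax or none")


@dataclass(frozen=True)
class RankedResult:
    source_cui: str
    source_name: str
    source_semtype: str
    raw_score: float
    normalized_score: float
    rank: int
    n_metapaths: int
    per_target_scores: tuple[float, ...] = ()


def normalize_scores(raw: Sequence[float], method: str = "minmax") -> list[float]:
    """Min-max normalize to [0, 1]; all-equal input maps to all 1.0.

    ``method='none'`` is the identity.  Empty input is an error.
    """
    if len(raw) == 0:
        raise ValueError("cannot normalize an empty score list")
    if method == "none":
        return list(raw)
    if method != "minmax":
        raise ValueError(f"unknown normalization {method!r}")
    lo, hi = min(raw), max(raw)
    if hi == lo:
        return [1.0] * len(raw)
    return [(x - lo) / (hi - lo) for x in raw]


def _dwpc_profile(
    graph: KnowledgeGraph,
    t: str,
    mp: MetaPath,
    w: float,
    cache: dict | None = None,
) -> dict[str, float]:
    """Walk-based DWPC of every source-semtype node against ``t``.

    Computed as a product of degree-damped adjacency matrices
    ``D_from^-w A_1 D^-w A_2 ... D_to^-w`` so whole candidate sets score in
    one pass; matches :func:`hetepath.metapaths.dwpc` with
    ``allow_revisits=True``.  ``cache`` memoizes per-step matrices across
    metapaths of one simulation.
    """
    from scipy import sparse

    if cache is None:
        cache = {}

    def damp(semtype: str) -> "sparse.dia_matrix":
        key = ("damp", semtype)
        if key not in cache:
            nodes = tuple(graph.nodes_of_semtype(semtype))
            degs = np.array([graph.degree(c) for c in nodes], dtype=float)
            with np.errstate(divide="ignore"):
                inv = np.where(degs > 0, degs ** (-w), 0.0)
            cache[key] = (nodes, sparse.diags(inv))
        return cache[key]

    def damped_step(step) -> "sparse.csr_matrix":
        if step not in cache:
            from_nodes, _ = damp(step.from_semtype)
            to_nodes, d_to = damp(step.to_semtype)
            fi = {c: i for i, c in enumerate(from_nodes)}
            ti = {c: i for i, c in enumerate(to_nodes)}
            rows, cols, vals = [], [], []
            for u, v, _support in graph.step_edges(
                step.predicate, step.from_semtype, step.to_semtype,
                reverse=step.is_reverse,
            ):
                rows.append(fi[u]); cols.append(ti[v]); vals.append(1.0)
            mat = sparse.csr_matrix(
                (vals, (rows, cols)), shape=(len(from_nodes), len(to_nodes))
            )
            cache[step] = mat @ d_to
        return cache[step]

    src_nodes, d_src = damp(mp.source_semtype)
    prod = d_src
    for step in mp.steps:
        prod = prod @ damped_step(step)
    tgt_nodes, _ = damp(mp.target_semtype)
    col = prod.tocsc()[:, tgt_nodes.index(t)].toarray().ravel()
    return dict(zip(src_nodes, col.tolist()))


def run_simulation(graph: KnowledgeGraph, spec: SimulationSpec) -> list[RankedResult]:
    """Score and rank every candidate node against the spec's targets.

    Candidates are all nodes whose semtype is allowed, minus the targets.
    Per target, metapaths of length <= ``max_metapath_length`` are
    enumerated; a candidate's per-target score is the mean per-metapath
    score (0 where its semtype has no metapath), and the raw score is the
    mean over targets.  Results are min-max normalized and sorted by
    normalized score, ties broken lexicographically by CUI.  Deterministic
    in (graph, spec).
    """
    for t in spec.target_cuis:
        if t not in graph:
            raise KeyError(f"target CUI {t} not found in graph")
    candidates = sorted(
        cui
        for st in spec.source_semtypes
        for cui in graph.nodes_of_semtype(st)
        if cui not in spec.target_cuis
    )
    if not candidates:
        logger.warning(
            "simulation %s: no candidates of semtypes %s",
            spec.name, sorted(spec.source_semtypes),
        )
        return []

    cache = OperatorCache(graph, spec.weighted)
    dwpc_cache: dict = {}
    per_target: dict[str, dict[str, float]] = {}
    n_mp_total = 0
    per_metapath_rankings: list[list[str]] = []
    for t in spec.target_cuis:
        metapaths = enumerate_metapaths(
            graph, spec.source_semtypes, t, spec.max_metapath_length
        )
        if spec.predicate_allowlist is not None:
            metapaths = [
                mp
                for mp in metapaths
                if all(s.predicate in spec.predicate_allowlist for s in mp.steps)
            ]
        n_mp_total += len(metapaths)
        sums = {c: 0.0 for c in candidates}
        for mp in metapaths:
            if spec.scoring == "dwpc":
                profile = _dwpc_profile(graph, t, mp, spec.dwpc_damping, dwpc_cache)
            else:
                profile = hetesim_profile(graph, t, mp, spec.weighted, cache)
            for c, v in profile.items():
                if c in sums:
                    sums[c] += v
            if spec.aggregation == "rank_aggregation":
                scored = [(c, profile.get(c, 0.0)) for c in candidates]
                per_metapath_rankings.append(
                    [c for c, _ in sorted(scored, key=lambda cv: (-cv[1], cv[0]))]
                )
        denom = max(len(metapaths), 1)
        per_target[t] = {c: sums[c] / denom for c in candidates}

    raw = {
        c: float(np.mean([per_target[t][c] for t in spec.target_cuis]))
        for c in candidates
    }
    if spec.aggregation == "rank_aggregation" and per_metapath_rankings:
        # consensus over the per-metapath rankings; the reported raw score
        # stays the mean HeteSim, the normalized score reflects consensus
        # position so the sorted-by-normalized-score contract holds
        ordered = aggregate_ranks(per_metapath_rankings, method="weighted_iterative")
        if len(ordered) > 1:
            norm_in_order = [
                1.0 - i / (len(ordered) - 1) for i in range(len(ordered))
            ]
        else:
            norm_in_order = [1.0]
        if spec.normalization == "none":
            norm_in_order = [raw[c] for c in ordered]
    else:
        ordered = sorted(candidates, key=lambda c: (-raw[c], c))
        norm_in_order = normalize_scores([raw[c] for c in ordered], spec.normalization)

    # ranks follow normalized score descending with lexicographic ties
    results = []
    for rank, (c, nv) in enumerate(zip(ordered, norm_in_order), start=1):
        node = graph.node(c)
        results.append(
            RankedResult(
                source_cui=c,
                source_name=node.name,
                source_semtype=node.semtype,
                raw_score=raw[c],
                normalized_score=nv,
                rank=rank,
                n_metapaths=n_mp_total,
                per_target_scores=tuple(per_target[t][c] for t in spec.target_cuis),
            )
        )
    return results


def aggregate_ranks(
    rankings: Sequence[Sequence[str]], method: str = "mean_rank"
) -> list[str]:
    """Combine ranked candidate lists into one consensus ordering.

    Candidates absent from a list are imputed rank ``len(list) + 1`` so
    rankers over different subsets stay commensurable.

    ``mean_rank``: order by mean imputed rank.  ``weighted_iterative``:
    start from uniform ranker weights, repeatedly set the consensus to the
    weighted mean of normalized ranks and each ranker's weight to the
    inverse of its mean squared deviation from that consensus, until the
    largest weight change is below 1e-6 (or 100 iterations).  Ties always
    break lexicographically by CUI.
    """
    if len(rankings) == 0:
        raise ValueError("need at least one ranking")
    universe = sorted({c for r in rankings for c in r})
    if method == "mean_rank":
        means = {
            c: float(
                np.mean(
                    [
                        (list(r).index(c) + 1) if c in r else len(r) + 1
                        for r in rankings
                    ]
                )
            )
            for c in universe
        }
        return sorted(universe, key=lambda c: (means[c], c))
    if method != "weighted_iterative":
        raise ValueError(f"unknown aggregation method {method!r}")

    # normalized rank matrix: rankers x candidates, imputed then / (len+1)
    mat = np.empty((len(rankings), len(universe)))
    for j, r in enumerate(rankings):
        pos = {c: i + 1 for i, c in enumerate(r)}
        for i, c in enumerate(universe):
            mat[j, i] = pos.get(c, len(r) + 1) / (len(r) + 1)
    weights = np.full(len(rankings), 1.0 / len(rankings))
    for _ in range(100):
        consensus = weights @ mat
        dev = np.mean((mat - consensus) ** 2, axis=1)
        new = 1.0 / (dev + 1e-12)
        new /= new.sum()
        if np.max(np.abs(new - weights)) < 1e-6:
            weights = new
            break
        weights = new
    consensus = weights @ mat
    order = {c: consensus[i] for i, c in enumerate(universe)}
    return sorted(universe, key=lambda c: (order[c], c))


# ---------------------------------------------------------------------------
# result serialization
# ---------------------------------------------------------------------------

RESULT_COLUMNS = [
    "rank", "cui", "name", "semtype", "raw_score", "normalized_score", "n_metapaths",
]


def results_frame(results: Sequence[RankedResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rank": r.rank,
                "cui": r.source_cui,
                "name": r.source_name,
                "semtype": r.source_semtype,
                "raw_score": f"{r.raw_score:.10g}",
                "normalized_score": f"{r.normalized_score:.10g}",
                "n_metapaths": r.n_metapaths,
            }
            for r in results
        ],
        columns=RESULT_COLUMNS,
    )


def graph_digest(graph: KnowledgeGraph) -> str:
    """SHA-256 of the canonical triple serialization."""
    import io

    buf = io.StringIO()
    write_triples(graph, buf)
    return hashlib.sha256(buf.getvalue().encode()).hexdigest()


def write_results(
    results: Sequence[RankedResult],
    spec: SimulationSpec,
    graph: KnowledgeGraph,
    out_dir: str | Path,
) -> Path:
    """Write the ranked table plus a JSON manifest; returns the table path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = out_dir / f"{spec.name}.tsv"
    results_frame(results).to_csv(table, sep="\t", index=False)
    manifest = {
        "simulation": spec.name,
        "spec": {
            **{k: sorted(v) if isinstance(v, frozenset) else v
               for k, v in asdict(spec).items()},
            "target_cuis": list(spec.target_cuis),
        },
        "graph_digest": graph_digest(graph),
        "n_results": len(results),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": spec.seed,
    }
    (out_dir / f"{spec.name}.manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=list)
    )
    return table
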
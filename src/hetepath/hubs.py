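"""Layered hub analysis: hub selection, per-hub simulations, back- and
cross-evaluation, and the final repurposed-candidate ranking.

The discovery procedure is layered: a preliminary simulation ranks sources
against the primary targets; highly ranked sources ("hubs" — nodes with many
related neighbors) become the targets of the next layer of simulations; a
candidate that keeps reappearing with a high normalized score across hub
simulations is promoted.  The final ranking orders candidates first by
recurrence (in how many layers/simulations they pass the score threshold)
and then by mean normalized score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .kg import KnowledgeGraph
from .simulation import RankedResult, SimulationSpec, run_simulation

logger = logging.getLogger(__name__)

DEFAULT_HUB_THRESHOLD = 0.2
DEFAULT_MAX_HUBS = 14
DRUG_SEMTYPES = frozenset({"PHSU", "CLND"})


@dataclass(frozen=True)
class HubSelection:
    """Hubs chosen from one simulation's ranked results."""

    hubs: tuple[RankedResult, ...]
    source_simulation: str
    threshold: float
    max_hubs: int

    @property
    def cuis(self) -> tuple[str, ...]:
        return tuple(h.source_cui for h in self.hubs)


@dataclass(frozen=True)
class CrossEvalTable:
    """Candidate x hub matrix of normalized scores above threshold.

    ``scores.loc[candidate, hub]`` is NaN where the candidate did not pass
    the threshold in that hub's simulation.  ``recurrence`` counts filled
    cells per candidate; ``mean_score`` averages them.
    """

    scores: pd.DataFrame
    recurrence: pd.Series
    mean_score: pd.Series
    threshold: float

    def column_rendering(self, hub_cui: str) -> list[tuple[str, float]]:
        """A hub's passing candidates with scores, descending (table-shaped
        output: within each column scores are listed in descending order)."""
        col = self.scores[hub_cui].dropna().sort_values(ascending=False)
        return list(zip(col.index.tolist(), col.tolist()))

    def row_rendering(self, candidate_cui: str) -> list[tuple[str, float]]:
        """The hubs in which a candidate passed, scores descending."""
        row = self.scores.loc[candidate_cui].dropna().sort_values(ascending=False)
        return list(zip(row.index.tolist(), row.tolist()))


def select_hubs(
    results: Sequence[RankedResult],
    threshold: float = DEFAULT_HUB_THRESHOLD,
    max_hubs: int = DEFAULT_MAX_HUBS,
    allowed_semtypes: Sequence[str] | None = None,
    source_simulation: str = "",
) -> HubSelection:
    """Top-ranked sources with normalized score >= threshold, optionally
    restricted by semtype, truncated to ``max_hubs`` (order preserved)."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    if max_hubs < 1:
        raise ValueError("max_hubs must be >= 1")
    allowed = set(allowed_semtypes) if allowed_semtypes is not None else None
    picked = [
        r
        for r in results
        if r.normalized_score >= threshold
        and (allowed is None or r.source_semtype in allowed)
    ][:max_hubs]
    if not picked:
        logger.warning("hub selection from %s is empty", source_simulation or "results")
    return HubSelection(
        hubs=tuple(picked),
        source_simulation=source_simulation,
        threshold=threshold,
        max_hubs=max_hubs,
    )


def run_hub_layer(
    graph: KnowledgeGraph,
    hubs: HubSelection,
    layer_spec: SimulationSpec,
) -> dict[str, list[RankedResult]]:
    """One simulation per hub, with that hub as the target.

    ``layer_spec`` is a template; its name is suffixed with the hub CUI and
    its targets replaced.  A hub missing from the graph is recorded and
    skipped; the other hubs proceed.
    """
    if not hubs.hubs:
        raise ValueError("hub selection is empty")
    out: dict[str, list[RankedResult]] = {}
    for hub in hubs.hubs:
        cui = hub.source_cui
        if cui not in graph:
            logger.error("hub %s missing from graph; skipped", cui)
            continue
        spec = replace(
            layer_spec, name=f"{layer_spec.name}_{cui}", target_cuis=(cui,)
        )
        out[cui] = run_simulation(graph, spec)
    return out


def back_evaluate(
    candidate_cui: str,
    hub_results: Mapping[str, Sequence[RankedResult]],
    threshold: float = DEFAULT_HUB_THRESHOLD,
) -> tuple[int, list[tuple[str, float]]]:
    """In which hub simulations does the candidate pass the threshold?

    Returns ``(count, [(hub_cui, normalized_score), ...])`` sorted by score
    descending (ties by hub CUI).  A candidate absent everywhere yields
    ``(0, [])``.
    """
    if not hub_results:
        raise ValueError("hub_results must be non-empty")
    passed = []
    for hub_cui in sorted(hub_results):
        for r in hub_results[hub_cui]:
            if r.source_cui == candidate_cui and r.normalized_score >= threshold:
                passed.append((hub_cui, r.normalized_score))
                break
    passed.sort(key=lambda hv: (-hv[1], hv[0]))
    return len(passed), passed


def cross_evaluate(
    hub_results: Mapping[str, Sequence[RankedResult]],
    threshold: float = DEFAULT_HUB_THRESHOLD,
) -> CrossEvalTable:
    """Tabulate candidates passing the threshold in >= 1 hub simulation.

    Rows ordered by (recurrence desc, mean score desc, CUI); needs at least
    two hub simulations to cross anything.
    """
    if len(hub_results) < 2:
        raise ValueError("cross-evaluation needs at least 2 hub simulations")
    hub_cuis = sorted(hub_results)
    cells: dict[str, dict[str, float]] = {}
    for hub in hub_cuis:
        for r in hub_results[hub]:
            if r.normalized_score >= threshold:
                cells.setdefault(r.source_cui, {})[hub] = r.normalized_score
    candidates = sorted(cells)
    scores = pd.DataFrame(
        [[cells[c].get(h, np.nan) for h in hub_cuis] for c in candidates],
        index=candidates,
        columns=hub_cuis,
        dtype=float,
    )
    recurrence = scores.notna().sum(axis=1)
    mean_score = scores.mean(axis=1)
    order = sorted(
        candidates, key=lambda c: (-recurrence[c], -mean_score[c], c)
    )
    scores = scores.loc[order]
    return CrossEvalTable(
        scores=scores,
        recurrence=recurrence.loc[order],
        mean_score=mean_score.loc[order],
        threshold=threshold,
    )


@dataclass(frozen=True)
class FinalCandidate:
    cui: str
    name: str
    semtype: str
    recurrence: int
    mean_score: float
    rank: int
    provenance: tuple[str, ...]  # layer/simulation labels where it passed


def final_ranking(
    preliminary: Sequence[tuple[str, Sequence[RankedResult]]],
    crosseval: CrossEvalTable | None,
    candidate_semtypes: Sequence[str] = tuple(sorted(DRUG_SEMTYPES)),
    threshold: float = DEFAULT_HUB_THRESHOLD,
    names: Mapping[str, tuple[str, str]] | None = None,
) -> list[FinalCandidate]:
    """Final candidate report: recurrence first, then mean score.

    ``preliminary`` is a list of (simulation name, results).  Recurrence is
    the number of preliminary simulations plus hub simulations in which the
    candidate's normalized score passes the threshold; the mean is over
    those passing scores.  Candidates are restricted to drug-like semtypes
    by default.  An empty/absent cross-eval table degrades to preliminary
    layers only (flagged in the log).
    """
    allowed = set(candidate_semtypes)
    info: dict[str, tuple[str, str]] = dict(names or {})
    passing: dict[str, list[tuple[str, float]]] = {}

    for sim_name, results in preliminary:
        for r in results:
            if r.source_semtype in allowed:
                info.setdefault(r.source_cui, (r.source_name, r.source_semtype))
                if r.normalized_score >= threshold:
                    passing.setdefault(r.source_cui, []).append(
                        (f"preliminary:{sim_name}", r.normalized_score)
                    )

    if crosseval is None or crosseval.scores.empty:
        logger.warning("empty cross-evaluation; final report from preliminary layers only")
    else:
        for cand in crosseval.scores.index:
            if cand in info and info[cand][1] not in allowed:
                continue
            if cand not in info:
                continue  # semtype unknown -> not a drug-like candidate
            row = crosseval.scores.loc[cand].dropna()
            for hub, v in row.items():
                passing.setdefault(cand, []).append((f"hub:{hub}", float(v)))

    ordered = sorted(
        passing,
        key=lambda c: (
            -len(passing[c]),
            -float(np.mean([v for _, v in passing[c]])),
            c,
        ),
    )
    out = []
    for rank, c in enumerate(ordered, start=1):
        name, semtype = info.get(c, ("?", "?"))
        out.append(
            FinalCandidate(
                cui=c,
                name=name,
                semtype=semtype,
                recurrence=len(passing[c]),
                mean_score=float(np.mean([v for _, v in passing[c]])),
                rank=rank,
                provenance=tuple(lbl for lbl, _ in passing[c]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# two-layer pipeline orchestration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed for one two-layer hub-analysis run."""

    preliminary: tuple[SimulationSpec, ...]
    hub_source_simulations: tuple[str, ...]  # which preliminary sims feed hub selection
    hub_threshold: float = DEFAULT_HUB_THRESHOLD
    max_hubs: int = DEFAULT_MAX_HUBS
    hub_allowed_semtypes: tuple[str, ...] | None = None
    hub_layer_template: SimulationSpec | None = None
    back_eval_cui: str | None = None
    candidate_semtypes: tuple[str, ...] = tuple(sorted(DRUG_SEMTYPES))


@dataclass(frozen=True)
class PipelineResult:
    preliminary: tuple[tuple[str, tuple[RankedResult, ...]], ...]
    hubs: HubSelection
    hub_results: dict[str, list[RankedResult]]
    crosseval: CrossEvalTable | None
    back_eval: tuple[int, list[tuple[str, float]]] | None
    final: tuple


def run_pipeline(graph: KnowledgeGraph, config: PipelineConfig) -> PipelineResult:
    """Preliminary simulations -> hub selection -> hub layer -> cross/back
    evaluation -> final ranking.  Deterministic in (graph, config)."""
    prelim: list[tuple[str, list[RankedResult]]] = []
    for spec in config.preliminary:
        prelim.append((spec.name, run_simulation(graph, spec)))

    hub_feed: list[RankedResult] = []
    for name, results in prelim:
        if name in config.hub_source_simulations:
            hub_feed.extend(results)
    hub_feed.sort(key=lambda r: (-r.normalized_score, r.source_cui))
    hubs = select_hubs(
        hub_feed,
        threshold=config.hub_threshold,
        max_hubs=config.max_hubs,
        allowed_semtypes=config.hub_allowed_semtypes,
        source_simulation=",".join(config.hub_source_simulations),
    )

    hub_results: dict[str, list[RankedResult]] = {}
    crosseval = None
    back = None
    if hubs.hubs and config.hub_layer_template is not None:
        hub_results = run_hub_layer(graph, hubs, config.hub_layer_template)
        if len(hub_results) >= 2:
            crosseval = cross_evaluate(hub_results, config.hub_threshold)
        if config.back_eval_cui is not None and hub_results:
            back = back_evaluate(config.back_eval_cui, hub_results, config.hub_threshold)

    names = {}
    for _, results in prelim:
        for r in results:
            names.setdefault(r.source_cui, (r.source_name, r.source_semtype))
    for results in hub_results.values():
        for r in results:
            names.setdefault(r.source_cui, (r.source_name, r.source_semtype))

    final = final_ranking(
        prelim,
        crosseval,
        candidate_semtypes=config.candidate_semtypes,
        threshold=config.hub_threshold,
        names=names,
    )
    return PipelineResult(
        preliminary=tuple((n, tuple(r)) for n, r in prelim),
        hubs=hubs,
        hub_results=hub_results,
        crosseval=crosseval,
        back_eval=back,
        final=tuple(final),
    )


def final_report_frame(final: Sequence[FinalCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rank": f.rank,
                "cui": f.cui,
                "name": f.name,
                "semtype": f.semtype,
                "recurrence": f.recurrence,
                "mean_score": f"{f.mean_score:.10g}",
                "provenance": ";".join(f.provenance),
            }
            for f in final
        ],
        columns=["rank", "cui", "name", "semtype", "recurrence", "mean_score", "provenance"],
    )


def load_hub_scores(source) -> dict[str, list[RankedResult]]:
    """Load precomputed hub-simulation scores for cross-eval replay.

    Expects a TSV with columns ``hub_cui, hub_name, candidate_cui,
    candidate_name, candidate_semtype, normalized_score``; one row per
    (hub simulation, candidate) cell.  Raw scores are taken equal to the
    normalized ones and ranks follow score order per hub.
    """
    df = pd.read_csv(source, sep="\t", dtype={"normalized_score": float})
    needed = {
        "hub_cui", "hub_name", "candidate_cui", "candidate_name",
        "candidate_semtype", "normalized_score",
    }
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"hub-score file missing column(s): {sorted(missing)}")
    out: dict[str, list[RankedResult]] = {}
    for hub_cui, group in df.groupby("hub_cui", sort=True):
        group = group.sort_values(
            ["normalized_score", "candidate_cui"], ascending=[False, True]
        )
        out[str(hub_cui)] = [
            RankedResult(
                source_cui=row.candidate_cui,
                source_name=row.candidate_name,
                source_semtype=row.candidate_semtype,
                raw_score=float(row.normalized_score),
                normalized_score=float(row.normalized_score),
                rank=i + 1,
                n_metapaths=0,
            )
            for i, row in enumerate(group.itertuples(index=False))
        ]
    return out


def crosseval_frame(table: CrossEvalTable) -> pd.DataFrame:
    """Delimited-matrix rendering of the cross-eval table (empty cells where
    a candidate missed the threshold)."""
    df = table.scores.copy()
    df.insert(0, "recurrence", table.recurrence)
    df.insert(1, "mean_score", table.mean_score.round(6))
    df.index.name = "candidate_cui"
    return df
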